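"""Internal cluster-validity indices and their best-k vote rules.

The default panel holds 25 label-free indices measuring cluster compactness
and separation (Ball-Hall, Banfield-Raftery, C-index, Calinski-Harabasz,
silhouette, ...).  Each index declares how its curve over k is read to cast
a vote for the number of clusters:

``min`` / ``max``
    the k minimizing / maximizing the index value;
``diff_drop`` / ``diff_rise``
    the k with the largest decrease / increase from k-1 (curves are
    anchored at the trivial k=1 partition where the index is defined);
``second_diff_max`` / ``second_diff_min``
    the k extremizing the second difference v[k-1] - 2 v[k] + v[k+1]
    (classic elbow reading for monotone curves such as trace(W));
``hartigan``
    the k with the largest drop of H(k) = (W_k / W_{k+1} - 1)(n - k - 1).

An index that is undefined for a partition (singular within-cluster
scatter, zero denominator, ...) abstains (NaN) instead of erroring.  All
cluster-internal variances use the population (1/n_q) convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class PartitionStats:
    """Shared geometry of a partition, computed once per index evaluation."""

    x: np.ndarray
    labels: np.ndarray  # 1..k

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.n, self.p = self.x.shape
        self.ks = np.unique(self.labels)
        self.k = len(self.ks)
        self.members = [np.flatnonzero(self.labels == q) for q in self.ks]
        self.sizes = np.array([len(m) for m in self.members])
        self.grand_mean = self.x.mean(axis=0)
        self.centroids = np.vstack([self.x[m].mean(axis=0) for m in self.members])
        diff = self.x - self.centroids[np.searchsorted(self.ks, self.labels)]
        self.d2_own = (diff**2).sum(axis=1)
        self.wgss_q = np.array([self.d2_own[m].sum() for m in self.members])
        self.wgss = float(self.wgss_q.sum())
        self.tss = float(((self.x - self.grand_mean) ** 2).sum())
        self.bgss = self.tss - self.wgss

    @cached_property
    def dist(self) -> np.ndarray:
        return squareform(pdist(self.x))

    @cached_property
    def pair_masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Condensed pairwise distances and within/between pair masks."""
        d = pdist(self.x)
        iu, ju = np.triu_indices(self.n, k=1)
        within = self.labels[iu] == self.labels[ju]
        return d, within, ~within

    @cached_property
    def scatter_w(self) -> np.ndarray:
        w = np.zeros((self.p, self.p))
        for m, c in zip(self.members, self.centroids):
            d = self.x[m] - c
            w += d.T @ d
        return w

    @cached_property
    def scatter_t(self) -> np.ndarray:
        d = self.x - self.grand_mean
        return d.T @ d

    @cached_property
    def concordance(self) -> tuple[float, float, int, int]:
        """(s_plus, s_minus, N_W, N_B) over within/between distance pairs."""
        d, within, between = self.pair_masks
        dw = np.sort(d[within])
        db = np.sort(d[between])
        nw, nb = len(dw), len(db)
        if nw == 0 or nb == 0:
            return np.nan, np.nan, nw, nb
        # s_plus: pairs (w, b) with w < b; s_minus: w > b; ties count neither
        lo = np.searchsorted(db, dw, side="left")
        hi = np.searchsorted(db, dw, side="right")
        s_minus = float(lo.sum())
        s_plus = float((nb - hi).sum())
        return s_plus, s_minus, nw, nb


# ---------------------------------------------------------------------------
# index formulas
# ---------------------------------------------------------------------------

def ball_hall(s: PartitionStats) -> float:
    return float(np.mean(s.wgss_q / s.sizes))


def banfield_raftery(s: PartitionStats) -> float:
    per = s.wgss_q / s.sizes
    if np.any(per <= 0):
        return np.nan
    return float((s.sizes * np.log(per)).sum())


def c_index(s: PartitionStats) -> float:
    d, within, _ = s.pair_masks
    nw = int(within.sum())
    if nw == 0 or nw == len(d):
        return np.nan
    ds = np.sort(d)
    s_min = ds[:nw].sum()
    s_max = ds[-nw:].sum()
    if s_max == s_min:
        return np.nan
    return float((d[within].sum() - s_min) / (s_max - s_min))


def calinski_harabasz(s: PartitionStats) -> float:
    if s.k < 2 or s.n == s.k or s.wgss == 0:
        return np.nan
    return float((s.bgss / (s.k - 1)) / (s.wgss / (s.n - s.k)))


def davies_bouldin(s: PartitionStats) -> float:
    if s.k < 2:
        return np.nan
    delta = np.array([np.sqrt(s.d2_own[m]).mean() for m in s.members])
    cd = squareform(pdist(s.centroids))
    if np.any(cd[np.triu_indices(s.k, 1)] == 0):
        return np.nan
    ratios = np.zeros(s.k)
    for q in range(s.k):
        other = [r for r in range(s.k) if r != q]
        ratios[q] = max((delta[q] + delta[r]) / cd[q, r] for r in other)
    return float(ratios.mean())


def dunn(s: PartitionStats) -> float:
    d, within, between = s.pair_masks
    if not between.any() or not within.any():
        return np.nan
    diam = d[within].max()
    if diam == 0:
        return np.nan
    return float(d[between].min() / diam)


def silhouette(s: PartitionStats) -> float:
    if s.k < 2 or s.k == s.n:
        return np.nan
    d = s.dist
    sil = np.zeros(s.n)
    for i in range(s.n):
        own = s.labels[i]
        same = (s.labels == own)
        same[i] = False
        a = d[i, same].mean() if same.any() else 0.0
        b = min(d[i, s.labels == q].mean() for q in s.ks if q != own)
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(sil.mean())


def xie_beni(s: PartitionStats) -> float:
    """Crisp Xie-Beni: WGSS over n times the minimal squared centroid gap."""
    if s.k < 2:
        return np.nan
    sep = pdist(s.centroids) ** 2
    if sep.min() == 0:
        return np.nan
    return float(s.wgss / (s.n * sep.min()))


def mcclain_rao(s: PartitionStats) -> float:
    d, within, between = s.pair_masks
    if not within.any() or not between.any() or d[between].mean() == 0:
        return np.nan
    return float(d[within].mean() / d[between].mean())


def ratkowsky_lance(s: PartitionStats) -> float:
    diff_t = s.x - s.grand_mean
    tss_j = (diff_t**2).sum(axis=0)
    wss_j = np.zeros(s.p)
    for m, c in zip(s.members, s.centroids):
        wss_j += ((s.x[m] - c) ** 2).sum(axis=0)
    if np.any(tss_j == 0):
        return np.nan
    rbar = np.sqrt((tss_j - wss_j) / tss_j).mean()
    return float(rbar / np.sqrt(s.k))


def scott_symons(s: PartitionStats) -> float:
    total = 0.0
    for m in s.members:
        nq = len(m)
        d = s.x[m] - s.x[m].mean(axis=0)
        sign, logdet = np.linalg.slogdet(d.T @ d / nq)
        if sign <= 0:
            return np.nan
        total += nq * logdet
    return float(total)


def marriot(s: PartitionStats) -> float:
    sign, logdet = np.linalg.slogdet(s.scatter_w)
    if sign <= 0:
        return np.nan
    return float(s.k**2 * np.exp(logdet))


def trace_w(s: PartitionStats) -> float:
    return float(s.wgss)


def trace_wib(s: PartitionStats) -> float:
    b = s.scatter_t - s.scatter_w
    try:
        return float(np.trace(np.linalg.solve(s.scatter_w, b)))
    except np.linalg.LinAlgError:
        return np.nan


def det_ratio(s: PartitionStats) -> float:
    st, lt = np.linalg.slogdet(s.scatter_t)
    sw, lw = np.linalg.slogdet(s.scatter_w)
    if st <= 0 or sw <= 0:
        return np.nan
    return float(np.exp(lt - lw))


def log_ss_ratio(s: PartitionStats) -> float:
    if s.bgss <= 0 or s.wgss <= 0:
        return np.nan
    return float(np.log(s.bgss / s.wgss))


def pbm(s: PartitionStats) -> float:
    e1 = np.sqrt(((s.x - s.grand_mean) ** 2).sum(axis=1)).sum()
    ek = np.sqrt(s.d2_own).sum()
    if ek == 0 or s.k < 2:
        return np.nan
    dk = pdist(s.centroids).max()
    return float(((1.0 / s.k) * (e1 / ek) * dk) ** 2)


def point_biserial(s: PartitionStats) -> float:
    d, within, between = s.pair_masks
    nw, nb = int(within.sum()), int(between.sum())
    nt = len(d)
    sd = d.std()
    if nw == 0 or nb == 0 or sd == 0:
        return np.nan
    return float((d[between].mean() - d[within].mean()) * np.sqrt(nw * nb) / nt / sd)


def gamma(s: PartitionStats) -> float:
    s_plus, s_minus, nw, nb = s.concordance
    if not np.isfinite(s_plus) or s_plus + s_minus == 0:
        return np.nan
    return float((s_plus - s_minus) / (s_plus + s_minus))


def g_plus(s: PartitionStats) -> float:
    s_plus, s_minus, nw, nb = s.concordance
    nt = nw + nb
    if not np.isfinite(s_minus) or nt < 2:
        return np.nan
    return float(2.0 * s_minus / (nt * (nt - 1)))


def tau(s: PartitionStats) -> float:
    s_plus, s_minus, nw, nb = s.concordance
    nt = nw + nb
    if not np.isfinite(s_plus) or nw == 0 or nb == 0:
        return np.nan
    return float((s_plus - s_minus) / np.sqrt(nb * nw * (nt * (nt - 1) / 2.0)))


def _scat(s: PartitionStats) -> float:
    var_tot = s.x.var(axis=0)
    norm_tot = np.linalg.norm(var_tot)
    if norm_tot == 0:
        return np.nan
    norms = [np.linalg.norm(s.x[m].var(axis=0)) for m in s.members]
    return float(np.mean(norms) / norm_tot)


def sd_index(s: PartitionStats) -> float:
    """Average scattering + total separation (unweighted variant)."""
    if s.k < 2:
        return np.nan
    scat = _scat(s)
    cd = squareform(pdist(s.centroids))
    np.fill_diagonal(cd, np.nan)
    row_sums = np.nansum(cd, axis=1)
    offdiag = cd[~np.isnan(cd)]
    if np.any(row_sums == 0) or offdiag.min() == 0 or not np.isfinite(scat):
        return np.nan
    dis = (offdiag.max() / offdiag.min()) * (1.0 / row_sums).sum()
    return float(scat + dis)


def s_dbw(s: PartitionStats) -> float:
    if s.k < 2:
        return np.nan
    scat = _scat(s)
    if not np.isfinite(scat):
        return np.nan
    radius = np.mean([np.sqrt(np.linalg.norm(s.x[m].var(axis=0))) for m in s.members])

    def density(point: np.ndarray, member_idx: np.ndarray) -> int:
        return int((np.linalg.norm(s.x[member_idx] - point, axis=1) <= radius).sum())

    total, pairs = 0.0, 0
    for q in range(s.k):
        for r in range(q + 1, s.k):
            union = np.concatenate([s.members[q], s.members[r]])
            dq = density(s.centroids[q], union)
            dr = density(s.centroids[r], union)
            dmid = density((s.centroids[q] + s.centroids[r]) / 2.0, union)
            if max(dq, dr) == 0:
                return np.nan
            total += dmid / max(dq, dr)
            pairs += 1
    return float(scat + total / pairs)


def wemmert_gancarski(s: PartitionStats) -> float:
    if s.k < 2:
        return np.nan
    d_cent = np.linalg.norm(s.x[:, None, :] - s.centroids[None, :, :], axis=2)
    own_pos = np.searchsorted(s.ks, s.labels)
    d_own = d_cent[np.arange(s.n), own_pos]
    d_cent[np.arange(s.n), own_pos] = np.inf
    d_other = d_cent.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(d_other > 0, d_own / d_other, np.where(d_own == 0, 1.0, np.inf))
    total = 0.0
    for q, m in enumerate(s.members):
        total += max(0.0, s.sizes[q] - r[m].sum())
    return float(total / s.n)


def hartigan_wgss(s: PartitionStats) -> float:
    """Within-cluster sum of squares; read through the Hartigan vote rule."""
    return float(s.wgss)


@dataclass(frozen=True)
class IndexSpec:
    name: str
    func: callable
    rule: str
    needs_anchor: bool = False  # curve rules use the k=1 partition as anchor


DEFAULT_PANEL: tuple[IndexSpec, ...] = (
    IndexSpec("ball_hall", ball_hall, "diff_drop", True),
    IndexSpec("banfield_raftery", banfield_raftery, "min"),
    IndexSpec("c_index", c_index, "min"),
    IndexSpec("calinski_harabasz", calinski_harabasz, "max"),
    IndexSpec("davies_bouldin", davies_bouldin, "min"),
    IndexSpec("dunn", dunn, "max"),
    IndexSpec("silhouette", silhouette, "max"),
    IndexSpec("xie_beni", xie_beni, "min"),
    IndexSpec("mcclain_rao", mcclain_rao, "min"),
    IndexSpec("ratkowsky_lance", ratkowsky_lance, "max"),
    IndexSpec("scott_symons", scott_symons, "min"),
    IndexSpec("marriot", marriot, "second_diff_max", True),
    IndexSpec("trace_w", trace_w, "second_diff_max", True),
    IndexSpec("trace_wib", trace_wib, "diff_rise", True),
    IndexSpec("det_ratio", det_ratio, "second_diff_min", True),
    IndexSpec("hartigan", hartigan_wgss, "hartigan", True),
    IndexSpec("pbm", pbm, "max"),
    IndexSpec("point_biserial", point_biserial, "max"),
    IndexSpec("gamma", gamma, "max"),
    IndexSpec("g_plus", g_plus, "min"),
    IndexSpec("tau", tau, "max"),
    IndexSpec("sd_index", sd_index, "min"),
    IndexSpec("s_dbw", s_dbw, "min"),
    IndexSpec("wemmert_gancarski", wemmert_gancarski, "max"),
    IndexSpec("log_ss_ratio", log_ss_ratio, "diff_rise"),
)

DEFAULT_PANEL_NAMES = tuple(ix.name for ix in DEFAULT_PANEL)
_PANEL_BY_NAME = {ix.name: ix for ix in DEFAULT_PANEL}


def get_panel(names: list[str] | None = None) -> tuple[IndexSpec, ...]:
    if names is None:
        return DEFAULT_PANEL
    unknown = [nm for nm in names if nm not in _PANEL_BY_NAME]
    if unknown:
        raise ValueError(f"unknown index name(s): {unknown}")
    return tuple(_PANEL_BY_NAME[nm] for nm in names)


def validity_indices(
    values: np.ndarray, labels: np.ndarray, panel: list[str] | None = None
) -> dict[str, float]:
    """Evaluate the index panel on one partition; NaN marks abstention."""
    specs = get_panel(panel)
    if len(specs) == 0:
        raise ValueError("panel must be non-empty")
    stats = PartitionStats(np.asarray(values, float), np.asarray(labels, int))
    out = {}
    for ix in specs:
        try:
            with np.errstate(all="ignore"):
                val = ix.func(stats)
        except (np.linalg.LinAlgError, ZeroDivisionError, FloatingPointError):
            val = np.nan
        out[ix.name] = float(val) if np.isfinite(val) else np.nan
    return out


# ---------------------------------------------------------------------------
# vote rules over index curves
# ---------------------------------------------------------------------------

def _argbest(cands: list[tuple[int, float]], maximize: bool) -> int | None:
    valid = [(k, v) for k, v in cands if np.isfinite(v)]
    if not valid:
        return None
    best = max(v for _, v in valid) if maximize else min(v for _, v in valid)
    # ties toward smaller k
    return min(k for k, v in valid if v == best)


def vote_for_k(spec: IndexSpec, curve: dict[int, float], n: int, k_range: tuple[int, int]) -> int | None:
    """Cast this index's vote given its value curve over k (1-anchored).

    Returns None when the index abstains (undefined values, or a curve rule
    with no admissible k).
    """
    k_min, k_max = k_range
    ks = [k for k in range(k_min, k_max + 1) if k in curve]
    if spec.rule == "min":
        return _argbest([(k, curve[k]) for k in ks], maximize=False)
    if spec.rule == "max":
        return _argbest([(k, curve[k]) for k in ks], maximize=True)
    if spec.rule in ("diff_drop", "diff_rise"):
        sign = 1.0 if spec.rule == "diff_drop" else -1.0
        cands = [
            (k, sign * (curve.get(k - 1, np.nan) - curve.get(k, np.nan))) for k in ks
        ]
        return _argbest(cands, maximize=True)
    if spec.rule in ("second_diff_max", "second_diff_min"):
        cands = [
            (k, curve.get(k - 1, np.nan) - 2 * curve.get(k, np.nan) + curve.get(k + 1, np.nan))
            for k in ks
        ]
        return _argbest(cands, maximize=spec.rule == "second_diff_max")
    if spec.rule == "hartigan":
        h = {}
        for k in range(1, k_max + 1):
            v, v1 = curve.get(k, np.nan), curve.get(k + 1, np.nan)
            if np.isfinite(v) and np.isfinite(v1) and v1 > 0:
                h[k] = (v / v1 - 1.0) * (n - k - 1)
        cands = [(k, h.get(k - 1, np.nan) - h.get(k, np.nan)) for k in ks]
        return _argbest(cands, maximize=True)
    raise AssertionError(spec.rule)
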