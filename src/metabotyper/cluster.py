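"""Multi-algorithm clustering, k selection by index voting, and consensus.

Nine partitioners are available: k-means, PAM (build+swap medoids), fuzzy
c-means (m=2, hardened by maximal membership), Ward hierarchical, Gaussian
mixture EM (diagonal covariance, hard posterior assignment), the three
hierarchically-initialized hybrids (H-Kmeans, H-PAM, H-fuzzy) and HCPC
(Ward on PCA scores covering >= 80% of variance, with a k-means
consolidation pass).

The number of clusters is chosen by majority voting: every internal
validity index of the panel votes for its optimal k per algorithm and
repeat, and the plurality wins (ties broken toward smaller k).  Final
cluster membership is a per-observation majority vote over the aligned
partitions of all algorithms (final consensus, FC).  A PC-score rule
assigns metabotypes directly from the signs of the first two autoscaled-PCA
score columns.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .indices import DEFAULT_PANEL_NAMES, get_panel, validity_indices, vote_for_k
from .pca import fit_pca

ALGORITHMS = (
    "hcpc",
    "h-kmeans",
    "h-pam",
    "h-fuzzy",
    "pam",
    "kmeans",
    "fuzzy",
    "hierarchical",
    "em",
)

_RETRY_CAP = 5


class EmptyClusterError(RuntimeError):
    pass


@dataclass
class Partition:
    """Per-sample cluster labels in 1..k from a single algorithm run."""

    labels: np.ndarray
    k: int
    algorithm: str = ""
    seed: int = 0
    repeat: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels))
        if present != set(range(1, self.k + 1)):
            raise ValueError(
                f"labels must cover 1..{self.k} with no empty cluster, got {sorted(present)}"
            )

    @property
    def n(self) -> int:
        return len(self.labels)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (deterministic)."""
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# individual algorithms
# ---------------------------------------------------------------------------

def _pam(x: np.ndarray, k: int, rng: np.random.Generator, medoids: np.ndarray | None = None) -> np.ndarray:
    """PAM: greedy BUILD then SWAP until no improving medoid exchange."""
    d = cdist(x, x)
    n = len(x)
    if medoids is None:
        # BUILD: first medoid minimizes total distance, then greedy additions
        medoids = [int(np.argmin(d.sum(axis=1)))]
        while len(medoids) < k:
            cur = d[:, medoids].min(axis=1)
            gains = np.maximum(cur[None, :] - d, 0).sum(axis=1)
            gains[medoids] = -np.inf
            medoids.append(int(np.argmax(gains)))
        medoids = np.array(medoids)
    else:
        medoids = np.array(medoids)
    cost = d[:, medoids].min(axis=1).sum()
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            others = np.setdiff1d(np.arange(n), medoids)
            for h in others:
                trial = medoids.copy()
                trial[mi] = h
                new_cost = d[:, trial].min(axis=1).sum()
                if new_cost < cost - 1e-12:
                    medoids, cost, improved = trial, new_cost, True
                    break
            if improved:
                break
    return np.argmin(d[:, medoids], axis=1) + 1


def _fuzzy_cmeans(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    m: float = 2.0,
    init_membership: np.ndarray | None = None,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means; returns (memberships n x k, hardened labels)."""
    n = len(x)
    if init_membership is None:
        u = rng.random((n, k)) + 1e-3
        u /= u.sum(axis=1, keepdims=True)
    else:
        u = init_membership.copy()
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d = cdist(x, centers)
        d = np.maximum(d, 1e-12)
        inv = d ** (-2.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(u_new - u).max() < tol:
            u = u_new
            break
        u = u_new
    return u, np.argmax(u, axis=1) + 1


def _ward_cut(x: np.ndarray, k: int) -> np.ndarray:
    z = linkage(x, method="ward")
    return fcluster(z, t=k, criterion="maxclust")


def _hier_centroids(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    return np.vstack([x[labels == q].mean(axis=0) for q in np.unique(labels)])


def _run_once(x: np.ndarray, algorithm: str, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    if algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(x) + 1
    if algorithm == "pam":
        return _pam(x, k, rng)
    if algorithm == "fuzzy":
        _, labels = _fuzzy_cmeans(x, k, rng)
        return labels
    if algorithm == "hierarchical":
        return _ward_cut(x, k)
    if algorithm == "em":
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", random_state=seed, reg_covar=1e-6
        )
        return gm.fit_predict(x) + 1
    if algorithm == "h-kmeans":
        init = _hier_centroids(x, _ward_cut(x, k))
        km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
        return km.fit_predict(x) + 1
    if algorithm == "h-pam":
        hl = _ward_cut(x, k)
        medoids = []
        for q in np.unique(hl):
            idx = np.flatnonzero(hl == q)
            within = cdist(x[idx], x[idx]).sum(axis=1)
            medoids.append(idx[int(np.argmin(within))])
        return _pam(x, k, rng, medoids=np.array(medoids))
    if algorithm == "h-fuzzy":
        hl = _ward_cut(x, k)
        u = np.full((len(x), k), 0.05 / max(k - 1, 1))
        u[np.arange(len(x)), hl - 1] = 0.95
        u /= u.sum(axis=1, keepdims=True)
        _, labels = _fuzzy_cmeans(x, k, rng, init_membership=u)
        return labels
    if algorithm == "hcpc":
        model = fit_pca(x, n_components=min(x.shape) - 1 if min(x.shape) > 2 else 2)
        a = int(np.searchsorted(model.r2x_cum, 0.80) + 1)
        a = max(2, min(a, model.scores.shape[1]))
        scores = model.scores[:, :a]
        hl = _ward_cut(scores, k)
        init = _hier_centroids(scores, hl)
        km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
        return km.fit_predict(scores) + 1
    raise ValueError(f"unknown algorithm {algorithm!r}")


def run_algorithm(
    values: np.ndarray, algorithm: str, k: int, seed: int, repeat: int = 0
) -> Partition:
    """Run one clustering algorithm at a given k.

    Retries with shifted seeds if hardening leaves an empty cluster
    (possible for fuzzy/EM); raises after the retry cap.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [2, {n - 1}]")
    for attempt in range(_RETRY_CAP):
        labels = _run_once(x, algorithm, k, seed + 1000 * attempt)
        if len(np.unique(labels)) == k:
            return Partition(_canonical(labels), k, algorithm, seed, repeat)
    raise EmptyClusterError(
        f"{algorithm} produced an empty cluster at k={k} after {_RETRY_CAP} retries"
    )


# ---------------------------------------------------------------------------
# k selection by index voting
# ---------------------------------------------------------------------------

@dataclass
class KSelectionResult:
    """Votes per index over the searched k range and the plurality winner."""

    best_k: int
    vote_counts: dict[int, int]
    votes: pd.DataFrame  # columns: algorithm, repeat, index, k
    per_repeat_best: list[int]
    panel: tuple[str, ...] = DEFAULT_PANEL_NAMES
    n_abstentions: int = 0


def select_k(
    values: np.ndarray,
    algorithms: tuple[str, ...] = ALGORITHMS,
    k_range: tuple[int, int] = (2, 10),
    repeats: int = 5,
    seed: int = 0,
    panel: list[str] | None = None,
) -> KSelectionResult:
    """Choose the number of clusters by plurality over index votes.

    For every algorithm x repeat, partitions are built for each k in the
    range, each panel index votes for its optimal k, and the winning k is
    the plurality over all votes (ties toward smaller k).  Per-repeat
    winners are recorded as a stability diagnostic.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    k_min, k_max = k_range
    if not (2 <= k_min <= k_max <= n - 1):
        raise ValueError(f"k_range {k_range} outside [2, {n - 1}]")
    specs = get_panel(panel)
    anchor = validity_indices(x, np.ones(n, dtype=int), panel=[s.name for s in specs])
    rows = []
    n_abst = 0
    for rep in range(repeats):
        for alg in algorithms:
            curves: dict[str, dict[int, float]] = {s.name: {1: anchor[s.name]} for s in specs}
            for k in range(k_min, k_max + 1):
                try:
                    part = run_algorithm(x, alg, k, seed + rep, repeat=rep)
                except EmptyClusterError:
                    continue
                vals = validity_indices(x, part.labels, panel=[s.name for s in specs])
                for name, v in vals.items():
                    curves[name][k] = v
            for s in specs:
                v = vote_for_k(s, curves[s.name], n, (k_min, k_max))
                if v is None:
                    n_abst += 1
                else:
                    rows.append({"algorithm": alg, "repeat": rep, "index": s.name, "k": v})
    if not rows:
        raise RuntimeError("all indices abstained; cannot select k")
    votes = pd.DataFrame(rows)
    counts = Counter(votes["k"])
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    per_repeat = []
    for rep in range(repeats):
        sub = Counter(votes.loc[votes["repeat"] == rep, "k"])
        if sub:
            per_repeat.append(max(sub.items(), key=lambda kv: (kv[1], -kv[0]))[0])
    return KSelectionResult(
        best_k=int(best),
        vote_counts=dict(sorted(counts.items())),
        votes=votes,
        per_repeat_best=per_repeat,
        panel=tuple(s.name for s in specs),
        n_abstentions=n_abst,
    )


# ---------------------------------------------------------------------------
# label alignment and final consensus
# ---------------------------------------------------------------------------

def align_labels(reference: Partition, other: Partition) -> Partition:
    """Relabel ``other`` by the bijection maximizing agreement with ``reference``.

    Solved exactly as an assignment problem on the k x k contingency table;
    agreement after alignment is never below agreement before.
    """
    if reference.n != other.n:
        raise ValueError("partitions have different numbers of observations")
    if reference.k != other.k:
        raise ValueError("partitions have different k")
    k = reference.k
    cont = np.zeros((k, k))
    for r, o in zip(reference.labels, other.labels):
        cont[r - 1, o - 1] += 1
    ref_idx, oth_idx = linear_sum_assignment(-cont)
    mapping = {o + 1: r + 1 for r, o in zip(ref_idx, oth_idx)}
    new_labels = np.array([mapping[lab] for lab in other.labels])
    return Partition(new_labels, k, other.algorithm, other.seed, other.repeat)


@dataclass
class ConsensusResult:
    """Per-observation majority vote over aligned partitions."""

    partition: Partition
    vote_table: pd.DataFrame  # observations x labels, counts
    contributing: list[str] = field(default_factory=list)


def final_consensus(partitions: list[Partition]) -> ConsensusResult:
    """Final consensus (FC): per-observation plurality over aligned partitions.

    All partitions must share n and k and be aligned to the first (the
    reference); ties go to the reference partition's label.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    ref = partitions[0]
    k, n = ref.k, ref.n
    for p in partitions[1:]:
        if p.n != n:
            raise ValueError("partitions have different numbers of observations")
        if p.k != k:
            raise ValueError(f"partition {p.algorithm!r} has k={p.k}, expected {k}")
    counts = np.zeros((n, k), dtype=int)
    for p in partitions:
        counts[np.arange(n), p.labels - 1] += 1
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        best = counts[i].max()
        winners = np.flatnonzero(counts[i] == best) + 1
        labels[i] = ref.labels[i] if ref.labels[i] in winners else winners[0]
    # consensus may leave a label empty in pathological vote splits; guard
    present = np.unique(labels)
    if len(present) < k:
        remap = {lab: j + 1 for j, lab in enumerate(present)}
        labels = np.array([remap[lab] for lab in labels])
        k = len(present)
    vote_table = pd.DataFrame(counts, columns=[f"label_{j + 1}" for j in range(ref.k)])
    return ConsensusResult(
        partition=Partition(labels, k, "final-consensus", ref.seed),
        vote_table=vote_table,
        contributing=[p.algorithm for p in partitions],
    )


def pc_score_clusters(scores: np.ndarray, mode: str = "2-group") -> Partition:
    """Metabotype assignment from the signs of 2 PCA score columns.

    2-group: group 1 iff PC2 >= 0, else group 2.  3-group: group 1 iff
    PC1 >= 0 and PC2 >= 0; group 2 iff PC1 >= 0 and PC2 < 0; group 3 iff
    PC1 < 0.  A score of exactly 0 counts as positive.  The scores should
    come from a PCA of autoscaled (centered + UV) data.
    """
    t = np.asarray(scores, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("PC-score clustering expects exactly 2 score columns")
    pc1, pc2 = t[:, 0], t[:, 1]
    if mode == "2-group":
        labels = np.where(pc2 >= 0, 1, 2)
        k = 2
    elif mode == "3-group":
        labels = np.where(pc1 < 0, 3, np.where(pc2 >= 0, 1, 2))
        k = 3
    else:
        raise ValueError(f"unknown mode {mode!r}")
    present = sorted(set(labels))
    if len(present) < k:  # a quadrant may be empty on real data
        remap = {lab: j + 1 for j, lab in enumerate(present)}
        labels = np.array([remap[lab] for lab in labels])
        k = len(present)
    return Partition(labels, k, f"pc-score-{mode}")
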