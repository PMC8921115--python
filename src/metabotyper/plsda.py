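"""PLS-DA with VIP selection, cross-validated Q², permutation and CV-ANOVA.

The classifier is PLS2 regression of autoscaled X on the centered one-hot
class matrix Y, fitted by the iterative NIPALS algorithm with deflation of
X per component.  Variable importance in projection (VIP) is

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a )

normalized so the mean squared VIP is 1; variables with VIP > 1 are the
selected set.  Q² is residual-based (1 - PRESS/SSY on raw dummy
predictions) under stratified row-wise cross-validation with per-fold
refitting of the autoscaling; model significance comes from a label
permutation test and from an F-test on cross-validated residuals
(CV-ANOVA, Eriksson-style formulation).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .cluster import Partition

_MAX_ITER = 1000
_TOL = 1e-12


@dataclass
class PLSDAModel:
    """Fitted PLS2 discriminant model on autoscaled X vs centered dummy Y."""

    weights: np.ndarray  # (p, A) X-weights w_a
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (m, A)
    scores: np.ndarray  # (n, A)
    classes: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    r2x: np.ndarray
    r2y: np.ndarray
    ssy_a: np.ndarray  # explained Y sum of squares per component
    n_components: int

    @property
    def r2x_cum(self) -> float:
        return float(self.r2x.sum())

    @property
    def r2y_cum(self) -> float:
        return float(self.r2y.sum())

    def coefficients(self) -> np.ndarray:
        """Regression coefficients B with Y_hat = Xs B (X autoscaled)."""
        w, p, q = self.weights, self.x_loadings, self.y_loadings
        r = w @ np.linalg.pinv(p.T @ w)
        return r @ q.T

    def predict(self, x_raw: np.ndarray) -> np.ndarray:
        xs = (np.asarray(x_raw, float) - self.x_mean) / self.x_sd
        return xs @ self.coefficients() + self.y_mean


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    y = (labels[:, None] == classes[None, :]).astype(float)
    return y, classes


def _autoscale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mean) / sd, mean, sd


def fit_plsda(values: np.ndarray, labels: Partition | np.ndarray, n_components: int = 2) -> PLSDAModel:
    """Fit a PLS-DA model; X is autoscaled internally, Y dummy is centered.

    Every class must have at least 2 members.  With a univariate y and one
    component the weight vector reduces to the closed form w ∝ X'y.
    """
    x_raw = np.asarray(values, dtype=float)
    lab = labels.labels if isinstance(labels, Partition) else np.asarray(labels)
    if len(lab) != len(x_raw):
        raise ValueError("labels and rows differ in length")
    classes, counts = np.unique(lab, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    small = classes[counts < 2]
    if len(small):
        raise ValueError(f"class(es) with < 2 members: {small.tolist()}")
    y_full, classes = _one_hot(lab)
    x, x_mean, x_sd = _autoscale(x_raw)
    y_mean = y_full.mean(axis=0)
    y = y_full - y_mean
    n, p = x.shape
    m = y.shape[1]
    ssx_tot = (x**2).sum()
    ssy_tot = (y**2).sum()
    a_max = n_components
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    Q = np.zeros((m, a_max))
    T = np.zeros((n, a_max))
    r2x = np.zeros(a_max)
    r2y = np.zeros(a_max)
    ssy_a = np.zeros(a_max)
    xr, yr = x.copy(), y.copy()
    for a in range(a_max):
        u = yr[:, int(np.argmax((yr**2).sum(axis=0)))].copy()
        if np.allclose(u, 0):
            break
        t = np.zeros(n)
        for _ in range(_MAX_ITER):
            w = xr.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t_new = xr @ w
            q = yr.T @ t_new / (t_new @ t_new)
            u = yr @ q / (q @ q) if q @ q > 0 else t_new
            if np.linalg.norm(t_new - t) <= _TOL * max(np.linalg.norm(t_new), 1e-30):
                t = t_new
                break
            t = t_new
        tt = t @ t
        if tt == 0:
            break
        pl = xr.T @ t / tt
        q = yr.T @ t / tt
        xr = xr - np.outer(t, pl)
        y_expl = np.outer(t, q)
        yr = yr - y_expl
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pl, q, t
        r2x[a] = np.outer(t, pl).ravel() @ np.outer(t, pl).ravel() / ssx_tot
        ssy_a[a] = (y_expl**2).sum()
        r2y[a] = ssy_a[a] / ssy_tot if ssy_tot > 0 else 0.0
    return PLSDAModel(
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        classes=classes,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        r2x=r2x,
        r2y=r2y,
        ssy_a=ssy_a,
        n_components=a_max,
    )


@dataclass
class VIPResult:
    vip: np.ndarray
    selected: np.ndarray  # indices with VIP > 1


def vip_scores(model: PLSDAModel) -> VIPResult:
    """Per-variable VIP and the VIP > 1 selected set (strict inequality)."""
    w, ssy = model.weights, model.ssy_a
    p = w.shape[0]
    tot = ssy.sum()
    if tot == 0:
        return VIPResult(np.ones(p), np.array([], dtype=int))
    norms = np.linalg.norm(w, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    contrib = (w / norms) ** 2 @ ssy
    vip = np.sqrt(p * contrib / tot)
    return VIPResult(vip, np.flatnonzero(vip > 1.0))


def _stratified_folds(labels: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Stratified test-index folds whose training parts keep all classes."""
    classes, counts = np.unique(labels, return_counts=True)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = [test for _, test in skf.split(np.zeros(len(labels)), labels)]
        ok = all(
            len(np.unique(np.delete(labels, test))) == len(classes) for test in splits
        )
        if ok:
            return splits
    raise ValueError("could not stratify folds without losing a class from training")


def q2_cv_plsda(
    values: np.ndarray,
    labels: Partition | np.ndarray,
    n_components: int = 2,
    folds: int = 7,
    seed: int = 0,
) -> float:
    """Cumulative Q² by stratified row-wise cross-validation.

    PRESS accumulates raw dummy-variable prediction error on held-out rows
    (residual-based, not classification error); autoscaling and Y centering
    are refit on each training fold.  Q² = 1 - PRESS/SSY.
    """
    x = np.asarray(values, dtype=float)
    lab = labels.labels if isinstance(labels, Partition) else np.asarray(labels)
    y_full, _ = _one_hot(lab)
    eff_folds = min(folds, int(np.bincount(np.unique(lab, return_inverse=True)[1]).min()))
    if eff_folds < 2:
        raise ValueError("smallest class too small for cross-validation")
    splits = _stratified_folds(lab, eff_folds, seed)
    press = 0.0
    ss = 0.0
    for test in splits:
        train = np.setdiff1d(np.arange(len(x)), test)
        model = fit_plsda(x[train], lab[train], n_components)
        y_hat = model.predict(x[test])
        y_test = y_full[test]
        press += ((y_test - y_hat) ** 2).sum()
        ss += ((y_test - y_full[train].mean(axis=0)) ** 2).sum()
    return 1.0 - press / ss if ss > 0 else np.nan


@dataclass
class PermutationResult:
    observed_q2: float
    observed_r2y: float
    null_q2: np.ndarray
    null_r2y: np.ndarray
    p_value: float


def permutation_test(
    values: np.ndarray,
    labels: Partition | np.ndarray,
    n_components: int = 2,
    n_perm: int = 99,
    seed: int = 0,
    folds: int = 7,
) -> PermutationResult:
    """Label permutation test on Q² with the add-one empirical p-value.

    p = (1 + #{null Q² >= observed Q²}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(values, dtype=float)
    lab = labels.labels if isinstance(labels, Partition) else np.asarray(labels)
    rng = np.random.default_rng(seed)
    obs_q2 = q2_cv_plsda(x, lab, n_components, folds, seed)
    obs_r2y = fit_plsda(x, lab, n_components).r2y_cum
    null_q2 = np.zeros(n_perm)
    null_r2y = np.zeros(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(lab)
        null_q2[b] = q2_cv_plsda(x, perm, n_components, folds, seed)
        null_r2y[b] = fit_plsda(x, perm, n_components).r2y_cum
    p = (1.0 + (null_q2 >= obs_q2).sum()) / (1.0 + n_perm)
    return PermutationResult(obs_q2, obs_r2y, null_q2, null_r2y, float(p))


@dataclass
class CVAnovaResult:
    f_statistic: float
    p_value: float
    df1: int
    df2: int
    press: float
    ssy: float
    degenerate: bool = False


def cv_anova(
    values: np.ndarray,
    labels: Partition | np.ndarray,
    n_components: int = 2,
    folds: int = 7,
    seed: int = 0,
) -> CVAnovaResult:
    """F-test on cross-validated predictive residuals (CV-ANOVA).

    Compares the PRESS of the PLS-DA model against the total corrected sum
    of squares of the class dummy matrix, with F = ((SSY - PRESS)/d1) /
    (PRESS/d2), d1 = A*M and d2 = M*(N - A - 1) for M dummy columns and A
    components.  When the model does not predict better than the class-mean
    null (PRESS >= SSY), p = 1.
    """
    x = np.asarray(values, dtype=float)
    lab = labels.labels if isinstance(labels, Partition) else np.asarray(labels)
    y_full, classes = _one_hot(lab)
    m = len(classes)
    n = len(lab)
    eff_folds = min(folds, int(np.bincount(np.unique(lab, return_inverse=True)[1]).min()))
    splits = _stratified_folds(lab, eff_folds, seed)
    press = 0.0
    ssy = 0.0
    for test in splits:
        train = np.setdiff1d(np.arange(n), test)
        model = fit_plsda(x[train], lab[train], n_components)
        y_hat = model.predict(x[test])
        press += ((y_full[test] - y_hat) ** 2).sum()
        ssy += ((y_full[test] - y_full[train].mean(axis=0)) ** 2).sum()
    df1 = n_components * m
    df2 = m * (n - n_components - 1)
    if press <= 0:
        return CVAnovaResult(np.inf, float(np.finfo(float).eps), df1, df2, press, ssy, True)
    f = ((ssy - press) / df1) / (press / df2)
    p = 1.0 if f <= 0 else float(sps.f.sf(f, df1, df2))
    return CVAnovaResult(float(f), p, df1, df2, float(press), float(ssy))
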