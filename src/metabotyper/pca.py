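"""Missing-tolerant PCA with R²X, cross-validated Q² and Hotelling flags.

Complete matrices are decomposed exactly (SVD); matrices with missing
cells (e.g. after a log transform of zero amounts) are fitted by EM-style
iterative imputation, alternating a low-rank reconstruction with
re-imputation of the missing cells, which minimizes the observed-cell
residual sum of squares.  Signs are fixed so the largest-magnitude loading
entry of each component is positive.

Q² is estimated by element-wise cross-validation: cells are deleted in a
deterministic diagonal-stripe pattern, the model is refit on the remaining
cells and Q² = 1 - PRESS/SS over the deleted cells.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pretreatment import PretreatmentSpec, enumerate_grid, pretreat

_MAX_ITER = 2000
# relative objective-improvement tolerance for the imputation iteration;
# tight enough that R2X/Q2 are stable at the precision reported
_TOL = 1e-5


class PCAConvergenceError(RuntimeError):
    def __init__(self, component: int):
        super().__init__(f"PCA did not converge on component {component}")
        self.component = component


@dataclass
class PCAModel:
    """Fitted principal component model.

    loadings: (p, A) with unit-norm columns; scores: (n, A);
    r2x: per-component explained variance; r2x_cum[a] = sum(r2x[:a+1]).
    """

    loadings: np.ndarray
    scores: np.ndarray
    r2x: np.ndarray
    r2x_cum: np.ndarray
    n_components: int

    def predict(self) -> np.ndarray:
        """Reconstruction T P' of the pretreated matrix."""
        return self.scores @ self.loadings.T


def _fix_sign(t: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    j = int(np.argmax(np.abs(p)))
    if p[j] < 0:
        return -t, -p
    return t, p


def fit_pca(values: np.ndarray, n_components: int = 2) -> PCAModel:
    """Fit PCA on a (possibly incomplete) pretreated matrix.

    Each row and column must retain at least one non-missing cell.  R²X is
    computed on non-missing cells: 1 - SS(residual)/SS(total).
    """
    x = np.asarray(values, dtype=float)
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    present = ~np.isnan(x)
    if np.any(present.sum(axis=1) == 0) or np.any(present.sum(axis=0) == 0):
        raise ValueError("each row and column needs >= 1 non-missing cell")
    ss_total = np.nansum(x**2)
    if present.all():
        # complete data: the sequential-deflation solution coincides with
        # the SVD, so take it directly
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        scores = u[:, :n_components] * s[:n_components]
        loadings = vt[:n_components].T.copy()
        for a in range(n_components):
            scores[:, a], loadings[:, a] = _fix_sign(scores[:, a], loadings[:, a])
        r2x = s[:n_components] ** 2 / ss_total if ss_total > 0 else np.zeros(n_components)
        return PCAModel(loadings, scores, r2x, np.cumsum(r2x), n_components)
    # incomplete data: EM-style iterative imputation — alternate a rank-A
    # SVD of the completed matrix with re-imputation of the missing cells
    # from the reconstruction; this minimizes the observed-cell residual
    # sum of squares monotonically (per-element skipping of missing cells
    # in the inner products is unstable when a row's observed columns all
    # carry small loadings)
    a_eff = min(n_components, n, p)
    colmean = np.nanmean(x, axis=0)
    xi = np.where(present, x, np.broadcast_to(colmean, x.shape))
    obj_prev = np.inf
    for _ in range(_MAX_ITER):
        u, s, vt = np.linalg.svd(xi, full_matrices=False)
        recon = (u[:, :a_eff] * s[:a_eff]) @ vt[:a_eff]
        obj = float(((x - recon)[present] ** 2).sum())
        xi = np.where(present, x, recon)
        # objective decreases monotonically; stop once improvements are
        # negligible relative to its size (the imputed cells may keep
        # drifting long after the observed-cell fit has stabilized)
        if obj_prev - obj <= _TOL * max(obj, 1e-30):
            break
        obj_prev = obj
    else:
        raise PCAConvergenceError(n_components)
    u, s, vt = np.linalg.svd(xi, full_matrices=False)
    scores = np.zeros((n, n_components))
    loadings = np.zeros((p, n_components))
    scores[:, :a_eff] = u[:, :a_eff] * s[:a_eff]
    loadings[:, :a_eff] = vt[:a_eff].T
    for a in range(a_eff):
        scores[:, a], loadings[:, a] = _fix_sign(scores[:, a], loadings[:, a])
    # R2X on observed cells, sequentially over components
    r2x = np.zeros(n_components)
    ss_prev = ss_total
    recon = np.zeros_like(x)
    for a in range(n_components):
        recon += np.outer(scores[:, a], loadings[:, a])
        ss_after = ((x - recon)[present] ** 2).sum()
        r2x[a] = (ss_prev - ss_after) / ss_total if ss_total > 0 else 0.0
        ss_prev = ss_after
    return PCAModel(loadings, scores, r2x, np.cumsum(r2x), n_components)


def q2_cv(values: np.ndarray, n_components: int = 2, folds: int = 7) -> float:
    """Cumulative Q² by diagonal-stripe element deletion.

    Fold f deletes cells (i, j) with (i + j) % folds == f.  Loadings are
    fitted on the fold's remaining cells (column-mean-completed SVD) and
    each deleted cell is predicted by projecting its row's remaining cells
    onto those loadings by least squares — a one-shot scheme that cannot
    drift, unlike fully iterated imputation whose held-out predictions are
    unbounded for high-leverage rows.  Q² = 1 - PRESS/SS over originally
    non-missing cells; it may be negative and never exceeds 1.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    x = np.asarray(values, dtype=float)
    n, p = x.shape
    a_eff = min(n_components, n, p)
    present = ~np.isnan(x)
    press = 0.0
    ss = np.nansum(x**2)
    rows = np.arange(n)[:, None]
    cols = np.arange(p)[None, :]
    for f in range(folds):
        mask = ((rows + cols) % folds == f) & present
        if not mask.any():
            continue
        xf = x.copy()
        xf[mask] = np.nan
        obs = ~np.isnan(xf)
        if np.any(obs.sum(axis=1) == 0) or np.any(obs.sum(axis=0) == 0):
            raise ValueError("fold pattern left an empty row or column")
        colmean = np.nanmean(xf, axis=0)
        xi = np.where(obs, xf, np.broadcast_to(colmean, xf.shape))
        _, _, vt = np.linalg.svd(xi, full_matrices=False)
        load = vt[:a_eff].T
        for i in np.unique(np.nonzero(mask)[0]):
            o = obs[i]
            t_i, *_ = np.linalg.lstsq(load[o], xf[i, o], rcond=None)
            pred = load @ t_i
            mj = mask[i]
            press += float(((pred[mj] - x[i, mj]) ** 2).sum())
    return 1.0 - press / ss if ss > 0 else np.nan


def hotelling_flags(scores: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Flag samples outside the Hotelling T² ellipse at level alpha.

    Flags are informational only; no observation is ever removed on their
    account (there is no wrong way to excrete these metabolites).
    """
    t = np.asarray(scores, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("Hotelling flagging expects 2-component scores")
    n, a = t.shape
    var = t.var(axis=0, ddof=1)
    if np.all(var == 0):
        return np.zeros(n, dtype=bool)
    var = np.where(var == 0, 1.0, var)
    t2 = (t**2 / var).sum(axis=1)
    crit = a * (n**2 - 1) / (n * (n - a)) * sps.f.ppf(1 - alpha, a, n - a)
    return t2 > crit


def pca_grid_report(
    individual: np.ndarray,
    sums: np.ndarray,
    n_components: int = 2,
    folds: int = 7,
) -> pd.DataFrame:
    """R²X(cum) and Q²(cum) for every cell of the pre-treatment grid.

    One row per spec (24 for both schemas), in the deterministic grid
    order.  A degenerate cell (e.g. a transform emptying a column) yields a
    ``failed`` status row instead of aborting the sweep.
    """
    data = {"individual": np.asarray(individual, float), "sums": np.asarray(sums, float)}
    rows = []
    for spec in enumerate_grid():
        row = {
            "dataset": spec.dataset,
            "transform": spec.transform,
            "scaling": spec.scaling,
            "r2x_cum": np.nan,
            "q2_cum": np.nan,
            "status": "ok",
        }
        try:
            pretreated, _ = pretreat(data[spec.dataset], spec)
            model = fit_pca(pretreated, n_components)
            row["r2x_cum"] = float(model.r2x_cum[-1])
            row["q2_cum"] = float(q2_cv(pretreated, n_components, folds))
        except (ValueError, PCAConvergenceError):
            row["status"] = "failed"
        rows.append(row)
    return pd.DataFrame(rows)
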