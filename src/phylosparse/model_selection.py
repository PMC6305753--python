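"""Cross-validation tuning of (lambda1, lambda2, alpha).

Model sparsity (lambda1), the strength of the phylogeny-based smoothing
(lambda2), and the phylogenetic depth of the signal (alpha) are tuned jointly
over a three-dimensional grid by k-fold cross-validation: predicted mean
square error (PMSE) for continuous outcomes, AUC for binary outcomes.  The
alpha and lambda2 grids default to {0} U {2^-5, ..., 2^5}; lambda1 runs on a
finer log-spaced path from the all-zero-solution anchor lambda_max down to a
small fraction of it, fitted with warm starts.

Leakage control: standardization, the lambda1 path anchor, and any
constant-column screening are computed inside each training fold only.  For
the linear family the outcome is also standardized fold-locally (and the
final refit's coefficients back-transformed), so that both penalty grids are
scale-free — the same convention glmnet uses for its gaussian family;
without it the absolute lambda2 grid would be meaningless for outcomes whose
scale is far from 1.  The
inverse correlation matrix depends on alpha alone, so it is built once per
alpha and shared across the (lambda2, lambda1) sub-grid — matrix inversion is
the O(p^3) part of the budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import phylo, solver
from .metrics import auc as auc_metric
from .metrics import pmse as pmse_metric

__all__ = [
    "TuningGrid",
    "CVResult",
    "default_grid",
    "lambda1_max",
    "lambda1_path",
    "cross_validate",
]

#: Available quadratic-structure choices for the smoothness penalty.
STRUCTURES = ("omega", "laplacian", "identity", "none")


@dataclass
class TuningGrid:
    """The three-dimensional search grid.

    ``lambda1_min_ratio=None`` resolves at fit time to 0.01 when p > n and
    0.0001 otherwise (glmnet convention).
    """

    alpha_values: np.ndarray
    lambda2_values: np.ndarray
    lambda1_path_length: int = 100
    lambda1_min_ratio: float | None = None

    def __post_init__(self) -> None:
        self.alpha_values = np.asarray(self.alpha_values, dtype=float)
        self.lambda2_values = np.asarray(self.lambda2_values, dtype=float)


def default_grid(lambda1_path_length: int = 100,
                 lambda1_min_ratio: float | None = None) -> TuningGrid:
    """The default {0} U {2^-5 ... 2^5} grids (12 values each) for alpha, lambda2."""
    vals = np.concatenate([[0.0], 2.0 ** np.arange(-5, 6)])
    return TuningGrid(alpha_values=vals, lambda2_values=vals.copy(),
                      lambda1_path_length=lambda1_path_length,
                      lambda1_min_ratio=lambda1_min_ratio)


def lambda1_max(design: solver.DesignMatrix, y: np.ndarray, family: str) -> float:
    """Smallest lambda1 at which the lambda2 = 0 solution is all-zero.

    For both families this is ``max_j |x_j'(y - ybar)| / n`` on the
    standardized design (for logistic, ybar is the case fraction).
    """
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        raise ValueError("y is constant; lambda_max undefined")
    r = y - y.mean()
    return float(np.max(np.abs(design.X.T @ r)) / design.n)


def lambda1_path(lam_max: float, length: int, min_ratio: float) -> np.ndarray:
    """Log-equispaced decreasing path from lam_max to lam_max * min_ratio."""
    if lam_max <= 0:
        raise ValueError("lambda_max must be positive")
    return np.exp(np.linspace(np.log(lam_max), np.log(lam_max * min_ratio), length))


@dataclass
class CVResult:
    """Cross-validation surface, selected parameters and the refitted model."""

    table: pd.DataFrame
    best: dict
    criterion_name: str
    fit: solver.SICSFit
    kept_columns: np.ndarray = field(repr=False, default=None)


def _resolve_structure(structure: str, D, alpha: float, p: int,
                       laplacian_sparsity: float, cache: dict) -> np.ndarray | None:
    """Build (and cache per alpha) the structure matrix for the penalty."""
    key = (structure, float(alpha))
    if key in cache:
        return cache[key]
    if structure == "none":
        S = None
    elif structure == "identity":
        S = np.eye(p)
    else:
        if D is None:
            raise ValueError(f"structure {structure!r} requires a distance matrix")
        C = phylo.correlation_matrix(D, alpha)
        if structure == "omega":
            S = phylo.inverse_correlation(C, alpha=alpha).Omega
        elif structure == "laplacian":
            S = phylo.build_laplacian(C, laplacian_sparsity).L
        else:
            raise ValueError(f"unknown structure {structure!r}")
    cache[key] = S
    return S


def _scale_outcome(y: np.ndarray, family: str):
    """Center/scale a continuous outcome to unit variance (fold-locally).

    Returns ``(y_scaled, shift, scale)``; the identity for the logistic
    family.  Makes the absolute lambda2 (and lambda1) grids scale-free.
    """
    if family != "linear":
        return y, 0.0, 1.0
    shift = float(y.mean())
    scale = float(y.std())
    if scale == 0:
        raise ValueError("y is constant")
    return (y - shift) / scale, shift, scale


def _unscale_fit(f: solver.SICSFit, shift: float, scale: float) -> solver.SICSFit:
    """Back-transform a fit trained on a scaled outcome to the original scale."""
    if shift == 0.0 and scale == 1.0:
        return f
    return solver.SICSFit(
        family=f.family, intercept=shift + scale * f.intercept,
        beta_std=scale * f.beta_std,
        intercept_orig=shift + scale * f.intercept_orig,
        beta_orig=scale * f.beta_orig, n_iter=f.n_iter,
        converged=f.converged, objective_trace=f.objective_trace,
        center=f.center, scale=f.scale, lambda1=f.lambda1,
        lambda2=f.lambda2, gamma=f.gamma,
    )


def _fold_standardize(X: np.ndarray):
    """Standardize, silently dropping fold-constant columns (recorded mask)."""
    sd = X.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    design = solver.standardize(X[:, keep])
    return design, keep


def cross_validate(
    X_raw: np.ndarray,
    y: np.ndarray,
    D=None,
    family: str = "linear",
    grid: TuningGrid | None = None,
    k: int = 5,
    seed: int = 0,
    gamma: float | None = None,
    structure: str = "omega",
    laplacian_sparsity: float = 0.9,
    tol: float = 1e-4,
) -> CVResult:
    """Tune (alpha, lambda2, lambda1) by k-fold CV and refit on all samples.

    Parameters
    ----------
    X_raw : ndarray of shape (n, p)
        Original-scale (normalized/transformed) abundances, samples by OTUs.
    D : PatristicDistanceMatrix or ndarray, optional
        Pairwise patristic distances; required unless ``structure`` is
        ``"identity"`` or ``"none"``.
    structure : {"omega", "laplacian", "identity", "none"}
        Quadratic penalty matrix: inverse phylogenetic correlation (the
        tree-regularized estimator), sparsified graph Laplacian, identity
        (MCP + ridge / Mnet), or no smoothness penalty (plain MCP; the
        lambda2 grid collapses to {0}).

    Returns
    -------
    CVResult
        CV table with one row per (alpha, lambda2, lambda1) and fold-mean
        criterion, the selected triple (ties broken toward larger lambda1,
        then larger alpha, then smaller lambda2), and the final model refit
        on all samples at the selected triple.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X_raw.shape
    if grid is None:
        grid = default_grid()
    if structure not in STRUCTURES:
        raise ValueError(f"structure must be one of {STRUCTURES}")
    if gamma is None:
        gamma = solver.GAMMA_DEFAULT[family]
    if n < 2 * k:
        raise ValueError(f"need n >= 2k samples for {k}-fold CV, got n={n}")

    min_ratio = grid.lambda1_min_ratio
    if min_ratio is None:
        min_ratio = 0.01 if p > n else 1e-4
    L = grid.lambda1_path_length

    alphas = grid.alpha_values
    lambda2s = grid.lambda2_values
    if structure == "none":
        lambda2s = np.array([0.0])
    if structure in ("identity", "none"):
        alphas = np.array([alphas[0]])  # alpha has no effect

    if family == "logistic":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_arg = y
        maximize = True
        criterion_name = "AUC"
        crit = auc_metric
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_arg = None
        maximize = False
        criterion_name = "PMSE"
        crit = pmse_metric

    folds = list(splitter.split(X_raw, split_arg))
    if family == "logistic":
        for tr, _ in folds:
            if len(np.unique(y[tr])) < 2:
                raise ValueError("a training fold contains a single class")

    # Per-fold designs, outcome scaling and path anchors are fold-local
    # (no leakage).
    fold_data = []
    for tr, te in folds:
        design, keep = _fold_standardize(X_raw[tr])
        y_tr, y_shift, y_scale = _scale_outcome(y[tr], family)
        lmax = lambda1_max(design, y_tr, family)
        path = lambda1_path(lmax, L, min_ratio)
        fold_data.append((tr, te, design, keep, path, y_tr, y_shift, y_scale))

    cache: dict = {}
    rows = []
    # criterion[ia, il2, ipath] mean over folds
    zero_l2_scores = None  # lambda2 = 0 surface is alpha-independent: reuse
    for ia, alpha in enumerate(alphas):
        S = None
        if np.any(lambda2s > 0):
            S = _resolve_structure(structure, D, alpha, p,
                                   laplacian_sparsity, cache)
        for il2, lam2 in enumerate(lambda2s):
            if lam2 == 0.0 and zero_l2_scores is not None:
                scores = zero_l2_scores
            else:
                scores = np.full((k, L), np.nan)
                for ifold, (tr, te, design, keep, path, y_tr, y_shift,
                            y_scale) in enumerate(fold_data):
                    Ssub = S[np.ix_(keep, keep)] if (S is not None and lam2 > 0) else None
                    fits = solver.fit_path(
                        design, y_tr, family, path, lambda2=float(lam2),
                        structure=Ssub, gamma=gamma, tol=tol,
                    )
                    X_te = X_raw[te][:, keep]
                    for il1, f in enumerate(fits):
                        pred = y_shift + y_scale * solver.predict(f, X_te)
                        scores[ifold, il1] = crit(y[te], pred)
                if lam2 == 0.0:
                    zero_l2_scores = scores
            mean = np.nanmean(scores, axis=0)
            se = np.nanstd(scores, axis=0, ddof=1) / np.sqrt(k)
            for il1 in range(L):
                rows.append((float(alpha), float(lam2), il1, mean[il1],
                             se[il1], scores[:, il1].copy()))

    table = pd.DataFrame(
        rows, columns=["alpha", "lambda2", "path_index", "mean_criterion",
                       "se_criterion", "fold_values"],
    )

    # Selection with deterministic tie-breaking: optimum first, then larger
    # lambda1 (smaller path index), larger alpha, smaller lambda2.
    crit_vals = table["mean_criterion"].to_numpy()
    best_val = np.nanmax(crit_vals) if maximize else np.nanmin(crit_vals)
    tied = table[np.isclose(crit_vals, best_val, rtol=0, atol=1e-12)]
    tied = tied.sort_values(
        by=["path_index", "alpha", "lambda2"],
        ascending=[True, False, True],
        kind="stable",
    )
    sel = tied.iloc[0]

    # Final refit on all samples at the selected triple.
    design_all, keep_all = _fold_standardize(X_raw)
    y_all, y_shift_all, y_scale_all = _scale_outcome(y, family)
    lmax_all = lambda1_max(design_all, y_all, family)
    path_all = lambda1_path(lmax_all, L, min_ratio)
    sel_alpha = float(sel["alpha"])
    sel_lambda2 = float(sel["lambda2"])
    sel_index = int(sel["path_index"])
    S = None
    if sel_lambda2 > 0:
        S = _resolve_structure(structure, D, sel_alpha, p,
                               laplacian_sparsity, cache)
        S = S[np.ix_(keep_all, keep_all)]
    fits = solver.fit_path(design_all, y_all, family, path_all[: sel_index + 1],
                           lambda2=sel_lambda2, structure=S, gamma=gamma,
                           tol=tol)
    final = _unscale_fit(fits[-1], y_shift_all, y_scale_all)
    # report lambda1 on the full-sample path; fold paths share the index
    table["lambda1"] = np.tile(path_all, len(table) // L)
    best = {
        "alpha": sel_alpha,
        "lambda2": sel_lambda2,
        "lambda1": float(path_all[sel_index]),
        "path_index": sel_index,
        "criterion": float(sel["mean_criterion"]),
    }
    # expand back to full p with zeros on dropped (constant) columns
    final = _expand_fit(final, keep_all, p)
    return CVResult(table=table, best=best, criterion_name=criterion_name,
                    fit=final, kept_columns=keep_all)


def _expand_fit(f: solver.SICSFit, keep: np.ndarray, p: int) -> solver.SICSFit:
    if keep.size == p:
        return f
    beta_std = np.zeros(p)
    beta_orig = np.zeros(p)
    center = np.zeros(p)
    scale = np.ones(p)
    beta_std[keep] = f.beta_std
    beta_orig[keep] = f.beta_orig
    center[keep] = f.center
    scale[keep] = f.scale
    return solver.SICSFit(
        family=f.family, intercept=f.intercept, beta_std=beta_std,
        intercept_orig=f.intercept_orig, beta_orig=beta_orig,
        n_iter=f.n_iter, converged=f.converged,
        objective_trace=f.objective_trace, center=center, scale=scale,
        lambda1=f.lambda1, lambda2=f.lambda2, gamma=f.gamma,
    )
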