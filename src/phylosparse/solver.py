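"""Penalized GLM core: MCP sparsity + quadratic structure penalty.

The estimator minimizes the penalized negative log-likelihood

    (1/n) sum_i -l(b0, beta; y_i, x_i)
        + sum_j mcp(|beta_j|; lambda1, gamma)
        + lambda2 * beta' S beta

over a standardized design (columns centered, sum of squares equal to n),
where ``S`` is a symmetric PSD structure matrix: the inverse phylogenetic
correlation matrix for the tree-regularized estimator, a graph Laplacian for
the Laplacian-regularized comparator, the identity for MCP+ridge (Mnet), or
absent (lambda2 = 0) for plain MCP / Lasso.  Linear models are solved by
cyclic coordinate descent with closed-form scalar updates; logistic models by
iteratively reweighted least squares (IRLS), each step solving a weighted
penalized linear problem with the same kernel.

Coefficients are reported both on the standardized scale and back-transformed
to the original scale.  No rescaling is applied to undo the l2-type shrinkage
of the quadratic penalty: for general designs rescaling inflates the variance
of the estimator and hurts prediction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._cd import cd_solve, mcp_value, scalar_mcp_update

__all__ = [
    "DesignMatrix",
    "PenaltySpec",
    "SICSFit",
    "standardize",
    "mcp_penalty",
    "quadratic_penalty",
    "scalar_update",
    "penalized_objective",
    "fit",
    "fit_path",
    "predict",
    "GAMMA_DEFAULT",
]

logger = logging.getLogger(__name__)

#: Default MCP concavity by family (ncvreg-style conventions).  gamma is
#: usually fixed to a reasonable value and not tuned.
GAMMA_DEFAULT = {"linear": 3.0, "logistic": 30.0}

_PROB_CLIP = 1e-5  # IRLS probability clipping


@dataclass
class DesignMatrix:
    """A standardized design: columns centered, sum of squares equal to n."""

    X: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    standardized: bool = True

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        """Apply the stored centering/scaling to new original-scale data."""
        X_raw = np.asarray(X_raw, dtype=float)
        return (X_raw - self.center) / self.scale


def standardize(X_raw: np.ndarray, column_ids=None) -> DesignMatrix:
    """Center columns to 0 and scale so each column's sum of squares is n.

    Raises on constant columns (zero variance), listing the offending OTU ids
    when ``column_ids`` is given; the caller should filter those out first.
    Idempotent: already-standardized input is returned unchanged to within
    numerical noise.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n = X_raw.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to standardize")
    center = X_raw.mean(axis=0)
    Xc = X_raw - center
    scale = np.sqrt(np.mean(Xc * Xc, axis=0))
    bad = np.flatnonzero(scale == 0)
    if bad.size:
        names = (
            [str(column_ids[j]) for j in bad] if column_ids is not None
            else [str(j) for j in bad]
        )
        raise ValueError(f"constant columns cannot be standardized: {names}")
    return DesignMatrix(X=Xc / scale, center=center, scale=scale)


@dataclass
class PenaltySpec:
    """Configuration of one penalized fit.

    ``structure`` is the symmetric PSD matrix of the quadratic penalty;
    ``None`` is only valid with ``lambda2 = 0``.
    """

    lambda1: float
    gamma: float = 3.0
    lambda2: float = 0.0
    structure: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be nonnegative")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be nonnegative")
        if self.gamma <= 1:
            raise ValueError(f"gamma must be > 1, got {self.gamma}")
        if self.lambda2 > 0 and self.structure is None:
            raise ValueError("lambda2 > 0 requires a structure matrix")
        if self.structure is not None:
            S = np.asarray(self.structure, dtype=float)
            if S.ndim != 2 or S.shape[0] != S.shape[1]:
                raise ValueError("structure matrix must be square")
            self.structure = S


@dataclass
class SICSFit:
    """Result of one penalized GLM fit."""

    family: str
    intercept: float                 # standardized-scale beta0
    beta_std: np.ndarray             # coefficients on the standardized scale
    intercept_orig: float
    beta_orig: np.ndarray            # coefficients on the original scale
    n_iter: int
    converged: bool
    objective_trace: np.ndarray
    center: np.ndarray = field(repr=False, default=None)
    scale: np.ndarray = field(repr=False, default=None)
    lambda1: float = np.nan
    lambda2: float = 0.0
    gamma: float = np.nan

    @property
    def nonzero(self) -> np.ndarray:
        """Indices of selected predictors (|beta| above numerical zero)."""
        return np.flatnonzero(np.abs(self.beta_std) > 1e-8)


def mcp_penalty(t, lambda1: float, gamma: float):
    """Minimax concave penalty, elementwise.

    ``lambda1 * |t| - t^2 / (2 gamma)`` for ``|t| <= gamma * lambda1``, then
    constant at ``gamma * lambda1^2 / 2`` (the penalty saturates, which is
    what makes large coefficients nearly unbiased).
    """
    if gamma <= 1:
        raise ValueError(f"gamma must be > 1, got {gamma}")
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    t = np.asarray(t, dtype=float)
    at = np.abs(t)
    out = np.where(
        at <= gamma * lambda1,
        lambda1 * at - at * at / (2.0 * gamma),
        0.5 * gamma * lambda1 * lambda1,
    )
    return out if out.ndim else float(out)


def quadratic_penalty(beta: np.ndarray, structure: np.ndarray, lambda2: float) -> float:
    """``lambda2 * beta' S beta`` for a symmetric PSD structure matrix."""
    beta = np.asarray(beta, dtype=float)
    S = np.asarray(structure, dtype=float)
    if S.shape != (beta.size, beta.size):
        raise ValueError(
            f"structure shape {S.shape} incompatible with beta of length {beta.size}"
        )
    return float(lambda2 * beta @ S @ beta)


def scalar_update(a: float, b: float, lambda1: float, gamma: float) -> float:
    """Closed-form minimizer of ``(a/2) t^2 - b t + mcp(|t|)``.

    Requires ``a > 1/gamma`` so the scalar subproblem is strictly convex.
    """
    if gamma <= 1:
        raise ValueError(f"gamma must be > 1, got {gamma}")
    if a <= 1.0 / gamma:
        raise ValueError(
            f"subproblem curvature a={a} <= 1/gamma={1.0 / gamma}: increase "
            "gamma or increase lambda2"
        )
    return float(scalar_mcp_update(a, b, lambda1, gamma))


def _neg_loglik(intercept: float, beta: np.ndarray, X: np.ndarray,
                y: np.ndarray, family: str) -> float:
    eta = intercept + X @ beta
    n = y.size
    if family == "linear":
        r = y - eta
        return float(0.5 * np.sum(r * r) / n)
    if family == "logistic":
        # -l = log(1 + e^eta) - y*eta, computed stably
        return float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    raise ValueError(f"unknown family {family!r}")


def penalized_objective(intercept: float, beta: np.ndarray, design: DesignMatrix,
                        y: np.ndarray, family: str, spec: PenaltySpec) -> float:
    """The full penalized negative log-likelihood at (intercept, beta)."""
    y = np.asarray(y, dtype=float)
    if family == "logistic" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("logistic family requires y in {0, 1}")
    beta = np.asarray(beta, dtype=float)
    obj = _neg_loglik(intercept, beta, design.X, y, family)
    obj += float(np.sum(mcp_penalty(beta, spec.lambda1, spec.gamma)))
    if spec.lambda2 > 0:
        obj += quadratic_penalty(beta, spec.structure, spec.lambda2)
    return obj


def _check_curvature(a_base: np.ndarray, spec: PenaltySpec) -> None:
    a = a_base.copy()
    if spec.lambda2 > 0:
        a = a + 2.0 * spec.lambda2 * np.diag(spec.structure)
    amin = float(a.min())
    if amin <= 1.0 / spec.gamma:
        raise ValueError(
            f"minimum coordinate curvature {amin:.3g} <= 1/gamma = "
            f"{1.0 / spec.gamma:.3g}; increase gamma or lambda2 so each "
            "scalar subproblem is convex"
        )


def _kernel_args(spec: PenaltySpec, p: int):
    if spec.lambda2 > 0:
        return np.ascontiguousarray(spec.structure), True
    return np.zeros((1, 1)), False


def fit(design: DesignMatrix, y: np.ndarray, family: str, spec: PenaltySpec,
        tol: float = 1e-4, max_sweeps: int = 1000, max_irls: int = 100,
        beta_init: np.ndarray | None = None,
        intercept_init: float | None = None) -> SICSFit:
    """Solve the penalized likelihood problem for one (lambda1, lambda2).

    Linear family: cyclic coordinate descent; the intercept equals the sample
    mean of ``y`` throughout (the design is centered) and is never penalized.
    Logistic family: IRLS outer loop, each step a weighted penalized linear
    solve, with probabilities clipped to [1e-5, 1 - 1e-5] and step-halving if
    the penalized objective increases.

    Convergence: ``max_j |delta beta_j| < tol * max(1, max_j |beta_j|)`` over
    a full sweep (per IRLS step for logistic).  Non-convergence returns a fit
    with ``converged=False`` and logs a warning.
    """
    X = np.ascontiguousarray(design.X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = (np.zeros(p) if beta_init is None
            else np.asarray(beta_init, dtype=float).copy())
    Omega, use_omega = _kernel_args(spec, p)

    if family == "linear":
        w = np.ones(n)
        _check_curvature(np.full(p, 1.0) if design.standardized
                         else (X * X).mean(axis=0), spec)
        beta0 = float(y.mean())
        beta0, n_iter, converged, trace = cd_solve(
            X, y, w, Omega, use_omega, spec.lambda1, spec.gamma, spec.lambda2,
            beta0, beta, False, tol, max_sweeps,
        )
    elif family == "logistic":
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("logistic family requires y in {0, 1}")
        ybar = float(np.clip(y.mean(), _PROB_CLIP, 1 - _PROB_CLIP))
        beta0 = (float(intercept_init) if intercept_init is not None
                 else float(np.log(ybar / (1 - ybar))))
        obj_prev = penalized_objective(beta0, beta, design, y, family, spec)
        trace_list = [obj_prev]
        converged = False
        n_iter = 0
        # Weight floor: with working response z = eta + (y - mu)/w the IRLS
        # fixed points solve the true score equations for ANY positive
        # weights, so flooring w only slows steps near separation while
        # keeping every scalar MCP subproblem convex (a_j > 1/gamma).
        w_floor = min(0.25, 2.0 / spec.gamma)
        for it in range(max_irls):
            n_iter = it + 1
            eta = beta0 + X @ beta
            mu = np.clip(expit(eta), _PROB_CLIP, 1 - _PROB_CLIP)
            w = np.maximum(mu * (1.0 - mu), w_floor)
            z = eta + (y - mu) / w
            _check_curvature((w[:, None] * X * X).mean(axis=0), spec)
            beta_old = beta.copy()
            beta0_old = beta0
            beta0, _, _, _ = cd_solve(
                X, z, w, Omega, use_omega, spec.lambda1, spec.gamma,
                spec.lambda2, beta0, beta, True, tol, max_sweeps,
            )
            obj = penalized_objective(beta0, beta, design, y, family, spec)
            halvings = 0
            while obj > obj_prev + 1e-12 and halvings < 20:
                beta = 0.5 * (beta + beta_old)
                beta0 = 0.5 * (beta0 + beta0_old)
                obj = penalized_objective(beta0, beta, design, y, family, spec)
                halvings += 1
            trace_list.append(obj)
            delta = np.max(np.abs(beta - beta_old)) if p else 0.0
            ref = max(1.0, float(np.max(np.abs(beta))) if p else 0.0)
            obj_prev = obj
            if delta < tol * ref:
                converged = True
                break
        trace = np.array(trace_list)
    else:
        raise ValueError(f"unknown family {family!r}")

    if not converged:
        logger.warning(
            "solver did not converge in %d iterations (family=%s, lambda1=%g, "
            "lambda2=%g)", n_iter, family, spec.lambda1, spec.lambda2,
        )

    beta_orig = beta / design.scale
    intercept_orig = beta0 - float(beta_orig @ design.center)
    return SICSFit(
        family=family, intercept=float(beta0), beta_std=beta,
        intercept_orig=intercept_orig, beta_orig=beta_orig,
        n_iter=int(n_iter), converged=bool(converged),
        objective_trace=np.asarray(trace), center=design.center,
        scale=design.scale, lambda1=spec.lambda1, lambda2=spec.lambda2,
        gamma=spec.gamma,
    )


def fit_path(design: DesignMatrix, y: np.ndarray, family: str,
             lambda1_sequence: np.ndarray, lambda2: float = 0.0,
             structure: np.ndarray | None = None, gamma: float | None = None,
             tol: float = 1e-4, max_sweeps: int = 1000,
             max_irls: int = 100) -> list[SICSFit]:
    """Fit a decreasing lambda1 path with warm starts.

    Each fit is initialized at the previous solution; the first at zero.
    """
    lam1 = np.asarray(lambda1_sequence, dtype=float)
    if lam1.size > 1 and np.any(np.diff(lam1) >= 0):
        raise ValueError("lambda1 sequence must be strictly decreasing")
    if gamma is None:
        gamma = GAMMA_DEFAULT[family]
    fits: list[SICSFit] = []
    beta = None
    b0 = None
    for l1 in lam1:
        spec = PenaltySpec(lambda1=float(l1), gamma=gamma, lambda2=lambda2,
                           structure=structure)
        f = fit(design, y, family, spec, tol=tol, max_sweeps=max_sweeps,
                max_irls=max_irls, beta_init=beta, intercept_init=b0)
        fits.append(f)
        beta = f.beta_std
        b0 = f.intercept
    return fits


def predict(fit_result: SICSFit, X_new: np.ndarray) -> np.ndarray:
    """Predict on original-scale predictors aligned with the training columns.

    Linear: the linear predictor.  Logistic: event probabilities.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != fit_result.beta_orig.size:
        raise ValueError(
            f"X_new has {X_new.shape[1] if X_new.ndim == 2 else '?'} columns, "
            f"model expects {fit_result.beta_orig.size}"
        )
    eta = fit_result.intercept_orig + X_new @ fit_result.beta_orig
    if fit_result.family == "logistic":
        return expit(eta)
    return eta
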