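"""Restricted cubic spline (natural spline) logistic dose–response modelling.

The restricted cubic basis with knots t_1 < … < t_k has k−1 columns: the
identity, plus for j = 1..k−2

    C_j(x) = [ (x−t_j)₊³
               − (x−t_{k−1})₊³ · (t_k−t_j)/(t_k−t_{k−1})
               + (x−t_k)₊³   · (t_{k−1}−t_j)/(t_k−t_{k−1}) ] / (t_k−t_1)²

which is C²-continuous and exactly linear outside [t_1, t_k].  The division
by (t_k−t_1)² is a conditioning convention only; it rescales coefficients
but not fitted probabilities.

Fitting is plain Newton–Raphson maximum likelihood with step halving;
bootstrap confidence bands are pointwise percentile intervals over
case-resampled refits (knots re-placed per resample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "SplineSpec",
    "RcsLogisticModel",
    "DoseResponseCurve",
    "place_knots",
    "rcs_basis",
    "fit_rcs_logistic",
    "dose_response",
    "DEFAULT_KNOT_PROBS",
]

# quantile probabilities for knot placement, by knot count (Harrell-style defaults)
DEFAULT_KNOT_PROBS = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations for a restricted cubic basis (biomarker units)."""

    knots: tuple

    def __post_init__(self):
        knots = tuple(float(t) for t in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 3:
            raise ValueError("restricted cubic splines need at least 3 knots")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing, got {knots}")

    @property
    def k(self) -> int:
        return len(self.knots)

    @property
    def n_basis(self) -> int:
        return self.k - 1


def place_knots(x, k: int = 4, probs=None) -> SplineSpec:
    """Place ``k`` knots at sample quantiles of ``x`` (linear interpolation).

    Default probabilities: 3 knots → (0.10, 0.50, 0.90); 4 → (0.05, 0.35,
    0.65, 0.95); 5 → (0.05, 0.275, 0.50, 0.725, 0.95).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if probs is None:
        if k not in DEFAULT_KNOT_PROBS:
            raise ValueError(f"no default quantile rule for k={k}; pass probs")
        probs = DEFAULT_KNOT_PROBS[k]
    if len(probs) != k:
        raise ValueError("len(probs) must equal k")
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct values to place {k} knots")
    knots = np.quantile(x, probs)  # numpy default = linear interpolation
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            f"coincident knots {knots} at quantiles {probs}; try a smaller k"
        )
    return SplineSpec(knots=tuple(knots))


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the restricted cubic basis; shape (n, k−1), column 0 = x."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(spec.knots)
    k = spec.k
    scale = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        tj = t[j]
        term = (
            np.clip(x - tj, 0, None) ** 3
            - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - tj) / (t[-1] - t[-2])
            + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - tj) / (t[-1] - t[-2])
        )
        cols.append(term / scale)
    return np.column_stack(cols)


@dataclass
class RcsLogisticModel:
    """Maximum-likelihood logistic fit on a restricted cubic basis."""

    spec: SplineSpec
    coef: np.ndarray  # (intercept, linear, k−2 nonlinear)
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    separation_flag: bool
    x_sd: np.ndarray = field(repr=False, default=None)

    def predict_prob(self, x) -> np.ndarray:
        X = np.column_stack([np.ones(np.asarray(x, dtype=float).shape[0]), rcs_basis(x, self.spec)])
        return expit(X @ self.coef)


def _bernoulli_loglik(y, eta):
    # stable: log σ(η)·y + log σ(−η)·(1−y)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_rcs_logistic(y, x, spec: SplineSpec, tol: float = 1e-8, max_iter: int = 100) -> RcsLogisticModel:
    """Newton–Raphson logistic MLE of the outcome on the spline basis of ``x``.

    Converges when the infinity-norm of the score drops below ``tol``.
    Separation is flagged when any coefficient exceeds 15 on the
    standardized (per-column SD) scale or the fit classifies perfectly.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    B = rcs_basis(x, spec)
    X = np.column_stack([np.ones(len(y)), B])
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    ll = _bernoulli_loglik(y, X @ beta)
    converged = False
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (y - p)
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < tol:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving keeps the log-likelihood nondecreasing
        t_step = 1.0
        for _ in range(50):
            cand = beta + t_step * step
            ll_new = _bernoulli_loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            t_step *= 0.5
        beta = beta + t_step * step
        ll = _bernoulli_loglik(y, X @ beta)
    eta = X @ beta
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p_dim, p_dim), np.nan)
    x_sd = X.std(axis=0, ddof=1)
    x_sd[0] = 1.0
    std_coef = beta * x_sd
    perfect = np.all((p > 0.5) == (y == 1.0))
    separation = bool(np.any(np.abs(std_coef[1:]) > 15.0) or (perfect and grad_norm > tol))
    return RcsLogisticModel(
        spec=spec,
        coef=beta,
        cov=cov,
        loglik=ll,
        converged=converged,
        n_iter=it,
        grad_norm=grad_norm,
        separation_flag=separation,
        x_sd=x_sd,
    )


@dataclass
class DoseResponseCurve:
    """Fitted event probability over a biomarker grid with bootstrap bands."""

    grid: np.ndarray
    fit: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_boot: int
    n_failed: int


def default_grid(x, n_points: int = 200, q=(0.005, 0.995)) -> np.ndarray:
    """Evaluation grid spanning the central part of the data support."""
    x = np.asarray(x, dtype=float)
    lo, hi = np.quantile(x, q)
    return np.linspace(lo, hi, n_points)


def dose_response(y, x, spec: SplineSpec, grid=None, B: int = 2000, seed: int = 0,
                  knot_probs=None) -> DoseResponseCurve:
    """Dose–response curve with pointwise 95% percentile bootstrap bands.

    Each of the ``B`` replicates case-resamples (y, x) pairs, re-places the
    knots on the resample with the same quantile rule, refits, and predicts
    on the grid.  Replicates whose refit fails (degenerate resample,
    coincident knots, one outcome class) are dropped and counted.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for percentile bands")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if grid is None:
        grid = default_grid(x)
    grid = np.asarray(grid, dtype=float)
    model = fit_rcs_logistic(y, x, spec)
    fit = model.predict_prob(grid)
    rng = np.random.default_rng(seed)
    n = len(y)
    curves = np.empty((B, grid.size))
    n_failed = 0
    kept = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        yb, xb = y[idx], x[idx]
        try:
            spec_b = place_knots(xb, k=spec.k, probs=knot_probs)
            mb = fit_rcs_logistic(yb, xb, spec_b)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        curves[kept] = mb.predict_prob(grid)
        kept += 1
    if kept == 0:
        raise RuntimeError("all bootstrap replicates failed")
    lo, hi = np.percentile(curves[:kept], [2.5, 97.5], axis=0)
    # percentile bands may not enclose the point fit at finite B
    lo = np.minimum(lo, fit)
    hi = np.maximum(hi, fit)
    return DoseResponseCurve(grid=grid, fit=fit, lo=lo, hi=hi, n_boot=kept, n_failed=n_failed)
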