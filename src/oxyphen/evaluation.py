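"""Out-of-fold model evaluation: discrimination, calibration, operating
points, paired bootstrap ΔAUC, and inversion of a probability threshold to
a biomarker-scale cutoff.

All bootstrap intervals are seeded percentile intervals over case
resamples.  The AUC is the Mann–Whitney estimator (tied predictions get
half credit), so it equals the fraction of correctly ordered
positive/negative pairs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit
import statsmodels.api as sm

from .rcs_logistic import (
    DoseResponseCurve,
    fit_rcs_logistic,
    place_knots,
    rcs_basis,
)

__all__ = [
    "auc",
    "auc_ci",
    "brier",
    "roc_curve",
    "youden_point",
    "paired_delta_auc",
    "calibration",
    "map_threshold_to_biomarker",
    "OperatingPoint",
    "DeltaAucResult",
    "CalibrationResult",
    "CutoffMapping",
]


def _check_binary(y):
    y = np.asarray(y, dtype=float)
    classes = set(np.unique(y))
    if classes - {0.0, 1.0}:
        raise ValueError("outcomes must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    return y


def auc(y, p) -> float:
    """Mann–Whitney AUC: P(p⁺ > p⁻) + ½·P(p⁺ = p⁻) via average ranks."""
    y = _check_binary(y)
    p = np.asarray(p, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def brier(y, p) -> float:
    """Mean squared difference between predicted probability and outcome."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def roc_curve(y, p):
    """Ordered (FPR, TPR) points over all distinct thresholds."""
    y = _check_binary(y)
    p = np.asarray(p, dtype=float)
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last point of each tied-threshold run
    keep = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tpr = np.r_[0.0, tps[keep] / y.sum()]
    fpr = np.r_[0.0, fps[keep] / (len(y) - y.sum())]
    return fpr, tpr


def _sens_spec(y, p, threshold):
    pred = p >= threshold
    pos = y == 1
    sens = np.mean(pred[pos]) if pos.any() else np.nan
    spec = np.mean(~pred[~pos]) if (~pos).any() else np.nan
    return float(sens), float(spec)


def _scan_youden(y, p):
    # candidate thresholds = observed prediction values; ties broken toward
    # the larger threshold (higher specificity)
    candidates = np.unique(p)
    best = None
    for t in candidates:
        sens, spec = _sens_spec(y, p, t)
        j = sens + spec - 1
        if best is None or j > best[1] + 1e-15 or (abs(j - best[1]) <= 1e-15 and t > best[0]):
            best = (t, j, sens, spec)
    return best


def auc_ci(y, p, B: int = 2000, seed: int = 0) -> tuple:
    """Percentile bootstrap 95% CI for the Mann–Whitney AUC."""
    y = _check_binary(y)
    p = np.asarray(p, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    vals = []
    while len(vals) < B:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        vals.append(auc(yb, p[idx]))
    return tuple(np.percentile(vals, [2.5, 97.5]))


@dataclass
class OperatingPoint:
    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float
    sens_ci: tuple
    spec_ci: tuple


def youden_point(y, p, B: int = 2000, seed: int = 0) -> OperatingPoint:
    """Youden-optimal probability threshold with bootstrap sens/spec CIs.

    The whole selection procedure (threshold re-scan) is repeated inside
    each bootstrap replicate.
    """
    y = _check_binary(y)
    p = np.asarray(p, dtype=float)
    t_star, j, sens, spec = _scan_youden(y, p)
    rng = np.random.default_rng(seed)
    n = len(y)
    sens_b, spec_b = [], []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        yb, pb = y[idx], p[idx]
        if yb.min() == yb.max():
            continue
        tb, _, sb, cb = _scan_youden(yb, pb)
        sens_b.append(sb)
        spec_b.append(cb)
    sens_ci = tuple(np.percentile(sens_b, [2.5, 97.5])) if sens_b else (np.nan, np.nan)
    spec_ci = tuple(np.percentile(spec_b, [2.5, 97.5])) if spec_b else (np.nan, np.nan)
    return OperatingPoint(threshold=float(t_star), youden_j=float(j),
                          sensitivity=sens, specificity=spec,
                          sens_ci=sens_ci, spec_ci=spec_ci)


@dataclass
class DeltaAucResult:
    delta: float
    ci: tuple
    p: float
    aucs: tuple  # (model A, model B)


def paired_delta_auc(y, p_a, p_b, B: int = 2000, seed: int = 0) -> DeltaAucResult:
    """Paired case-resampling bootstrap for ΔAUC = AUC_B − AUC_A.

    Both AUCs are recomputed on the same resample; the two-sided p-value is
    2·min(frac(Δ ≤ 0), frac(Δ ≥ 0)) with a +1 continuity correction in
    numerator and denominator, capped at 1.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    y = _check_binary(y)
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if len(p_a) != len(y) or len(p_b) != len(y):
        raise ValueError("prediction vectors must match the outcome vector")
    delta = auc(y, p_b) - auc(y, p_a)
    rng = np.random.default_rng(seed)
    n = len(y)
    deltas = []
    while len(deltas) < B:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        deltas.append(auc(yb, p_b[idx]) - auc(yb, p_a[idx]))
    deltas = np.asarray(deltas)
    ci = tuple(np.percentile(deltas, [2.5, 97.5]))
    p_le = (1 + np.sum(deltas <= 0)) / (B + 1)
    p_ge = (1 + np.sum(deltas >= 0)) / (B + 1)
    p = min(1.0, 2 * min(p_le, p_ge))
    return DeltaAucResult(delta=float(delta), ci=ci, p=float(p),
                          aucs=(auc(y, p_a), auc(y, p_b)))


@dataclass
class CalibrationResult:
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    bins: "object"  # reliability table (DataFrame)
    degenerate: bool = False


def calibration(y, p, n_bins: int = 10, clip: float = 1e-6) -> CalibrationResult:
    """Logistic recalibration intercept and slope plus a reliability table.

    slope: coefficient of logit(p̂) in a logistic refit of y on logit(p̂);
    intercept: intercept of a logistic refit with logit(p̂) as fixed offset.
    Perfectly calibrated predictions give slope 1, intercept 0.
    """
    import pandas as pd

    y = _check_binary(y)
    p = np.clip(np.asarray(p, dtype=float), clip, 1 - clip)
    lp = logit(p)
    if np.ptp(lp) == 0:
        return CalibrationResult(np.nan, np.nan, np.nan, np.nan, None, degenerate=True)
    X = sm.add_constant(lp)
    slope_fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    off_fit = sm.GLM(y, np.ones((len(y), 1)), offset=lp,
                     family=sm.families.Binomial()).fit()
    # equal-count reliability bins
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    which = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        m = which == b
        if m.any():
            rows.append({"bin": b, "n": int(m.sum()),
                         "p_mean": float(p[m].mean()),
                         "y_rate": float(y[m].mean())})
    return CalibrationResult(
        intercept=float(off_fit.params[0]),
        intercept_se=float(off_fit.bse[0]),
        slope=float(slope_fit.params[1]),
        slope_se=float(slope_fit.bse[1]),
        bins=pd.DataFrame(rows),
    )


@dataclass
class CutoffMapping:
    p_star: float
    crossings: list  # all biomarker values where the curve crosses p*
    selected: float | None  # smallest down-crossing (None if absent)
    ci: tuple
    n_boot: int
    n_failed: int
    no_crossing: bool


def _find_crossings(grid, fit, p_star):
    diff = fit - p_star
    crossings, down = [], []
    for i in range(len(grid) - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0:
            crossings.append(float(grid[i]))
            if i + 1 < len(diff) and diff[i + 1] < 0:
                down.append(float(grid[i]))
        elif a * b < 0:
            x = grid[i] + (grid[i + 1] - grid[i]) * (-a) / (b - a)
            crossings.append(float(x))
            if a > 0 > b:
                down.append(float(x))
    if diff[-1] == 0.0:
        crossings.append(float(grid[-1]))
    return crossings, down


def map_threshold_to_biomarker(y, x, p_star: float, spec=None, grid=None,
                               B: int = 2000, seed: int = 0, k: int = 4) -> CutoffMapping:
    """Invert a probability threshold to biomarker concentration(s).

    Fits the restricted-cubic-spline logistic dose–response on (y, x),
    finds all grid crossings of the fitted curve with ``p_star`` by linear
    interpolation, and selects the smallest value where the predicted
    probability falls from above to below ``p_star`` (risk decreasing with
    rising biomarker).  The CI is the percentile interval of that selected
    crossing over ``B`` case-resampled refit-and-invert replicates;
    replicates without a down-crossing are counted and excluded.
    """
    if not (0.0 < p_star < 1.0):
        raise ValueError("p_star must lie strictly inside (0, 1)")
    y = _check_binary(y)
    x = np.asarray(x, dtype=float)
    if spec is None:
        spec = place_knots(x, k=k)
    if grid is None:
        from .rcs_logistic import default_grid

        grid = default_grid(x)
    grid = np.asarray(grid, dtype=float)
    model = fit_rcs_logistic(y, x, spec)
    fit = model.predict_prob(grid)
    crossings, down = _find_crossings(grid, fit, p_star)
    selected = down[0] if down else None
    rng = np.random.default_rng(seed)
    n = len(y)
    boot_vals = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        yb, xb = y[idx], x[idx]
        try:
            spec_b = place_knots(xb, k=spec.k)
            mb = fit_rcs_logistic(yb, xb, spec_b)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        _, down_b = _find_crossings(grid, mb.predict_prob(grid), p_star)
        if down_b:
            boot_vals.append(down_b[0])
        else:
            n_failed += 1
    ci = tuple(np.percentile(boot_vals, [2.5, 97.5])) if boot_vals else (np.nan, np.nan)
    return CutoffMapping(
        p_star=float(p_star), crossings=crossings, selected=selected, ci=ci,
        n_boot=len(boot_vals), n_failed=n_failed, no_crossing=selected is None,
    )
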