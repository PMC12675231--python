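"""Robust linear modelling: OLS with HC3 sandwich inference, backward
elimination, collinearity diagnostics and the PCA subscale-replacement
sensitivity analysis.

p-values on HC3 standard errors use the t reference with n−p degrees of
freedom (small-sample convention).  Backward elimination drops the
largest-p predictor while that p exceeds the threshold strictly, so a
predictor sitting exactly at the threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "LinearModelFit",
    "EliminationTrace",
    "PCAResult",
    "fit_ols_hc3",
    "backward_eliminate",
    "vif",
    "pca_scores",
    "standardized_betas",
]


@dataclass
class LinearModelFit:
    outcome: str
    table: pd.DataFrame  # per-term: B, se, ci_lo, ci_hi, beta_std, p, vif
    r2: float
    adj_r2: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def predictors(self) -> list:
        return [t for t in self.table.index if t != "const"]


def _design(X: pd.DataFrame) -> pd.DataFrame:
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # identify columns involved in the deficiency via near-infinite VIF
        bad = []
        vals = Xc.drop(columns="const")
        if vals.shape[1] >= 2:
            for name, v in vif(vals).items():
                if not np.isfinite(v) or v > 1e10:
                    bad.append(name)
        raise ValueError(f"design matrix is rank deficient (collinear columns: {bad or 'unknown'})")
    return Xc


def fit_ols_hc3(y, X: pd.DataFrame, outcome: str = "y") -> LinearModelFit:
    """OLS point estimates with HC3 heteroskedasticity-robust inference.

    HC3: (XᵀX)⁻¹ Xᵀ diag(e_i²/(1−h_ii)²) X (XᵀX)⁻¹.  Confidence intervals
    and p-values use the t distribution with n−p df on the robust SEs.
    """
    y = np.asarray(y, dtype=float)
    Xc = _design(X)
    if len(y) <= Xc.shape[1]:
        raise ValueError("need n > number of parameters")
    res = sm.OLS(y, Xc).fit(cov_type="HC3", use_t=True)
    ci = res.conf_int()
    sd_y = y.std(ddof=1)
    betas = {}
    for name in Xc.columns:
        if name == "const":
            betas[name] = np.nan
        else:
            sd_x = Xc[name].std(ddof=1)
            betas[name] = res.params[name] * sd_x / sd_y if sd_y > 0 else np.nan
    vifs = vif(Xc.drop(columns="const")) if Xc.shape[1] > 2 else pd.Series(
        {c: 1.0 for c in Xc.columns if c != "const"}
    )
    table = pd.DataFrame(
        {
            "B": res.params,
            "se_hc3": res.bse,
            "ci_lo": ci[0],
            "ci_hi": ci[1],
            "beta_std": pd.Series(betas),
            "p": res.pvalues,
            "vif": pd.Series({c: vifs.get(c, np.nan) for c in Xc.columns}),
        }
    )
    return LinearModelFit(
        outcome=outcome,
        table=table,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n=int(res.nobs),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
    )


@dataclass
class EliminationTrace:
    steps: list  # (dropped predictor, its p at drop)
    final_predictors: list


def backward_eliminate(y, candidates: pd.DataFrame, threshold: float = 0.10,
                       outcome: str = "y"):
    """Backward elimination on HC3 p-values.

    Repeatedly drops the predictor with the largest p strictly above
    ``threshold`` and refits; the intercept is never dropped.  May return
    an intercept-only fit when every candidate is uninformative.
    """
    if candidates.shape[1] == 0:
        raise ValueError("candidate set must be nonempty")
    cols = list(candidates.columns)
    steps = []
    while cols:
        fit = fit_ols_hc3(y, candidates[cols], outcome=outcome)
        pvals = fit.table["p"].drop("const")
        worst = pvals.idxmax()
        if pvals[worst] > threshold:
            steps.append((worst, float(pvals[worst])))
            cols.remove(worst)
        else:
            return fit, EliminationTrace(steps=steps, final_predictors=cols)
    # intercept-only model
    fit = _intercept_only(y, outcome)
    return fit, EliminationTrace(steps=steps, final_predictors=[])


def _intercept_only(y, outcome: str) -> LinearModelFit:
    y = np.asarray(y, dtype=float)
    n = len(y)
    mean = y.mean()
    se = y.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    table = pd.DataFrame(
        {
            "B": [mean], "se_hc3": [se], "ci_lo": [mean - tcrit * se],
            "ci_hi": [mean + tcrit * se], "beta_std": [np.nan],
            "p": [2 * stats.t.sf(abs(mean / se), n - 1) if se > 0 else np.nan],
            "vif": [np.nan],
        },
        index=["const"],
    )
    return LinearModelFit(outcome=outcome, table=table, r2=0.0, adj_r2=0.0, n=n,
                          residuals=y - mean, fitted=np.full(n, mean))


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1/(1−R_j²); inf for perfect collinearity."""
    X = design.astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col), has_constant="add")
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables × components
    explained_variance_ratio: np.ndarray
    scores: np.ndarray
    flipped: np.ndarray  # per-component sign-orientation flag


def pca_scores(table: pd.DataFrame, variables, k: int = 1) -> PCAResult:
    """PCA on internally standardized variables with a deterministic sign rule.

    Each component is oriented so its score correlates non-negatively with
    the mean of the standardized input variables.
    """
    variables = list(variables)
    if k > len(variables):
        raise ValueError("k cannot exceed the number of variables")
    Z = table[variables].astype(float)
    Z = (Z - Z.mean()) / Z.std(ddof=1)
    Z = Z.to_numpy()
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()
    mean_z = Z.mean(axis=1)
    flipped = np.zeros(k, dtype=bool)
    for j in range(k):
        c = np.corrcoef(scores[:, j], mean_z)[0, 1]
        if np.isfinite(c) and c < 0:
            scores[:, j] *= -1
            loadings[:, j] *= -1
            flipped[j] = True
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=variables,
                              columns=[f"PC{i+1}" for i in range(k)]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
        flipped=flipped,
    )


def standardized_betas(fit: LinearModelFit) -> pd.Series:
    """Standardized coefficients β_j = B_j · SD(x_j)/SD(y) from a fit table."""
    return fit.table["beta_std"].drop("const")
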