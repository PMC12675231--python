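"""Leakage-free nested (outer 5 × inner 5) cross-validation.

Two model families are evaluated on out-of-fold (OOF) predictions of the
binary outcome (global EDE-Q ≥ 2.5):

* ``oxytocin_only`` — unpenalized logistic regression on a restricted
  cubic spline of plasma oxytocin;
* ``combined`` — elastic-net logistic regression on the oxytocin spline
  plus leptin, BMI, waist circumference, HSI, VAI and the first principal
  component of the four EDE-Q subscales.

Every data-dependent preprocessing step — median imputation, spline knot
placement, PCA loadings, centering/scaling — is learned on the outer
training split only and applied to the held-out fold with the stored
constants, so corrupting outer-test rows can never change a fitted fold
(the property the test suite asserts bitwise).  Elastic-net (λ, α) are
chosen by mean inner-fold AUC and the model is refit on the full outer
training split at the selected pair.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import elastic_net as enet
from .evaluation import auc
from .rcs_logistic import SplineSpec, fit_rcs_logistic, place_knots, rcs_basis

__all__ = [
    "FoldPlan",
    "ModelSpec",
    "PreprocessorState",
    "make_fold_plan",
    "fit_fold",
    "collect_oof",
    "oxytocin_only_spec",
    "combined_spec",
    "EDEQ_SUBSCALES",
]

EDEQ_SUBSCALES = (
    "edeq_restraint",
    "edeq_eating_concern",
    "edeq_weight_concern",
    "edeq_shape_concern",
)


@dataclass
class FoldPlan:
    """Outer fold id per participant and inner splits within each outer-train set."""

    outer: np.ndarray  # outer fold id per row
    inner: dict  # outer fold id -> list of (train_idx, val_idx), absolute row positions
    outer_k: int
    inner_k: int
    seed: int

    def digest(self) -> str:
        h = hashlib.sha256(self.outer.tobytes())
        for f in sorted(self.inner):
            for tr, va in self.inner[f]:
                h.update(np.asarray(tr).tobytes())
                h.update(np.asarray(va).tobytes())
        return h.hexdigest()


def make_fold_plan(outcomes, outer_k: int = 5, inner_k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified outer folds; stratified inner folds inside each outer-train set."""
    y = np.asarray(outcomes, dtype=int)
    n = len(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < outer_k:
        raise ValueError(
            f"smallest class ({counts.min()}) must have at least outer_k={outer_k} members"
        )
    outer = np.empty(n, dtype=int)
    skf = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed % (2**32))
    inner = {}
    for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
        outer[test_idx] = f
        y_train = y[train_idx]
        if np.bincount(y_train, minlength=2).min() < inner_k:
            raise ValueError("smallest class too small for the inner split")
        inner_skf = StratifiedKFold(
            n_splits=inner_k, shuffle=True, random_state=(seed * 31 + f + 1) % (2**32)
        )
        inner[f] = [
            (train_idx[tr], train_idx[va])
            for tr, va in inner_skf.split(np.zeros(len(train_idx)), y_train)
        ]
    return FoldPlan(outer=outer, inner=inner, outer_k=outer_k, inner_k=inner_k, seed=seed)


@dataclass
class ModelSpec:
    """Which predictors enter a model and how its hyperparameters are tuned."""

    model_id: str
    linear_predictors: tuple = ()
    spline_variable: str = "oxytocin"
    spline_k: int = 4
    use_pca_component: bool = True
    pca_variables: tuple = EDEQ_SUBSCALES
    penalized: bool = True
    alphas: tuple = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-4

    @property
    def raw_columns(self) -> tuple:
        cols = (self.spline_variable,) + tuple(self.linear_predictors)
        if self.penalized and self.use_pca_component:
            cols = cols + tuple(self.pca_variables)
        return cols


def oxytocin_only_spec(spline_k: int = 4) -> ModelSpec:
    return ModelSpec(model_id="oxytocin_only", penalized=False,
                     use_pca_component=False, spline_k=spline_k)


def combined_spec(drop_edeq_component: bool = False, spline_k: int = 4,
                  alphas=None, n_lambda: int = 50) -> ModelSpec:
    """The multivariable elastic-net model.

    ``drop_edeq_component`` removes the EDE-Q PCA predictor, which is
    derived from the same instrument as the outcome (kept by default to
    mirror the published model; the flag makes the circularity avoidable).
    """
    kwargs = {}
    if alphas is not None:
        kwargs["alphas"] = tuple(alphas)
    return ModelSpec(
        model_id="combined",
        linear_predictors=("leptin", "bmi", "wc", "hsi", "vai"),
        use_pca_component=not drop_edeq_component,
        penalized=True,
        spline_k=spline_k,
        n_lambda=n_lambda,
        **kwargs,
    )


@dataclass
class PreprocessorState:
    """Constants learned on an outer-train split only."""

    medians: pd.Series  # imputation values per raw column
    spline_spec: SplineSpec
    pca_mean: np.ndarray | None
    pca_sd: np.ndarray | None
    pca_loading: np.ndarray | None
    feature_names: tuple
    center: np.ndarray
    scale: np.ndarray

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.medians.to_numpy().tobytes())
        h.update(np.asarray(self.spline_spec.knots).tobytes())
        for arr in (self.pca_mean, self.pca_sd, self.pca_loading, self.center, self.scale):
            if arr is not None:
                h.update(np.asarray(arr).tobytes())
        return h.hexdigest()


def _impute(df: pd.DataFrame, cols, medians: pd.Series) -> pd.DataFrame:
    out = df[list(cols)].astype(float).copy()
    for c in cols:
        out[c] = out[c].fillna(medians[c])
    return out


def fit_preprocessor(train_df: pd.DataFrame, spec: ModelSpec) -> PreprocessorState:
    cols = spec.raw_columns
    medians = train_df[list(cols)].astype(float).median()
    imputed = _impute(train_df, cols, medians)
    spline_spec = place_knots(imputed[spec.spline_variable].to_numpy(), k=spec.spline_k)
    pca_mean = pca_sd = pca_loading = None
    if spec.penalized and spec.use_pca_component:
        Z = imputed[list(spec.pca_variables)].to_numpy()
        pca_mean = Z.mean(axis=0)
        pca_sd = Z.std(axis=0, ddof=1)
        pca_sd = np.where(pca_sd > 0, pca_sd, 1.0)
        Zs = (Z - pca_mean) / pca_sd
        # leading right singular vector, oriented toward the subscale mean
        _, _, vt = np.linalg.svd(Zs, full_matrices=False)
        loading = vt[0]
        score = Zs @ loading
        if np.corrcoef(score, Zs.mean(axis=1))[0, 1] < 0:
            loading = -loading
        pca_loading = loading
    X, names = _raw_features(imputed, spec, spline_spec, pca_mean, pca_sd, pca_loading)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    return PreprocessorState(
        medians=medians, spline_spec=spline_spec, pca_mean=pca_mean,
        pca_sd=pca_sd, pca_loading=pca_loading, feature_names=tuple(names),
        center=center, scale=scale,
    )


def _raw_features(imputed: pd.DataFrame, spec: ModelSpec, spline_spec, pca_mean,
                  pca_sd, pca_loading):
    basis = rcs_basis(imputed[spec.spline_variable].to_numpy(), spline_spec)
    names = [f"{spec.spline_variable}_rcs{i}" for i in range(basis.shape[1])]
    blocks = [basis]
    for c in spec.linear_predictors:
        blocks.append(imputed[c].to_numpy()[:, None])
        names.append(c)
    if pca_loading is not None:
        Zs = (imputed[list(spec.pca_variables)].to_numpy() - pca_mean) / pca_sd
        blocks.append((Zs @ pca_loading)[:, None])
        names.append("edeq_pc1")
    return np.column_stack(blocks), names


def transform(df: pd.DataFrame, state: PreprocessorState, spec: ModelSpec) -> np.ndarray:
    """Apply stored preprocessing constants to any data; never refits."""
    imputed = _impute(df, spec.raw_columns, state.medians)
    X, _ = _raw_features(imputed, spec, state.spline_spec, state.pca_mean,
                         state.pca_sd, state.pca_loading)
    return (X - state.center) / state.scale


@dataclass
class FittedFold:
    spec: ModelSpec
    state: PreprocessorState
    model: object  # RcsLogisticModel or EnetFit
    chosen: tuple | None = None  # (lambda, alpha) for penalized fits
    inner_auc: float | None = None

    def predict_prob(self, df: pd.DataFrame) -> np.ndarray:
        if self.spec.penalized:
            return self.model.predict_prob(transform(df, self.state, self.spec))
        imputed = _impute(df, self.spec.raw_columns, self.state.medians)
        return self.model.predict_prob(imputed[self.spec.spline_variable].to_numpy())


def fit_fold(train_df: pd.DataFrame, y_train, spec: ModelSpec,
             inner_splits=None, outcome_col: str = "outcome") -> FittedFold:
    """Fit one outer fold: learn preprocessing, tune (λ, α) on the inner
    folds when penalized, refit on the full outer-train split."""
    y_train = np.asarray(y_train, dtype=float)
    state = fit_preprocessor(train_df, spec)
    if not spec.penalized:
        imputed = _impute(train_df, spec.raw_columns, state.medians)
        model = fit_rcs_logistic(y_train, imputed[spec.spline_variable].to_numpy(),
                                 state.spline_spec)
        return FittedFold(spec=spec, state=state, model=model)
    X = transform(train_df, state, spec)
    if inner_splits is None:
        raise ValueError("penalized models need inner splits for tuning")
    lam_grids = {a: enet.lambda_grid(X, y_train, a, spec.n_lambda, spec.lambda_min_ratio)
                 for a in spec.alphas}
    # mean inner-fold AUC per (alpha, lambda)
    scores = {a: np.zeros(spec.n_lambda) for a in spec.alphas}
    counts = {a: np.zeros(spec.n_lambda) for a in spec.alphas}
    pos = {idx: i for i, idx in enumerate(train_df.index)}
    for tr_abs, va_abs in inner_splits:
        tr = np.array([pos[i] for i in tr_abs])
        va = np.array([pos[i] for i in va_abs])
        y_tr, y_va = y_train[tr], y_train[va]
        if y_tr.min() == y_tr.max() or y_va.min() == y_va.max():
            raise ValueError("an inner split contains a single outcome class")
        for a in spec.alphas:
            fits = enet.enet_path(X[tr], y_tr, a, lam_grids[a],
                                  kkt_tol=1e-7, tol=1e-9)
            for j, fit in enumerate(fits):
                p_va = fit.predict_prob(X[va])
                scores[a][j] += auc(y_va, p_va)
                counts[a][j] += 1
    best = None  # (mean_auc, alpha, lam_index)
    for a in spec.alphas:
        mean_auc = scores[a] / counts[a]
        for j in range(spec.n_lambda):
            cand = (mean_auc[j], a, j)
            if best is None or cand[0] > best[0] + 1e-12:
                best = cand
    _, alpha_star, j_star = best
    lam_star = float(np.sort(lam_grids[alpha_star])[::-1][j_star])
    # warm-start down the path to the selected λ for the final refit
    path = enet.enet_path(X, y_train, alpha_star,
                          np.sort(lam_grids[alpha_star])[::-1][: j_star + 1],
                          kkt_tol=1e-8, tol=1e-10)
    model = path[-1]
    return FittedFold(spec=spec, state=state, model=model,
                      chosen=(lam_star, alpha_star), inner_auc=float(best[0]))


def collect_oof(df: pd.DataFrame, specs, plan: FoldPlan,
                outcome_col: str = "outcome"):
    """Out-of-fold predictions for each model spec.

    Returns ``(oof, folds)``: a DataFrame with one row per participant
    (id, fold, y, one probability column per model) and the per-fold
    fitted objects for inspection.
    """
    df = df.reset_index(drop=True)  # inner splits address absolute row positions
    y = df[outcome_col].to_numpy(dtype=float)
    oof = pd.DataFrame({
        "id": df["id"].to_numpy() if "id" in df else np.arange(len(df)),
        "fold": plan.outer,
        "y": y.astype(int),
    })
    folds = {}
    for spec in specs:
        preds = np.full(len(df), np.nan)
        folds[spec.model_id] = {}
        for f in range(plan.outer_k):
            test_mask = plan.outer == f
            train_idx = np.flatnonzero(~test_mask)
            fitted = fit_fold(df.iloc[train_idx], y[train_idx], spec,
                              inner_splits=plan.inner[f] if spec.penalized else None,
                              outcome_col=outcome_col)
            preds[test_mask] = fitted.predict_prob(df.iloc[np.flatnonzero(test_mask)])
            folds[spec.model_id][f] = fitted
        assert not np.any(np.isnan(preds))
        oof[f"p_{spec.model_id}"] = preds
    return oof, folds
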