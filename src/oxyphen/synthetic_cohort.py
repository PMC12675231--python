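"""Seeded synthetic cohort generator for the oxytocin/leptin disordered-eating
analyses, plus known-truth scenarios for recovery testing.

The generator draws a metabolic obesity phenotype first (4-component
mixture), then biometrics conditional on the phenotype: hormones and
right-skewed labs are log-normal with phenotype-specific locations
(oxytocin decreasing and leptin increasing from MHNW to MUO), BMI is a
truncated normal inside each phenotype's BMI class.  Disordered-eating
severity is a latent linear combination of standardized log-leptin (+)
and log-oxytocin (−) plus Gaussian noise; the global EDE-Q score is a
logistic squashing of that latent severity onto the 0–6 scale, and the
twelve questionnaire subscales are the global score plus independent
noise re-clipped to their instrument ranges (EDE-Q and EBA-O 0–6,
DEBQ 1–5).

The default severity coefficients, noise SD and squashing constants were
calibrated once against a large-n simulation so that the default cohort
reproduces the targeted rank correlations (≈ −0.73 oxytocin vs global
EDE-Q, ≈ +0.92 leptin vs global EDE-Q) and outcome prevalence
(P(global ≥ 2.5) ≈ 0.64), and then frozen.

Leptin is generated in ng/mL throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .group_comparisons import normality_gate
from .metabolic_indices import PHENOTYPES

__all__ = [
    "GeneratorConfig",
    "TrueModel",
    "ConfigError",
    "generate_cohort",
    "generate_known_truth",
    "summarize_cohort",
    "save_cohort",
    "save_config",
    "SUBSCALE_COLUMNS",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20250320

#: 12 questionnaire subscales + the global EDE-Q score
SUBSCALE_COLUMNS = (
    "edeq_restraint",
    "edeq_eating_concern",
    "edeq_weight_concern",
    "edeq_shape_concern",
    "debq_emotional",
    "debq_external",
    "debq_restrained",
    "ebao_binge",
    "ebao_food_addiction",
    "ebao_hyperphagia",
    "ebao_night",
    "ebao_sweet",
)

_DEBQ = tuple(c for c in SUBSCALE_COLUMNS if c.startswith("debq"))


class ConfigError(ValueError):
    """A generator configuration field is invalid."""


def _lognorm(mus, sigma):
    return {ph: (float(mu), float(sigma)) for ph, mu in zip(PHENOTYPES, mus)}


def _truncnorm(params):
    return {ph: tuple(float(v) for v in p) for ph, p in zip(PHENOTYPES, params)}


def _default_lognormal_params():
    # per-phenotype (mu, sigma) of the natural log, order MHNW, MUNW, MUOW, MUO
    return {
        "oxytocin": _lognorm((4.85, 4.35, 4.05, 3.30), 0.50),
        "leptin": _lognorm((1.80, 2.40, 2.90, 3.60), 0.35),
        "insulin": _lognorm((1.70, 2.60, 2.60, 2.95), 0.40),
        "glucose": _lognorm((1.577, 1.650, 1.650, 1.720), 0.08),
        "alt": _lognorm((2.77, 3.00, 3.10, 3.40), 0.35),
        "ast": _lognorm((3.00, 3.00, 3.05, 3.10), 0.30),
        "ggt": _lognorm((3.00, 3.40, 3.50, 3.70), 0.50),
        "tg": _lognorm((-0.22, 0.10, 0.20, 0.45), 0.35),
        "hdl": _lognorm((0.37, 0.20, 0.15, 0.095), 0.15),
        "tc": _lognorm((1.50, 1.57, 1.57, 1.62), 0.18),
        "ldl": _lognorm((0.70, 0.79, 0.80, 0.85), 0.25),
    }


def _default_truncnorm_params():
    # per-phenotype (mean, sd, lo, hi)
    return {
        "bmi": _truncnorm([(22.5, 1.5, 18.5, 24.9), (23.5, 1.2, 18.5, 24.9),
                           (27.5, 1.4, 25.0, 29.9), (35.5, 4.0, 30.0, 55.0)]),
        "wc": _truncnorm([(74, 6, 55, 180), (80, 6, 55, 180),
                          (90, 6, 55, 180), (110, 12, 55, 180)]),
        "hba1c": _truncnorm([(4.9, 0.30, 3.5, 9.0), (5.1, 0.35, 3.5, 9.0),
                             (5.1, 0.35, 3.5, 9.0), (5.4, 0.40, 3.5, 9.0)]),
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator (defaults are frozen
    calibration results; see the package methods note)."""

    n: int = 99
    seed: int = DEFAULT_SEED
    phenotype_probs: tuple = (18 / 99, 12 / 99, 13 / 99, 56 / 99)
    female_prob: float = 0.768
    age_mean: float = 38.94
    age_sd: float = 10.40
    height_mean: float = 164.0
    height_sd: float = 6.0
    lognormal_params: dict = field(default_factory=_default_lognormal_params)
    truncnorm_params: dict = field(default_factory=_default_truncnorm_params)
    #: within-phenotype correlation of log-oxytocin and log-leptin
    hormone_corr: float = -0.20
    #: coefficients of standardized log-leptin (+) and log-oxytocin (−)
    severity_coefs: dict = field(
        default_factory=lambda: {"log_leptin": 1.0, "log_oxytocin": -0.16}
    )
    noise_sd: float = 0.42
    #: logistic squashing of latent severity onto the 0–6 EDE-Q scale
    squash_rate: float = 0.60
    squash_center: float = 0.2565
    subscale_noise_sd: float = 0.50
    outcome_cutoff: float = 2.5

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be at least 1")
        probs = np.asarray(self.phenotype_probs, dtype=float)
        if probs.size != 4 or np.any(probs < 0):
            raise ConfigError("phenotype_probs must be 4 nonnegative values")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigError("phenotype_probs must sum to 1 (±1e-12)")
        if not (0.0 <= self.female_prob <= 1.0):
            raise ConfigError("female_prob must lie in [0, 1]")
        for scale_name in ("age_sd", "height_sd", "noise_sd", "squash_rate",
                           "subscale_noise_sd"):
            if getattr(self, scale_name) <= 0:
                raise ConfigError(f"{scale_name} must be positive")
        for var, per_ph in self.lognormal_params.items():
            for ph, (_, sigma) in per_ph.items():
                if sigma <= 0:
                    raise ConfigError(f"lognormal_params[{var!r}][{ph!r}] sigma must be positive")
        for var, per_ph in self.truncnorm_params.items():
            for ph, (_, sd, lo, hi) in per_ph.items():
                if sd <= 0 or hi <= lo:
                    raise ConfigError(f"truncnorm_params[{var!r}][{ph!r}] is invalid")
        if not (-1.0 < self.hormone_corr < 1.0):
            raise ConfigError("hormone_corr must lie in (−1, 1)")
        if not (0.0 < self.outcome_cutoff < 6.0):
            raise ConfigError("outcome_cutoff must lie inside the 0–6 scale")


def _draw_truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a seeded synthetic cohort table (one row per participant)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    probs = np.asarray(config.phenotype_probs, dtype=float)
    probs = probs / probs.sum()
    ph_idx = rng.choice(4, size=n, p=probs)
    phenotype = np.asarray(PHENOTYPES, dtype=object)[ph_idx]
    female = rng.random(n) < config.female_prob
    age = _draw_truncnorm(rng, config.age_mean, config.age_sd, 18, 65, n)
    height = _draw_truncnorm(rng, config.height_mean, config.height_sd, 145, 195, n)

    def per_ph_truncnorm(var):
        out = np.empty(n)
        for i, ph in enumerate(PHENOTYPES):
            m = ph_idx == i
            if m.any():
                mean, sd, lo, hi = config.truncnorm_params[var][ph]
                out[m] = _draw_truncnorm(rng, mean, sd, lo, hi, int(m.sum()))
        return out

    bmi = per_ph_truncnorm("bmi")
    wc = per_ph_truncnorm("wc")
    hba1c = per_ph_truncnorm("hba1c")
    weight = bmi * (height / 100.0) ** 2
    hc = np.clip(wc / 0.83 + rng.normal(0, 4, n), 60, 200)

    # hormones: correlated bivariate log-normal within phenotype
    rho = config.hormone_corr
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    log_oxy = np.empty(n)
    log_lep = np.empty(n)
    for i, ph in enumerate(PHENOTYPES):
        m = ph_idx == i
        mu_o, sd_o = config.lognormal_params["oxytocin"][ph]
        mu_l, sd_l = config.lognormal_params["leptin"][ph]
        log_oxy[m] = mu_o + sd_o * z[m, 0]
        log_lep[m] = mu_l + sd_l * z[m, 1]

    labs = {}
    for var in ("insulin", "glucose", "alt", "ast", "ggt", "tg", "hdl", "tc", "ldl"):
        vals = np.empty(n)
        draws = rng.normal(0, 1, n)
        for i, ph in enumerate(PHENOTYPES):
            m = ph_idx == i
            mu, sd = config.lognormal_params[var][ph]
            vals[m] = np.exp(mu + sd * draws[m])
        labs[var] = vals

    # latent disordered-eating severity → global EDE-Q on the 0–6 scale
    z_lep = (log_lep - log_lep.mean()) / log_lep.std(ddof=0)
    z_oxy = (log_oxy - log_oxy.mean()) / log_oxy.std(ddof=0)
    severity = (
        config.severity_coefs["log_leptin"] * z_lep
        + config.severity_coefs["log_oxytocin"] * z_oxy
        + rng.normal(0, config.noise_sd, n)
    )
    edeq_global = 6.0 * expit(config.squash_rate * (severity - config.squash_center))

    data = {
        "id": np.arange(1, n + 1),
        "phenotype": phenotype,
        "sex": np.where(female, "female", "male"),
        "age": age,
        "height": height,
        "weight": weight,
        "bmi": bmi,
        "wc": wc,
        "hc": hc,
        "glucose": labs["glucose"],
        "insulin": labs["insulin"],
        "alt": labs["alt"],
        "ast": labs["ast"],
        "ggt": labs["ggt"],
        "tc": labs["tc"],
        "hdl": labs["hdl"],
        "ldl": labs["ldl"],
        "tg": labs["tg"],
        "hba1c": hba1c,
        "oxytocin": np.exp(log_oxy),
        "leptin": np.exp(log_lep),
        "edeq_global": edeq_global,
    }
    for col in SUBSCALE_COLUMNS:
        noise = rng.normal(0, config.subscale_noise_sd, n)
        if col in _DEBQ:
            data[col] = np.clip(1.0 + edeq_global * (4.0 / 6.0) + noise, 1.0, 5.0)
        else:
            data[col] = np.clip(edeq_global + noise, 0.0, 6.0)
    df = pd.DataFrame(data)
    df["outcome"] = (df["edeq_global"] >= config.outcome_cutoff).astype(int)
    return df


@dataclass
class TrueModel:
    """Ground-truth event-probability model for recovery testing.

    kind "logistic":        logit p(x) = b0 + b1·x (monotone)
    kind "ushaped":         logit p(x) = a + b·(x − v)², b > 0
    ``true_cutoff`` is the biomarker value where p crosses
    ``threshold_prob`` from above (None for flat/crossing-free truths).
    """

    kind: str
    params: dict
    threshold_prob: float | None = None
    true_cutoff: float | None = None

    def prob(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "logistic":
            eta = self.params["b0"] + self.params["b1"] * x
        elif self.kind == "ushaped":
            eta = self.params["a"] + self.params["b"] * (x - self.params["v"]) ** 2
        else:
            raise ValueError(f"unknown truth kind {self.kind!r}")
        return expit(eta)

    @classmethod
    def flat(cls, p: float = 0.5) -> "TrueModel":
        return cls(kind="logistic", params={"b0": float(logit(p)), "b1": 0.0})

    @classmethod
    def monotone_decreasing(cls, cutoff: float = 90.0, prob_at_cutoff: float = 0.69,
                            slope: float = -0.04) -> "TrueModel":
        """Decreasing logistic truth passing through (cutoff, prob_at_cutoff)."""
        if slope >= 0:
            raise ValueError("slope must be negative for a decreasing truth")
        b0 = float(logit(prob_at_cutoff) - slope * cutoff)
        return cls(kind="logistic", params={"b0": b0, "b1": float(slope)},
                   threshold_prob=float(prob_at_cutoff), true_cutoff=float(cutoff))


def generate_known_truth(config: GeneratorConfig, true_model: TrueModel):
    """Cohort whose binary outcome is drawn from a known probability law.

    The questionnaire-derived outcome is replaced by a Bernoulli draw of
    ``true_model.prob(oxytocin)``; the truth object is returned untouched.
    """
    df = generate_cohort(config)
    x = df["oxytocin"].to_numpy()
    if true_model.true_cutoff is not None and not (
        x.min() < true_model.true_cutoff < x.max()
    ):
        raise ValueError(
            f"true cutoff {true_model.true_cutoff} lies outside the generated "
            f"biomarker support [{x.min():.1f}, {x.max():.1f}]"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    df = df.copy()
    df["outcome"] = (rng.random(len(df)) < true_model.prob(x)).astype(int)
    return df, true_model


def summarize_cohort(table: pd.DataFrame, alpha: float = 0.05,
                     max_shapiro_n: int = 5000) -> pd.DataFrame:
    """Table-1-style descriptives: mean ± SD or median (IQR) by normality gate.

    Quantiles use linear interpolation (Hyndman–Fan type 7).  Columns with
    more than ``max_shapiro_n`` values are gated on a deterministic
    subsample.  All-missing columns are flagged, not summarized.
    """
    rows = []
    numeric = table.select_dtypes(include=[np.number])
    for col in numeric.columns:
        if col == "id":
            continue
        v = numeric[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            rows.append({"variable": col, "n": 0, "flag": "all-missing"})
            continue
        if v.size < 3:
            rows.append({"variable": col, "n": int(v.size), "flag": "too-few"})
            continue
        gate_sample = v if v.size <= max_shapiro_n else v[
            np.linspace(0, v.size - 1, max_shapiro_n).astype(int)
        ]
        gate = normality_gate(gate_sample, alpha=alpha)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        display = (
            f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
            if gate.is_normal
            else f"{med:.2f} ({q1:.2f}–{q3:.2f})"
        )
        rows.append(
            {
                "variable": col, "n": int(v.size), "mean": v.mean(),
                "sd": v.std(ddof=1), "median": med, "q1": q1, "q3": q3,
                "shapiro_p": gate.p, "is_normal": gate.is_normal,
                "display": display, "flag": "degenerate" if gate.degenerate else "",
            }
        )
    return pd.DataFrame(rows)


def save_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def save_config(config: GeneratorConfig, path) -> None:
    """Write the generator configuration as JSON (or YAML by extension)."""
    payload = dataclasses.asdict(config)
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
    else:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=list)
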