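"""Derived metabolic indices and metabolic obesity phenotyping.

All indices operate on SI-style clinical units: glucose, lipids in mmol/L,
insulin in μU/mL, transaminases in U/L, BMI in kg/m², waist circumference
in cm.  The four metabolic obesity phenotypes are

* MHNW — metabolically healthy, normal weight
* MUNW — metabolically unhealthy, normal weight
* MUOW — metabolically unhealthy, overweight
* MUO  — metabolically unhealthy, obese

Metabolic health is defined biochemically (insulin resistance or hepatic
steatosis risk) and is therefore independent of the BMI class; metabolically
healthy participants above the normal-weight range fall outside the
four-phenotype scheme and are labelled :data:`UNCLASSIFIED`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "homa_ir",
    "hsi",
    "vai",
    "atherogenic_index",
    "classify_phenotype",
    "add_indices",
    "PHENOTYPES",
    "UNCLASSIFIED",
    "HOMA_IR_CUTOFF",
    "HSI_CUTOFF",
]

PHENOTYPES = ("MHNW", "MUNW", "MUOW", "MUO")
UNCLASSIFIED = "unclassified"

#: insulin-resistance bound (conventional adult threshold)
HOMA_IR_CUTOFF = 2.5
#: hepatic-steatosis (NAFLD-risk) bound
HSI_CUTOFF = 36.0

_BMI_NORMAL = (18.5, 25.0)
_BMI_OVERWEIGHT = (25.0, 30.0)


class DomainError(ValueError):
    """An index was requested for physiologically impossible inputs."""


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise DomainError(f"{name} must be positive and finite, got {value!r}")


def homa_ir(glucose, insulin):
    """Homeostatic model assessment of insulin resistance.

    ``insulin [μU/mL] × glucose [mmol/L] / 22.5``
    """
    _check_positive(glucose=glucose, insulin=insulin)
    return np.asarray(insulin, dtype=float) * np.asarray(glucose, dtype=float) / 22.5


def hsi(alt, ast, bmi, female, diabetes=False):
    """Hepatic steatosis index: ``8·(ALT/AST) + BMI + 2·[female] + 2·[diabetes]``.

    Values at or above :data:`HSI_CUTOFF` flag NAFLD risk.
    """
    _check_positive(alt=alt, ast=ast, bmi=bmi)
    female = np.asarray(female, dtype=bool)
    diabetes = np.asarray(diabetes, dtype=bool)
    return (
        8.0 * np.asarray(alt, dtype=float) / np.asarray(ast, dtype=float)
        + np.asarray(bmi, dtype=float)
        + 2.0 * female
        + 2.0 * diabetes
    )


def vai(wc, bmi, tg, hdl, female):
    """Visceral adiposity index with sex-specific reference equations.

    males:   (WC / (39.68 + 1.88·BMI)) · (TG/1.03) · (1.31/HDL)
    females: (WC / (36.58 + 1.89·BMI)) · (TG/0.81) · (1.52/HDL)

    A metabolically "reference" individual of either sex scores 1.0.
    """
    _check_positive(wc=wc, bmi=bmi, tg=tg, hdl=hdl)
    wc = np.asarray(wc, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    tg = np.asarray(tg, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    female = np.asarray(female, dtype=bool)
    male_val = (wc / (39.68 + 1.88 * bmi)) * (tg / 1.03) * (1.31 / hdl)
    female_val = (wc / (36.58 + 1.89 * bmi)) * (tg / 0.81) * (1.52 / hdl)
    return np.where(female, female_val, male_val)


def atherogenic_index(tc, hdl):
    """Atherogenic index ``(TC − HDL) / HDL`` (non-HDL to HDL cholesterol ratio)."""
    _check_positive(tc=tc, hdl=hdl)
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    return (tc - hdl) / hdl


def classify_phenotype(bmi, homa, hsi_value):
    """Assign a metabolic obesity phenotype from BMI, HOMA-IR and HSI.

    Metabolically unhealthy ⇔ HOMA-IR ≥ 2.5 or HSI ≥ 36 (BMI-independent).
    BMI 18.5–24.9 → MHNW / MUNW; 25–29.9 → MUOW if unhealthy;
    ≥ 30 → MUO if unhealthy.  Metabolically healthy overweight/obese
    participants fall outside the four-group scheme and are returned as
    :data:`UNCLASSIFIED`.

    Accepts scalars or arrays; returns a string or an object array.
    """
    bmi_arr = np.atleast_1d(np.asarray(bmi, dtype=float))
    homa_arr = np.atleast_1d(np.asarray(homa, dtype=float))
    hsi_arr = np.atleast_1d(np.asarray(hsi_value, dtype=float))
    if np.any(bmi_arr < _BMI_NORMAL[0]):
        raise DomainError("BMI below 18.5 kg/m² is outside cohort eligibility")
    unhealthy = (homa_arr >= HOMA_IR_CUTOFF) | (hsi_arr >= HSI_CUTOFF)
    labels = np.empty(bmi_arr.shape, dtype=object)
    normal = bmi_arr < _BMI_NORMAL[1]
    overweight = (bmi_arr >= _BMI_OVERWEIGHT[0]) & (bmi_arr < _BMI_OVERWEIGHT[1])
    obese = bmi_arr >= _BMI_OVERWEIGHT[1]
    labels[normal & ~unhealthy] = "MHNW"
    labels[normal & unhealthy] = "MUNW"
    labels[overweight & unhealthy] = "MUOW"
    labels[obese & unhealthy] = "MUO"
    labels[(overweight | obese) & ~unhealthy] = UNCLASSIFIED
    if np.isscalar(bmi) or np.asarray(bmi).ndim == 0:
        return labels.item()
    return labels


def add_indices(df: pd.DataFrame) -> pd.DataFrame:
    """Append index and classified-phenotype columns to a cohort table.

    Requires columns ``glucose, insulin, alt, ast, bmi, wc, tg, hdl, tc, sex``.
    Adds ``homa_ir, hsi, vai, ai, phenotype_classified``.
    """
    out = df.copy()
    female = out["sex"].astype(str).str.lower().eq("female").to_numpy()
    out["homa_ir"] = homa_ir(out["glucose"].to_numpy(), out["insulin"].to_numpy())
    out["hsi"] = hsi(out["alt"].to_numpy(), out["ast"].to_numpy(), out["bmi"].to_numpy(), female)
    out["vai"] = vai(
        out["wc"].to_numpy(), out["bmi"].to_numpy(), out["tg"].to_numpy(), out["hdl"].to_numpy(), female
    )
    out["ai"] = atherogenic_index(out["tc"].to_numpy(), out["hdl"].to_numpy())
    out["phenotype_classified"] = classify_phenotype(
        out["bmi"].to_numpy(), out["homa_ir"].to_numpy(), out["hsi"].to_numpy()
    )
    return out
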