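"""Decision-curve analysis: net benefit across threshold probabilities.

Net benefit at threshold probability p_t for a rule that calls positives
when p̂ ≥ p_t is

    NB(p_t) = TP/n − (FP/n) · p_t/(1−p_t)

"treat all" has NB = π − (1−π)·p_t/(1−p_t) (π = prevalence) and
"treat none" has NB ≡ 0; a useful model should sit above both in the
clinically relevant threshold range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["net_benefit", "default_thresholds"]


def default_thresholds(lo: float = 0.05, hi: float = 0.95, step: float = 0.01) -> np.ndarray:
    return np.round(np.arange(lo, hi + step / 2, step), 10)


def net_benefit(y, predictions: dict, thresholds=None) -> pd.DataFrame:
    """Net-benefit table for one or more models plus the two references.

    ``predictions`` maps model name → predicted probability vector.
    Returns one row per threshold with columns ``threshold``,
    ``treat_all``, ``treat_none``, one column per model, and the sample
    prevalence in ``df.attrs["prevalence"]``.
    """
    y = np.asarray(y, dtype=float)
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    pi = float(y.mean())
    odds = thresholds / (1 - thresholds)
    rows = {"threshold": thresholds,
            "treat_all": pi - (1 - pi) * odds,
            "treat_none": np.zeros_like(thresholds)}
    for name, p in predictions.items():
        p = np.asarray(p, dtype=float)
        if len(p) != n:
            raise ValueError(f"prediction vector for {name!r} has wrong length")
        nb = np.empty_like(thresholds)
        for i, t in enumerate(thresholds):
            pred = p >= t
            tp = np.sum(pred & (y == 1))
            fp = np.sum(pred & (y == 0))
            nb[i] = tp / n - (fp / n) * odds[i]
        rows[name] = nb
    out = pd.DataFrame(rows)
    out.attrs["prevalence"] = pi
    return out
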