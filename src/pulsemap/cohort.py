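"""Cohort-level summaries of per-eye results.

Per-eye outputs (AU-ROC, ideal threshold, critical amplitude,
illumination SD, movement index) are summarised the way the clinical
validation cohort was reported: AU-ROC via a ``log(1 - AUC)`` transform,
right-skewed positive quantities via medians with a back-transformed
log-scale t-interval.  The 26-eye reference cohort from the clinical
validation study ships with the package so the summaries are testable
offline (``load_reference_cohort``).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "transform_auc",
    "median_and_log_ci",
    "summarize_eyes",
    "load_reference_cohort",
]

EYE_COLUMNS = [
    "eye", "age", "side", "auc", "ideal_threshold",
    "critical_amplitude", "illum_sd", "tot_movt",
]


def load_reference_cohort() -> pd.DataFrame:
    """Per-eye summary measurements of the 26-eye clinical validation cohort."""
    with resources.files("pulsemap.data").joinpath("cohort_eyes.csv").open() as f:
        return pd.read_csv(f)


def transform_auc(auc) -> np.ndarray:
    """``ln(1 - AUC)`` — normalising transform for left-skewed AUC values.

    AUC of exactly 1 maps to ``-inf`` (flagged by the caller via isfinite).
    """
    auc = np.asarray(auc, dtype=float)
    if np.any(auc > 1):
        raise ValueError("AUC values cannot exceed 1")
    with np.errstate(divide="ignore"):
        return np.log1p(-auc)


def median_and_log_ci(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """Median with a back-transformed log-scale t-interval.

    The interval is ``exp(mean(ln v) +/- t_{n-1} * sd(ln v) / sqrt(n))``:
    a t-interval for the log-scale mean, back-transformed, so it is
    centred on the geometric mean and symmetric on the log scale.
    Requires n >= 3 strictly positive values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.any(v <= 0):
        raise ValueError("log-scale interval requires strictly positive values")
    lv = np.log(v)
    n = v.size
    half = stats.t.ppf(0.5 + confidence / 2, n - 1) * lv.std(ddof=1) / np.sqrt(n)
    lo, hi = np.exp(lv.mean() - half), np.exp(lv.mean() + half)
    return float(np.median(v)), float(lo), float(hi)


def summarize_eyes(records: pd.DataFrame, confidence: float = 0.95) -> dict:
    """Cohort summary of a per-eye results table (EYE_COLUMNS schema)."""
    missing = [c for c in ("auc", "ideal_threshold", "critical_amplitude")
               if c not in records.columns]
    if missing:
        raise ValueError(f"per-eye table lacks columns: {missing}")
    auc = records["auc"].to_numpy(dtype=float)
    if np.any((auc <= 0) | (auc >= 1)):
        raise ValueError("per-eye AUC values must lie in (0, 1)")
    med_it, lo_it, hi_it = median_and_log_ci(
        records["ideal_threshold"].to_numpy(dtype=float), confidence
    )
    med_ca, lo_ca, hi_ca = median_and_log_ci(
        records["critical_amplitude"].to_numpy(dtype=float), confidence
    )
    return {
        "n_eyes": int(len(records)),
        "auc": {
            "median": float(np.median(auc)),
            "mean": float(auc.mean()),
            "log1m_transform_mean": float(transform_auc(auc).mean()),
        },
        "ideal_threshold": {
            "median": med_it, "ci_low": lo_it, "ci_high": hi_it,
            "confidence": confidence, "transform": "log",
        },
        "critical_amplitude": {
            "median": med_ca, "ci_low": lo_ca, "ci_high": hi_ca,
            "confidence": confidence, "transform": "log",
        },
    }
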