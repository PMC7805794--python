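"""Accuracy and bias profiling for age predictions.

The two headline accuracy statistics for a clock are Pearson's r between
predicted and chronological age and the RMSE in years.  Age-dependent bias
is profiled by splitting the cohort into equal-frequency chronological-age
deciles and summarising the delta-age (predicted - chronological)
distribution per decile with box-plot statistics: clocks trained on cohorts
lacking old donors show increasingly negative medians in the top deciles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association_models import FitReport, fit_age_association

__all__ = ["pearson_r", "rmse", "decile_error_summary", "variance_explained"]


def _pair(pred, chron, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    c = np.asarray(chron, dtype=float)
    if p.shape != c.shape:
        raise ValueError("prediction and age vectors differ in length")
    if len(p) < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return p, c


def pearson_r(pred, chron) -> float:
    """Pearson correlation between predicted and chronological age."""
    p, c = _pair(pred, chron, min_n=3)
    if np.ptp(p) == 0 or np.ptp(c) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(p, c).statistic)


def rmse(pred, chron) -> float:
    """Root mean squared prediction error, in years."""
    p, c = _pair(pred, chron, min_n=1)
    return float(np.sqrt(np.mean((p - c) ** 2)))


def decile_error_summary(pred, chron, n_bins: int = 10,
                         equal_width: bool = False) -> pd.DataFrame:
    """Per-age-bin box statistics of delta age.

    Bins are equal-frequency deciles of chronological age by default
    (stable sort, so tied ages fill the lower bin first); ``equal_width``
    switches to equal-width bins over the age range.  Each row reports the
    bin's age range, size, median/Q1/Q3 of delta age, 1.5·IQR whiskers
    (clamped to the data) and the number of points beyond them.
    """
    p, c = _pair(pred, chron, min_n=n_bins)
    delta = p - c
    n = len(c)
    if equal_width:
        edges = np.linspace(c.min(), c.max(), n_bins + 1)
        bin_of = np.clip(np.searchsorted(edges, c, side="right") - 1, 0, n_bins - 1)
    else:
        order = np.argsort(c, kind="stable")
        bin_of = np.empty(n, dtype=int)
        bin_of[order] = (np.arange(n) * n_bins) // n

    rows = []
    for b in range(n_bins):
        mask = bin_of == b
        if not mask.any():
            rows.append((b, np.nan, np.nan, 0) + (np.nan,) * 5 + (0,))
            continue
        d = delta[mask]
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        iqr = q3 - q1
        lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = d[(d >= lo_lim) & (d <= hi_lim)]
        rows.append((
            b, float(c[mask].min()), float(c[mask].max()), int(mask.sum()),
            float(med), float(q1), float(q3),
            float(inside.min()), float(inside.max()),
            int(((d < lo_lim) | (d > hi_lim)).sum()),
        ))
    return pd.DataFrame(rows, columns=[
        "bin", "age_min", "age_max", "n", "median_delta", "q1", "q3",
        "whisker_lo", "whisker_hi", "n_outliers",
    ])


def variance_explained(pred, chron, donor_ids=None) -> float:
    """Share of DNAm-age variation explained by chronological age.

    Fits the age-association model (random intercept per donor when donors
    repeat, OLS otherwise) and returns the marginal fixed-effect R²; with
    one sample per donor this equals Pearson r².
    """
    report: FitReport = fit_age_association(pred, chron, donor_ids=donor_ids,
                                            quadratic=False)
    return report.marginal_r2
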