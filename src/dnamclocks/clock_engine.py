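"""Apply a CpG-coefficient clock to a beta matrix.

DNAm age for a sample is the linear score

    s = intercept + sum_j coef_j * beta_j

over the clock's sites, mapped back to years through the clock's age
transform.  Delta age (the prediction error) is DNAm age minus chronological
age.  Sites absent from the target matrix — routine when a 450K-trained
clock is applied to EPIC data — are handled by a missing-site policy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .age_transform import HORVATH, inverse_transform_age
from .core_io import BetaMatrix, ClockDefinition, PredictionResult, SampleSheet

__all__ = [
    "predict_dnam_age",
    "delta_age",
    "intersect_clock_sites",
    "predictions_to_frame",
    "MISSING_POLICIES",
]

MISSING_POLICIES = ("error", "impute_reference_mean", "drop_site")


def delta_age(dnam_age: float, chron_age: float) -> float:
    """Signed prediction error in years: predicted minus chronological."""
    if not (np.isfinite(dnam_age) and np.isfinite(chron_age)):
        raise ValueError("ages must be finite")
    return float(dnam_age) - float(chron_age)


def intersect_clock_sites(a: ClockDefinition, b: ClockDefinition) -> list[str]:
    """Sorted list of CpG sites shared by two clocks."""
    return sorted(set(a.sites) & set(b.sites))


def predict_dnam_age(
    betas: BetaMatrix,
    clock: ClockDefinition,
    samples: SampleSheet | None = None,
    missing_policy: str = "impute_reference_mean",
    max_missing_fraction: float = 0.2,
) -> list[PredictionResult]:
    """Estimate DNAm age for every sample in ``betas``.

    Parameters
    ----------
    betas:
        Beta matrix; rows not in the clock are ignored.  Values are clipped
        to [0, 1] before scoring (with a warning) to absorb normalization
        overshoot.
    clock:
        Coefficient table plus transform.
    samples:
        Optional sample sheet supplying chronological ages; without it the
        reported ``delta_age`` is NaN.
    missing_policy:
        ``"impute_reference_mean"`` (default) substitutes the clock's
        training-set mean beta for a missing site, ``"drop_site"`` omits the
        term, ``"error"`` refuses any missingness.  A sample missing more
        than ``max_missing_fraction`` of the clock's sites is an error under
        every policy.

    Returns
    -------
    list of :class:`~dnamclocks.core_io.PredictionResult`, in the matrix's
    sample order (order of sites and samples never affects the values).
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    if missing_policy == "impute_reference_mean" and clock.n_sites > 0 \
            and clock.reference_means is None:
        raise ValueError(
            f"clock {clock.name!r} has no reference means; cannot impute "
            "(use missing_policy='drop_site' or 'error')"
        )

    clock_sites = list(clock.sites)
    coef = pd.Series(clock.sites, dtype=float)
    # sub-matrix aligned to the clock's site order; absent probes become NaN rows
    sub = betas.data.reindex(clock_sites)
    vals = sub.to_numpy(dtype=float)

    n_clip = int(((vals < 0) | (vals > 1)).sum())
    if n_clip:
        warnings.warn(f"clipped {n_clip} beta values to [0, 1] before scoring",
                      stacklevel=2)
        vals = np.clip(vals, 0.0, 1.0)

    miss = np.isnan(vals)  # sites x samples
    n_missing = miss.sum(axis=0)
    p = clock.n_sites

    sample_ids = betas.sample_ids
    if p > 0:
        frac = n_missing / p
        over = frac > max_missing_fraction
        if over.any():
            bad = [s for s, o in zip(sample_ids, over) if o]
            raise ValueError(
                f"samples missing more than {max_missing_fraction:.0%} of the "
                f"{p} clock sites: {bad[:10]}"
            )
        if missing_policy == "error" and n_missing.sum() > 0:
            bad = [s for s, m in zip(sample_ids, n_missing) if m > 0]
            raise ValueError(f"missing clock sites for samples: {bad[:10]}")
        if missing_policy == "impute_reference_mean":
            ref = np.array([clock.reference_means[s] for s in clock_sites])
            vals = np.where(miss, ref[:, None], vals)
        else:  # drop_site: omit the term, no rescaling
            vals = np.where(miss, 0.0, vals)
        scores = clock.intercept + coef.to_numpy() @ vals
    else:
        scores = np.full(len(sample_ids), clock.intercept)

    if clock.transform == HORVATH:
        dnam_ages = inverse_transform_age(scores, clock.transform_spec)
    else:
        dnam_ages = scores

    ages = samples.ages_for(sample_ids) if samples is not None else None
    out: list[PredictionResult] = []
    for i, sid in enumerate(sample_ids):
        chron = float(ages.loc[sid]) if ages is not None and pd.notna(ages.loc[sid]) else np.nan
        d = float(dnam_ages[i]) - chron if np.isfinite(chron) else float("nan")
        out.append(PredictionResult(
            sample_id=sid,
            dnam_age=float(dnam_ages[i]),
            delta_age=d,
            n_clock_sites_missing=int(n_missing[i]) if p > 0 else 0,
        ))
    return out


def predictions_to_frame(results: list[PredictionResult]) -> pd.DataFrame:
    """Tabulate predictions: sample_id, dnam_age, delta_age, n_missing."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "dnam_age": [r.dnam_age for r in results],
            "delta_age": [r.delta_age for r in results],
            "n_missing": [r.n_clock_sites_missing for r in results],
        }
    )
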