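"""Synthetic methylation cohorts with the structure a linear CpG clock assumes.

The generator emulates the shape of a multi-region post-mortem cortex
methylation study: donors spanning childhood to extreme old age, several
cortical regions per donor sharing age, sex and genotype, a sparse set of
age-associated CpGs, bounded beta-scale noise, optional batch offsets, SNP
probes with trimodal genotype clusters and sex-chromosome probes with
sex-differential methylation.

Age-associated sites are linear in *transformed* age on the beta scale:

    beta_j(a) = mid_j + c_j * (F(a) - F_mid)

with per-site slopes shrunk so the noiseless trajectory stays inside
[0.02, 0.98] over the configured age range — betas are bounded by
construction, and the cohort is exactly recoverable by a linear clock: the
returned ``true_clock`` (weights w_j = c_j / sum c^2 and matching intercept)
reproduces every age to machine precision at zero noise.  Measurement noise
is Gaussian on the beta scale, clipped to (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .age_transform import HORVATH, TransformSpec, transform_age
from .core_io import BetaMatrix, ClockDefinition, SampleSheet

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort", "inject_defects"]

_BETA_LO, _BETA_HI = 0.02, 0.98  # noiseless age trajectories stay inside
_CLIP = 1e-6


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator.

    ``effect_size_sd`` is the spread of per-site slopes on the beta scale
    per unit transformed age (before the boundedness shrink);
    ``noise_sd`` is beta-scale measurement noise.  Defaults mirror a
    life-course cortex cohort: ages 1–108 y, bounded betas, noise sd 0.02.
    """

    n_donors: int = 100
    regions_per_donor: int = 1
    age_range: tuple[float, float] = (1.0, 108.0)
    age_distribution: str = "uniform"  # or "old_skewed": Beta(5,2) over the range
    n_sites: int = 1000
    n_age_sites: int = 50
    effect_size_sd: float = 0.05
    noise_sd: float = 0.02
    batch_effect_sd: float = 0.0
    n_batches: int = 2
    n_snp_sites: int = 0
    sex_effect: bool = False
    adult_age: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_age_sites > self.n_sites:
            raise ValueError("n_age_sites must be <= n_sites")
        if min(self.noise_sd, self.batch_effect_sd, self.effect_size_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.age_range[0] < 0 or self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be an increasing pair of non-negative ages")
        if self.age_distribution not in ("uniform", "old_skewed"):
            raise ValueError("age_distribution must be 'uniform' or 'old_skewed'")
        if self.n_donors < 1 or self.regions_per_donor < 1 or self.n_batches < 1:
            raise ValueError("counts must be positive")


_N_X_SITES, _N_Y_SITES = 30, 10


@dataclass
class SimulatedCohort:
    """Everything a downstream module needs, plus the generating truth."""

    betas: BetaMatrix
    samples: SampleSheet
    detection_p: pd.DataFrame  # sites x samples, conformable with betas
    true_clock: ClockDefinition
    annotation: pd.DataFrame  # per-site: chromosome, on_450k, on_epic, is_snp, probe_type
    defect_labels: dict[str, list[str]] = field(default_factory=dict)


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Draw a cohort per ``cfg``; bit-identical for a given seed."""
    rng = np.random.default_rng(cfg.seed)
    spec = TransformSpec(kind=HORVATH, adult_age=cfg.adult_age)

    lo, hi = cfg.age_range
    if cfg.age_distribution == "uniform":
        donor_ages = rng.uniform(lo, hi, cfg.n_donors)
    else:
        donor_ages = lo + (hi - lo) * rng.beta(5.0, 2.0, cfg.n_donors)
    donor_sex = rng.choice(["F", "M"], cfg.n_donors)

    donors = [f"donor{i:04d}" for i in range(cfg.n_donors)]
    regions = [f"region{k + 1}" for k in range(cfg.regions_per_donor)]
    rows = []
    for i, d in enumerate(donors):
        for r in regions:
            rows.append((f"{d}_{r}", donor_ages[i], donor_sex[i], d, r))
    sample_ids = [r[0] for r in rows]
    n = len(rows)
    ages = np.array([r[1] for r in rows])
    sexes = np.array([r[2] for r in rows])
    f_age = transform_age(ages, spec)

    batches = np.array([f"batch{i % cfg.n_batches + 1}" for i in range(n)])

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "age": ages,
        "sex": sexes,
        "donor_id": [r[3] for r in rows],
        "region": [r[4] for r in rows],
        "batch": batches,
        "pmi_hours": np.round(rng.uniform(4.0, 96.0, n), 1),
        "neuronal_proportion": np.round(rng.uniform(0.2, 0.6, n), 4),
        "bisulphite_conversion_pct": np.round(rng.uniform(85.0, 99.5, n), 2),
    }))

    # --- autosomal sites -------------------------------------------------
    site_ids = [f"cg{j:08d}" for j in range(cfg.n_sites)]
    f_lo, f_hi = transform_age(lo, spec), transform_age(hi, spec)
    f_mid = 0.5 * (f_lo + f_hi)
    half_span = 0.5 * (f_hi - f_lo)

    mids = rng.uniform(0.25, 0.75, cfg.n_age_sites)
    slopes = rng.normal(0.0, cfg.effect_size_sd, cfg.n_age_sites)
    # shrink each slope so mid +/- |c|*half_span stays in [_BETA_LO, _BETA_HI]
    room = np.minimum(mids - _BETA_LO, _BETA_HI - mids)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(np.abs(slopes) * half_span > room,
                         room / (np.abs(slopes) * half_span), 1.0)
    slopes = slopes * scale

    clean = np.empty((cfg.n_sites, n))
    clean[:cfg.n_age_sites] = mids[:, None] + slopes[:, None] * (f_age - f_mid)[None, :]
    baselines = rng.uniform(0.1, 0.9, cfg.n_sites - cfg.n_age_sites)
    clean[cfg.n_age_sites:] = baselines[:, None]

    if cfg.batch_effect_sd > 0:
        batch_idx = np.array([int(b[5:]) - 1 for b in batches])
        offsets = rng.normal(0.0, cfg.batch_effect_sd, (cfg.n_batches, cfg.n_sites))
        clean = clean + offsets[batch_idx].T
    if cfg.noise_sd > 0:
        clean = clean + rng.normal(0.0, cfg.noise_sd, clean.shape)
    values = np.clip(clean, _CLIP, 1.0 - _CLIP)

    chrom = ["1"] * cfg.n_sites
    is_snp = [False] * cfg.n_sites

    # --- SNP probes: trimodal genotype clusters shared within donor ------
    if cfg.n_snp_sites > 0:
        snp_ids = [f"rs{j:06d}" for j in range(cfg.n_snp_sites)]
        genotypes = rng.choice([0.0, 0.5, 1.0], (cfg.n_snp_sites, cfg.n_donors),
                               p=[0.25, 0.5, 0.25])
        donor_idx = {d: i for i, d in enumerate(donors)}
        g = genotypes[:, [donor_idx[r[3]] for r in rows]]
        snp_vals = np.clip(g + rng.normal(0.0, 0.03, g.shape), _CLIP, 1.0 - _CLIP)
        site_ids += snp_ids
        values = np.vstack([values, snp_vals])
        chrom += ["1"] * cfg.n_snp_sites
        is_snp += [True] * cfg.n_snp_sites

    # --- sex-chromosome probes -------------------------------------------
    if cfg.sex_effect:
        x_ids = [f"cgX{j:06d}" for j in range(_N_X_SITES)]
        y_ids = [f"cgY{j:06d}" for j in range(_N_Y_SITES)]
        is_f = (sexes == "F")
        x_mean = np.where(is_f, 0.55, 0.25)
        x_vals = np.clip(x_mean[None, :] + rng.normal(0.0, 0.05, (_N_X_SITES, n)),
                         _CLIP, 1.0 - _CLIP)
        # male Y probes: real signal with high between-sample spread;
        # female Y probes: background, tight near zero
        y_sd = np.where(is_f, 0.02, 0.15)
        y_mean = np.where(is_f, 0.05, 0.5)
        y_vals = np.clip(y_mean[None, :] + rng.normal(0.0, 1.0, (_N_Y_SITES, n)) * y_sd[None, :],
                         _CLIP, 1.0 - _CLIP)
        site_ids += x_ids + y_ids
        values = np.vstack([values, x_vals, y_vals])
        chrom += ["X"] * _N_X_SITES + ["Y"] * _N_Y_SITES
        is_snp += [False] * (_N_X_SITES + _N_Y_SITES)

    betas = BetaMatrix(pd.DataFrame(values, index=site_ids, columns=sample_ids))

    detection_p = pd.DataFrame(
        rng.uniform(0.0, 0.01, values.shape), index=site_ids, columns=sample_ids
    )

    annotation = pd.DataFrame({
        "chromosome": chrom,
        "on_450k": True,
        "on_epic": True,
        "is_snp": is_snp,
        "probe_type": np.where(rng.random(len(site_ids)) < 0.3, "I", "II"),
    }, index=pd.Index(site_ids, name="site_id"))

    # --- generating clock: exact linear inverse of the age sites ---------
    causal = np.abs(slopes) > 0
    if causal.any():
        c = slopes[causal]
        w = c / np.sum(c ** 2)
        m = mids[causal]
        clock_sites = dict(zip(np.array(site_ids[:cfg.n_age_sites])[causal], w))
        intercept = f_mid - float(np.sum(w * m))
    else:
        clock_sites, intercept = {}, f_mid
    empirical_means = betas.data.loc[list(clock_sites)].mean(axis=1) if clock_sites else pd.Series(dtype=float)
    true_clock = ClockDefinition(
        name="true_clock",
        intercept=intercept,
        sites=clock_sites,
        reference_means={s: float(np.clip(m, 0, 1)) for s, m in empirical_means.items()} or None,
        transform=HORVATH,
        adult_age=cfg.adult_age,
    )
    return SimulatedCohort(betas, sheet, detection_p, true_clock, annotation)


DEFECT_KINDS = ("bad_sample_detp", "sex_swap", "genotype_mismatch",
                "pca_outlier", "low_conversion")


def inject_defects(cohort: SimulatedCohort, defects: Mapping[str, int],
                   seed: int = 0) -> SimulatedCohort:
    """Plant QC defects with ground-truth labels.

    ``defects`` maps defect kind to a count of affected samples; each kind
    hits distinct samples so recall/precision of each QC step is measurable.
    Kinds: ``bad_sample_detp`` (2% of probes get detection p = 0.5),
    ``sex_swap`` (reported sex flipped), ``genotype_mismatch`` (one sample's
    SNP betas redrawn, breaking within-donor concordance), ``pca_outlier``
    (10-SD shift on up to 200 probes) and ``low_conversion`` (bisulphite
    conversion set to 79.9, below the 80% cut).
    """
    unknown = set(defects) - set(DEFECT_KINDS)
    if unknown:
        raise ValueError(f"unknown defect kinds: {sorted(unknown)}")
    total = sum(defects.values())
    n = cohort.betas.n_samples
    if total > n:
        raise ValueError("more defects than samples")

    rng = np.random.default_rng(seed)
    beta_df = cohort.betas.data.copy()
    detp = cohort.detection_p.copy()
    sheet = cohort.samples.data.copy()
    labels: dict[str, list[str]] = {k: [] for k in defects}

    pool = list(beta_df.columns)
    rng.shuffle(pool)
    snp_sites = cohort.annotation.index[cohort.annotation["is_snp"]].tolist()

    def take(kind: str) -> str:
        if kind == "genotype_mismatch":
            # needs a donor with >= 2 samples so a same-donor pair exists
            by_donor = sheet.groupby("donor_id")["sample_id"].apply(list)
            for sid in pool:
                donor = sheet.set_index("sample_id").loc[sid, "donor_id"]
                if len(by_donor[donor]) >= 2:
                    pool.remove(sid)
                    return sid
            raise ValueError("genotype_mismatch needs a donor with >= 2 samples")
        return pool.pop()

    for kind, count in defects.items():
        for _ in range(count):
            sid = take(kind)
            labels[kind].append(sid)
            if kind == "bad_sample_detp":
                n_fail = max(int(np.ceil(0.02 * len(detp))), 2)
                idx = rng.choice(len(detp), n_fail, replace=False)
                detp.iloc[idx, detp.columns.get_loc(sid)] = 0.5
            elif kind == "sex_swap":
                i = sheet.index[sheet["sample_id"] == sid][0]
                sheet.loc[i, "sex"] = {"F": "M", "M": "F"}.get(sheet.loc[i, "sex"], "F")
            elif kind == "genotype_mismatch":
                if not snp_sites:
                    raise ValueError("cohort has no SNP probes")
                g = rng.choice([0.0, 0.5, 1.0], len(snp_sites), p=[0.25, 0.5, 0.25])
                beta_df.loc[snp_sites, sid] = np.clip(
                    g + rng.normal(0.0, 0.03, len(snp_sites)), _CLIP, 1 - _CLIP)
            elif kind == "pca_outlier":
                non_snp = [s for s in beta_df.index if s not in set(snp_sites)]
                hit = non_snp[:min(200, len(non_snp))]
                sd = beta_df.loc[hit].std(axis=1).to_numpy()
                col = beta_df.loc[hit, sid].to_numpy()
                direction = np.where(col <= 0.5, 1.0, -1.0)
                beta_df.loc[hit, sid] = np.clip(col + direction * 10.0 * np.maximum(sd, 0.02),
                                                _CLIP, 1 - _CLIP)
            elif kind == "low_conversion":
                i = sheet.index[sheet["sample_id"] == sid][0]
                sheet.loc[i, "bisulphite_conversion_pct"] = 79.9

    return SimulatedCohort(
        betas=BetaMatrix(beta_df),
        samples=SampleSheet(sheet),
        detection_p=detp,
        true_clock=cohort.true_clock,
        annotation=cohort.annotation,
        defect_labels=labels,
    )
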