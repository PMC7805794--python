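"""Tabular QC and normalization for methylation beta matrices.

Covers the sample/probe-level checks that operate on matrices and sample
sheets: bisulphite-conversion thresholding, detection-p filtering, sex
confirmation by multidimensional scaling of sex-chromosome probes,
SNP-probe genotype concordance, PCA outlier removal, blacklist probe
removal, and per-probe-type quantile normalization of methylated and
unmethylated intensities.  Every filter only removes rows/columns (values
are untouched) and is idempotent; quantile normalization is the single
value-modifying step.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core_io import BetaMatrix, SampleSheet

__all__ = [
    "filter_bisulphite_conversion",
    "detection_p_filter",
    "predict_sex",
    "genotype_concordance",
    "pca_outliers",
    "remove_blacklist_probes",
    "quantile_normalize",
    "run_qc_pipeline",
]


@dataclass
class ConversionFilterResult:
    kept: list[str]
    excluded: list[str]
    min_pct: float


def filter_bisulphite_conversion(samples: SampleSheet,
                                 min_pct: float = 80.0) -> ConversionFilterResult:
    """Exclude samples whose bisulphite conversion rate is strictly below
    ``min_pct`` (default 80%); boundary samples are kept.

    The conversion statistic is a precomputed per-sample percentage in the
    sample sheet; samples lacking it raise an error naming them.
    """
    col = "bisulphite_conversion_pct"
    df = samples.data
    if col not in df.columns or df[col].isna().any():
        missing = (df["sample_id"].tolist() if col not in df.columns
                   else df.loc[df[col].isna(), "sample_id"].tolist())
        raise ValueError(f"bisulphite conversion metric missing for samples: {missing[:10]}")
    vals = df[col].astype(float)
    excluded = df.loc[vals < min_pct, "sample_id"].tolist()
    kept = df.loc[vals >= min_pct, "sample_id"].tolist()
    return ConversionFilterResult(kept=kept, excluded=excluded, min_pct=min_pct)


def detection_p_filter(
    betas: BetaMatrix,
    detp: pd.DataFrame,
    sample_frac: float = 0.01,
    probe_frac: float = 0.01,
    p_cut: float = 0.05,
) -> tuple[BetaMatrix, dict]:
    """Drop unreliable samples, then unreliable probes, by detection p-value.

    A measurement fails when its detection p-value exceeds ``p_cut``.
    Samples with a failing-probe fraction strictly above ``sample_frac``
    are removed first; probes with a failing fraction strictly above
    ``probe_frac`` across the remaining samples are removed second.
    """
    if set(detp.index) < set(betas.site_ids) or set(detp.columns) < set(betas.sample_ids):
        raise ValueError("detection-p matrix does not cover the beta matrix")
    dp = detp.loc[betas.site_ids, betas.sample_ids]
    fail = dp.to_numpy() > p_cut

    sample_fail_frac = fail.mean(axis=0)
    bad_samples = [s for s, f in zip(betas.sample_ids, sample_fail_frac) if f > sample_frac]
    keep_samples = [s for s in betas.sample_ids if s not in set(bad_samples)]

    fail2 = dp[keep_samples].to_numpy() > p_cut
    probe_fail_frac = fail2.mean(axis=1) if keep_samples else np.zeros(len(dp))
    bad_probes = [p for p, f in zip(betas.site_ids, probe_fail_frac) if f > probe_frac]

    out = betas.select_samples(keep_samples).drop_sites(bad_probes)
    report = {"samples_removed": bad_samples, "probes_removed": bad_probes,
              "p_cut": p_cut, "sample_frac": sample_frac, "probe_frac": probe_frac}
    return out, report


def _cmdscale_first_coord(vals: np.ndarray) -> np.ndarray:
    """First classical (Torgerson) MDS coordinate of samples.

    ``vals``: probes x samples.  Double-centres the squared Euclidean
    distance matrix and takes the leading eigenvector.
    """
    d2 = squareform(pdist(vals.T, metric="sqeuclidean"))
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    lead = np.argmax(evals)
    lam = max(evals[lead], 0.0)
    return evecs[:, lead] * np.sqrt(lam)


@dataclass
class SexCheckReport:
    predictions: pd.DataFrame  # sample_id, predicted_sex, reported_sex, mismatch
    n_mismatches: int
    confident: bool


def predict_sex(betas: BetaMatrix, annotation: pd.DataFrame,
                samples: SampleSheet | None = None) -> SexCheckReport:
    """Confirm reported sex from X/Y-chromosome methylation.

    Classical multidimensional scaling of inter-sample distances is run on
    X-chromosome probes and Y-chromosome probes separately; samples are
    split into two clusters on the first coordinate of each.  The cluster
    with the larger between-sample variance of Y-probe betas is labelled
    male (in females Y probes carry only background, which is tight and
    near zero).  Samples on which the X- and Y-based partitions disagree,
    or everything when the coordinates are degenerate, come back
    ``undetermined``.
    """
    chrom = annotation.reindex(betas.site_ids)["chromosome"].astype(str)
    x_sites = [s for s, c in zip(betas.site_ids, chrom) if c.upper().lstrip("CHR") == "X"]
    y_sites = [s for s, c in zip(betas.site_ids, chrom) if c.upper().lstrip("CHR") == "Y"]
    if len(x_sites) < 20 or len(y_sites) < 5:
        raise ValueError(
            f"need >= 20 X and >= 5 Y probes; found {len(x_sites)} X, {len(y_sites)} Y")
    if betas.n_samples < 4:
        raise ValueError("need >= 4 samples for sex clustering")

    ids = betas.sample_ids
    xv = betas.data.loc[x_sites].to_numpy()
    yv = betas.data.loc[y_sites].to_numpy()

    def split(coord: np.ndarray) -> np.ndarray | None:
        if np.var(coord) < 1e-12:
            return None
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(coord.reshape(-1, 1))
        if np.abs(np.diff(km.cluster_centers_.ravel()))[0] < 1e-9:
            return None
        return km.labels_

    lx = split(_cmdscale_first_coord(xv))
    ly = split(_cmdscale_first_coord(yv))

    pred = np.array(["undetermined"] * len(ids), dtype=object)
    confident = lx is not None and ly is not None
    if ly is not None:
        # label male = Y cluster with larger between-sample beta variance
        var = [yv[:, ly == k].var(axis=1).mean() if (ly == k).any() else -1.0
               for k in (0, 1)]
        male_label = int(np.argmax(var))
        pred = np.where(ly == male_label, "M", "F").astype(object)
        if lx is not None:
            # X partition must agree (up to relabelling); disagreeing samples
            # are undetermined
            match = (lx == lx[np.argmax(ly == male_label)])
            agree = (ly == male_label) == match
            if not agree.all():
                agree2 = (ly == male_label) == ~match
                agree = agree if agree.sum() >= agree2.sum() else agree2
                pred[~agree] = "undetermined"

    reported = (samples.data.set_index("sample_id")["sex"].reindex(ids).to_numpy()
                if samples is not None else np.array([None] * len(ids)))
    mismatch = [
        (p in ("F", "M")) and (r in ("F", "M")) and p != r
        for p, r in zip(pred, reported)
    ]
    df = pd.DataFrame({"sample_id": ids, "predicted_sex": pred,
                       "reported_sex": reported, "mismatch": mismatch})
    return SexCheckReport(predictions=df, n_mismatches=int(sum(mismatch)),
                          confident=confident)


@dataclass
class GenotypeConcordanceReport:
    pairs: pd.DataFrame  # sample_a, sample_b, r, same_donor, flag
    mismatches: list[tuple[str, str]]
    duplications: list[tuple[str, str]]


def genotype_concordance(snp_betas: BetaMatrix, samples: SampleSheet,
                         r_threshold: float = 0.9) -> GenotypeConcordanceReport:
    """Check sample identity from SNP-probe betas.

    SNP probes cluster at genotypes ~0 / 0.5 / 1, so the Pearson
    correlation of SNP betas between two samples of the same individual is
    near 1.  Pairs at or above ``r_threshold`` are called same-individual;
    same-donor pairs below it are flagged as mismatches and
    different-donor pairs above it as duplications.
    """
    if snp_betas.n_sites < 10:
        raise ValueError(f"need >= 10 SNP probes, got {snp_betas.n_sites}")
    ids = snp_betas.sample_ids
    donor = samples.data.set_index("sample_id")["donor_id"].reindex(ids)
    vals = snp_betas.data.to_numpy()
    r = np.corrcoef(vals.T)

    rows, mismatches, duplications = [], [], []
    for i, j in itertools.combinations(range(len(ids)), 2):
        same = donor.iloc[i] == donor.iloc[j]
        rij = float(r[i, j])
        flag = "ok"
        if same and rij < r_threshold:
            flag = "mismatch"
            mismatches.append((ids[i], ids[j]))
        elif not same and rij >= r_threshold:
            flag = "duplication"
            duplications.append((ids[i], ids[j]))
        rows.append((ids[i], ids[j], rij, bool(same), flag))
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "r", "same_donor", "flag"])
    return GenotypeConcordanceReport(pairs=pairs, mismatches=mismatches,
                                     duplications=duplications)


def pca_outliers(betas: BetaMatrix, n_pc: int = 3, sd_thresh: float = 3.0) -> list[str]:
    """Samples beyond ``sd_thresh`` standard deviations on any of the first
    ``n_pc`` principal components of the site-centred beta matrix."""
    n = betas.n_samples
    if n < n_pc + 2:
        raise ValueError(f"need >= {n_pc + 2} samples for {n_pc} components, got {n}")
    X = betas.data.to_numpy().T  # samples x sites
    X = X - np.nanmean(X, axis=0)
    X = np.nan_to_num(X)
    scores = PCA(n_components=n_pc, random_state=0).fit_transform(X)
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    flagged = np.abs(scores) > sd_thresh * sd
    return [s for s, f in zip(betas.sample_ids, flagged.any(axis=1)) if f]


def remove_blacklist_probes(betas: BetaMatrix, blacklist) -> tuple[BetaMatrix, int]:
    """Drop cross-hybridizing / SNP-overlapping probes listed in ``blacklist``."""
    hit = set(blacklist) & set(betas.site_ids)
    out = betas.drop_sites(hit)
    if out.n_sites == 0:
        warnings.warn("blacklist removed every probe", stacklevel=2)
    return out, len(hit)


def _qn_block(block: np.ndarray) -> np.ndarray:
    """Replace each column by the rank-wise mean distribution."""
    order = np.argsort(block, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(block.shape[0])[:, None]
    np.put_along_axis(ranks, order, rows, axis=0)
    target = np.sort(block, axis=0).mean(axis=1)
    return target[ranks]


def quantile_normalize_intensities(intensities: pd.DataFrame,
                                   probe_type: pd.Series) -> pd.DataFrame:
    """Quantile-normalize one intensity channel across samples, within each
    probe chemistry type.  After this, every sample's intensity multiset
    within a type is identical, and each sample keeps its own probe ranks."""
    if (intensities.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    types = probe_type.reindex(intensities.index)
    if types.isna().any():
        raise ValueError("probe_type must cover every probe")
    out = intensities.to_numpy(dtype=float).copy()
    for t in pd.unique(types):
        idx = np.flatnonzero((types == t).to_numpy())
        if idx.size:
            out[idx] = _qn_block(out[idx])
    return pd.DataFrame(out, index=intensities.index, columns=intensities.columns)


def quantile_normalize(meth: pd.DataFrame, unmeth: pd.DataFrame,
                       probe_type: pd.Series, offset: float = 100.0) -> BetaMatrix:
    """Between-sample quantile normalization by probe chemistry type.

    Within each probe type (I and II are distinct chemistries with distinct
    intensity distributions), the methylated and unmethylated intensity
    matrices are separately quantile-normalized across samples: each
    sample's values are replaced by the rank-wise mean distribution.  Betas
    are then M / (M + U + offset) with the usual offset of 100.
    """
    if meth.shape != unmeth.shape or not meth.index.equals(unmeth.index) \
            or not meth.columns.equals(unmeth.columns):
        raise ValueError("methylated/unmethylated matrices must be conformable")
    m_out = quantile_normalize_intensities(meth, probe_type)
    u_out = quantile_normalize_intensities(unmeth, probe_type)
    beta = m_out.to_numpy() / (m_out.to_numpy() + u_out.to_numpy() + offset)
    return BetaMatrix(pd.DataFrame(beta, index=meth.index, columns=meth.columns))


@dataclass
class QCPipelineResult:
    betas: BetaMatrix
    samples: SampleSheet
    steps: dict = field(default_factory=dict)


def run_qc_pipeline(
    betas: BetaMatrix,
    samples: SampleSheet,
    detp: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    blacklist=(),
    min_conversion_pct: float = 80.0,
    r_threshold: float = 0.9,
    n_pc: int = 3,
    sd_thresh: float = 3.0,
) -> QCPipelineResult:
    """Run the tabular QC steps in pipeline order and collect a report.

    Order: conversion threshold -> sex check (flags only) -> genotype
    concordance (flags only) -> detection-p filter -> PCA outliers ->
    blacklist probes.  Flagged-only steps never remove samples silently;
    their reports are in ``steps`` for the caller to act on.
    """
    steps: dict = {}

    conv = filter_bisulphite_conversion(samples, min_conversion_pct)
    steps["conversion"] = conv
    betas = betas.select_samples(conv.kept)
    samples = samples.subset(conv.kept)

    if annotation is not None:
        chrom = annotation.reindex(betas.site_ids)["chromosome"].astype(str).str.upper()
        if (chrom == "X").sum() >= 20 and (chrom == "Y").sum() >= 5 and betas.n_samples >= 4:
            steps["sex_check"] = predict_sex(betas, annotation, samples)
        if "is_snp" in annotation.columns:
            snp_sites = [s for s in betas.site_ids
                         if bool(annotation.loc[s, "is_snp"]) if s in annotation.index]
            if len(snp_sites) >= 10:
                steps["genotype"] = genotype_concordance(
                    betas.select_sites(snp_sites), samples, r_threshold)

    if detp is not None:
        betas, rep = detection_p_filter(betas, detp)
        samples = samples.subset(betas.sample_ids)
        steps["detection_p"] = rep

    # PCA outlier scan on autosomal non-SNP probes only: genotype clusters
    # (SNP probes) and sex clusters (X/Y probes) would dominate the leading
    # components and mask genuine technical outliers
    pca_input = betas
    if annotation is not None:
        ann = annotation.reindex(betas.site_ids)
        chrom = ann["chromosome"].astype(str).str.upper()
        autosomal = ~chrom.isin(["X", "Y", "CHRX", "CHRY"])
        if "is_snp" in ann.columns:
            autosomal &= ~ann["is_snp"].fillna(False).astype(bool)
        keep_sites = [s for s, ok in zip(betas.site_ids, autosomal) if ok]
        if len(keep_sites) >= 2:
            pca_input = betas.select_sites(keep_sites)
    outliers = pca_outliers(pca_input, n_pc=n_pc, sd_thresh=sd_thresh)
    steps["pca_outliers"] = outliers
    if outliers:
        keep = [s for s in betas.sample_ids if s not in set(outliers)]
        betas = betas.select_samples(keep)
        samples = samples.subset(keep)

    betas, n_removed = remove_blacklist_probes(betas, blacklist)
    steps["blacklist_removed"] = n_removed
    return QCPipelineResult(betas=betas, samples=samples, steps=steps)
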