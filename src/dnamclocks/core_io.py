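"""Domain types and delimited-text I/O for methylation clock workflows.

All on-disk formats are plain delimited text (tab by default, comma via
``dialect="csv"``): beta matrices are sites x samples with the first column
holding CpG probe IDs; sample sheets are one row per sample; clock
definitions are two/three-column coefficient tables with ``#``-prefixed
header metadata and an ``(Intercept)`` row.  ``"NA"`` and the empty string
denote missing values everywhere.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .age_transform import HORVATH, IDENTITY, TransformSpec

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "ClockDefinition",
    "PredictionResult",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_clock_definition",
    "write_clock_definition",
    "load_packaged_clock",
    "match_samples",
]

_NA_VALUES = ["NA", ""]
_RANGE_TOL = 1e-9

#: packaged clock fixtures.  These are SYNTHETIC stand-in coefficient tables
#: (see the file headers): deterministic placeholder CpG IDs and coefficients
#: carrying the published structure of each clock — the cortical clock's 347
#: sites and its 5 / 15 / 5 site overlaps with the 353-site multi-tissue,
#: 514-site blood and 513-site pheno-age clocks — not the published values.
PACKAGED_CLOCKS = {
    "cortical": "cortical_clock.synthetic.tsv",
    "multi_tissue": "multi_tissue_clock.synthetic.tsv",
    "blood": "blood_clock.synthetic.tsv",
    "pheno_age": "pheno_age_clock.synthetic.tsv",
}


def _sep(dialect: str) -> str:
    if dialect in ("tsv", "\t", "tab"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    raise ValueError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")


# ---------------------------------------------------------------------------
# domain types


class BetaMatrix:
    """CpG sites x samples matrix of methylation proportions in [0, 1].

    Wraps a float DataFrame (rows = sites, columns = samples, NaN = missing)
    and enforces unique IDs and the value range on construction.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site IDs: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        values = data.to_numpy(dtype=float)
        bad = (values < -_RANGE_TOL) | (values > 1.0 + _RANGE_TOL)
        bad &= ~np.isnan(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0, 1]: site {data.index[i]!r}, "
                f"sample {data.columns[j]!r}, value {values[i, j]}"
            )
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "site_id"
        self.data.columns = self.data.columns.astype(str)
        self.data.columns.name = None

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def select_sites(self, sites: Iterable[str]) -> "BetaMatrix":
        sites = [s for s in sites if s in self.data.index]
        return BetaMatrix(self.data.loc[sites])

    def drop_sites(self, sites: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.data.drop(index=[s for s in sites if s in self.data.index]))

    def select_samples(self, samples: Iterable[str]) -> "BetaMatrix":
        samples = [s for s in samples if s in self.data.columns]
        return BetaMatrix(self.data[samples])

    def __repr__(self) -> str:  # pragma: no cover
        return f"BetaMatrix({self.n_sites} sites x {self.n_samples} samples)"


_SEXES = {"F", "M", "unknown"}


class SampleSheet:
    """Per-sample metadata: age, sex, donor, region, batch and QC covariates.

    Columns: ``sample_id`` (unique), ``age`` (years, finite >= 0), ``sex``
    (F/M/unknown), ``donor_id``, ``region``, ``batch`` and the optional
    ``pmi_hours``, ``neuronal_proportion`` (in [0, 1]) and
    ``bisulphite_conversion_pct`` (in [0, 100]).
    """

    REQUIRED = ["sample_id", "age", "sex", "donor_id", "region", "batch"]
    OPTIONAL = ["pmi_hours", "neuronal_proportion", "bisulphite_conversion_pct"]

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        data = data.copy()
        data["sample_id"] = data["sample_id"].astype(str)
        if data["sample_id"].duplicated().any():
            dups = data.loc[data["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        ages = pd.to_numeric(data["age"], errors="raise")
        if not np.all(np.isfinite(ages)) or (ages < 0).any():
            raise ValueError("ages must be finite and >= 0")
        data["age"] = ages.astype(float)
        data["sex"] = data["sex"].fillna("unknown").astype(str)
        bad_sex = set(data["sex"]) - _SEXES
        if bad_sex:
            raise ValueError(f"sex must be one of {_SEXES}, got {bad_sex}")
        if "neuronal_proportion" in data.columns:
            npn = pd.to_numeric(data["neuronal_proportion"], errors="raise")
            if ((npn < 0) | (npn > 1)).any():
                raise ValueError("neuronal_proportion must lie in [0, 1]")
        if "bisulphite_conversion_pct" in data.columns:
            bc = pd.to_numeric(data["bisulphite_conversion_pct"], errors="raise")
            if ((bc < 0) | (bc > 100)).any():
                raise ValueError("bisulphite_conversion_pct must lie in [0, 100]")
        self.data = data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def ages_for(self, sample_ids: Sequence[str]) -> pd.Series:
        s = self.data.set_index("sample_id")["age"]
        return s.reindex(list(sample_ids))

    def row(self, sample_id: str) -> pd.Series:
        return self.data.set_index("sample_id").loc[sample_id]

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        keep = self.data[self.data["sample_id"].isin(set(sample_ids))]
        return SampleSheet(keep)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ClockDefinition:
    """A linear CpG clock: intercept plus per-site coefficients.

    ``sites`` maps probe ID to coefficient.  ``reference_means`` (optional,
    same key set) are training-set mean betas used to impute sites missing
    from a target matrix.  ``transform`` says which scale the linear score
    lives on: ``horvath_transformed`` scores are inverse-transformed to
    years, ``identity`` scores are years already.  An intercept-only clock
    (no sites, e.g. the full-shrinkage elastic-net solution) is permitted.
    """

    name: str
    intercept: float
    sites: dict[str, float]
    reference_means: dict[str, float] | None = None
    transform: str = HORVATH
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.transform not in (HORVATH, IDENTITY):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        coefs = np.array(list(self.sites.values()), dtype=float)
        if coefs.size and not np.all(np.isfinite(coefs)):
            raise ValueError("coefficients must be finite")
        if self.reference_means is not None:
            missing = set(self.sites) - set(self.reference_means)
            if missing:
                raise ValueError(
                    f"reference_means must cover all sites; missing {len(missing)}"
                )
            means = np.array([self.reference_means[s] for s in self.sites])
            if means.size and (np.any(means < 0) or np.any(means > 1)):
                raise ValueError("reference means must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def transform_spec(self) -> TransformSpec:
        return TransformSpec(kind=self.transform, adult_age=self.adult_age)


@dataclass
class PredictionResult:
    """One sample's clock output: DNAm age and its deviation from truth."""

    sample_id: str
    dnam_age: float
    delta_age: float  # dnam_age - chronological age; NaN if age unknown
    n_clock_sites_missing: int = 0


# ---------------------------------------------------------------------------
# beta matrix I/O


def read_beta_matrix(path, dialect: str = "tsv") -> BetaMatrix:
    """Read a sites-x-samples beta matrix from delimited text.

    First column holds site IDs, header row holds sample IDs; ``NA``/empty
    cells are missing.  Values outside [0, 1] (tolerance 1e-9) and duplicate
    IDs raise ``ValueError`` naming the offender; non-numeric cells raise.
    """
    df = pd.read_csv(
        path, sep=_sep(dialect), index_col=0, na_values=_NA_VALUES,
        keep_default_na=False, comment="#",
    )
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in beta matrix {path}: {exc}") from exc
    return BetaMatrix(df)


def write_beta_matrix(betas: BetaMatrix, path, dialect: str = "tsv",
                      float_format: str = "%.10g") -> None:
    betas.data.to_csv(path, sep=_sep(dialect), na_rep="NA",
                      float_format=float_format, index_label="site_id")


def read_sample_sheet(path, dialect: str = "tsv") -> SampleSheet:
    df = pd.read_csv(path, sep=_sep(dialect), na_values=_NA_VALUES,
                     keep_default_na=False, comment="#")
    return SampleSheet(df)


def write_sample_sheet(samples: SampleSheet, path, dialect: str = "tsv") -> None:
    samples.data.to_csv(path, sep=_sep(dialect), na_rep="NA", index=False)


# ---------------------------------------------------------------------------
# clock definition I/O

_INTERCEPT_KEYS = {"(intercept)", "intercept"}


def read_clock_definition(path, dialect: str = "tsv") -> ClockDefinition:
    """Read a clock coefficient table.

    Expected layout: optional ``# key: value`` header lines (name, transform,
    adult_age, intercept), then a header row ``site<TAB>coefficient
    [<TAB>reference_mean]`` and one row per site.  The intercept may instead
    appear as a row with site ``(Intercept)``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep=_sep(dialect),
                     na_values=_NA_VALUES, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    if "site" not in cols or "coefficient" not in cols:
        raise ValueError(f"clock table {path} needs 'site' and 'coefficient' columns")
    df = df.rename(columns={cols["site"]: "site", cols["coefficient"]: "coefficient"})
    if "reference_mean" in cols:
        df = df.rename(columns={cols["reference_mean"]: "reference_mean"})

    is_int = df["site"].str.lower().isin(_INTERCEPT_KEYS)
    intercept = meta.get("intercept")
    if is_int.any():
        if is_int.sum() > 1:
            raise ValueError("multiple intercept rows")
        intercept = float(df.loc[is_int, "coefficient"].iloc[0])
        df = df[~is_int]
    elif intercept is not None:
        intercept = float(intercept)
    else:
        raise ValueError(f"clock table {path} has no intercept (row or '# intercept:')")

    if df["site"].duplicated().any():
        dups = df.loc[df["site"].duplicated(), "site"].tolist()
        raise ValueError(f"duplicate clock sites: {dups[:5]}")

    sites = dict(zip(df["site"], df["coefficient"].astype(float)))
    ref = None
    if "reference_mean" in df.columns and df["reference_mean"].notna().all():
        ref = dict(zip(df["site"], df["reference_mean"].astype(float)))
    return ClockDefinition(
        name=meta.get("name", path.stem),
        intercept=float(intercept),
        sites=sites,
        reference_means=ref,
        transform=meta.get("transform", HORVATH),
        adult_age=float(meta.get("adult_age", 20.0)),
    )


def write_clock_definition(clock: ClockDefinition, path, dialect: str = "tsv") -> None:
    sep = _sep(dialect)
    with open(path, "w") as fh:
        fh.write(f"# name: {clock.name}\n")
        fh.write(f"# transform: {clock.transform}\n")
        fh.write(f"# adult_age: {clock.adult_age:g}\n")
        cols = ["site", "coefficient"]
        has_ref = clock.reference_means is not None
        if has_ref:
            cols.append("reference_mean")
        fh.write(sep.join(cols) + "\n")
        fh.write(sep.join(["(Intercept)", f"{clock.intercept:.12g}"]
                          + (["NA"] if has_ref else [])) + "\n")
        for site, coef in clock.sites.items():
            row = [site, f"{coef:.12g}"]
            if has_ref:
                row.append(f"{clock.reference_means[site]:.12g}")
            fh.write(sep.join(row) + "\n")


def load_packaged_clock(name: str) -> ClockDefinition:
    """Load one of the packaged clock fixtures by short name.

    Available: ``cortical``, ``multi_tissue``, ``blood``, ``pheno_age``.
    These tables are synthetic stand-ins (see :data:`PACKAGED_CLOCKS`).
    """
    if name not in PACKAGED_CLOCKS:
        raise KeyError(f"unknown packaged clock {name!r}; choose from {sorted(PACKAGED_CLOCKS)}")
    ref = importlib.resources.files("dnamclocks") / "data" / PACKAGED_CLOCKS[name]
    with importlib.resources.as_file(ref) as p:
        return read_clock_definition(p)


# ---------------------------------------------------------------------------
# sample matching


def match_samples(betas: BetaMatrix, samples: SampleSheet) -> tuple[BetaMatrix, SampleSheet]:
    """Align a beta matrix and sample sheet on their shared sample IDs.

    Samples present in only one input are dropped with a warning (partial
    cohorts are normal); the returned pair has identical sample order.
    """
    shared = [s for s in betas.sample_ids if s in set(samples.sample_ids)]
    dropped = (set(betas.sample_ids) | set(samples.sample_ids)) - set(shared)
    if not shared:
        raise ValueError("no shared sample IDs between beta matrix and sample sheet")
    if dropped:
        warnings.warn(f"dropping {len(dropped)} unmatched samples", stacklevel=2)
    b = betas.select_samples(shared)
    s = samples.subset(shared)
    s.data = s.data.set_index("sample_id").loc[shared].reset_index()
    return b, s
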