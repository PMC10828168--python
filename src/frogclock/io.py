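"""Data model and delimited-text I/O.

The package's universal input is a :class:`MethylationCohort`: a CpG-by-sample
matrix of methylation beta fractions joined with per-sample metadata.  All
files are plain delimited text; the delimiter is auto-detected from the
extension (``.csv`` -> comma, anything else -> tab) and can be overridden.

Missing betas are carried as NaN.  Array data normally arrive complete after
normalization, so no single convention exists for stray missing values;
downstream stages take an explicit policy: drop any CpG with a missing value
(default) or impute the CpG mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "BetaMatrix",
    "SampleRecord",
    "SpeciesInfo",
    "SpeciesRegistry",
    "MethylationCohort",
    "AnnotationSets",
    "default_registry",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation_sets",
    "write_annotation_sets",
    "assemble_cohort",
    "handle_missing",
]

SEXES = ("female", "male", "unknown")


class FormatError(ValueError):
    """A file does not have the expected layout."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


def _delimiter(path, override: str | None = None) -> str:
    if override is not None:
        return override
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of beta fractions in [0, 1] (NaN = missing)."""

    cpg_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.cpg_ids)} CpGs, {len(self.sample_ids)} samples)"
            )
        _check_unique(self.cpg_ids, "CpG ids")
        _check_unique(self.sample_ids, "sample ids")
        bad = np.nonzero((self.values < 0) | (self.values > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {self.values[i, j]!r} outside [0, 1] at "
                f"CpG {self.cpg_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)

    def subset_cpgs(self, cpg_ids: Iterable[str]) -> "BetaMatrix":
        idx = {c: i for i, c in enumerate(self.cpg_ids)}
        keep = [idx[c] for c in cpg_ids]
        return BetaMatrix(
            [self.cpg_ids[i] for i in keep], list(self.sample_ids), self.values[keep, :]
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        keep = [idx[s] for s in sample_ids]
        return BetaMatrix(
            list(self.cpg_ids), [self.sample_ids[i] for i in keep], self.values[:, keep]
        )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    species: str
    tissue: str
    age_years: float
    sex: str = "unknown"
    cohort: str = ""

    def __post_init__(self):
        if self.age_years < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative age {self.age_years}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"sample {self.sample_id!r}: bad sex {self.sex!r}")
        if not self.cohort:
            object.__setattr__(
                self, "cohort", "human" if self.species == "human" else "frog"
            )


@dataclass(frozen=True)
class SpeciesInfo:
    max_lifespan_years: float
    maturity_years: float

    def __post_init__(self):
        if not (self.max_lifespan_years > self.maturity_years > 0):
            raise ValidationError(
                "need max_lifespan > maturity > 0, got "
                f"({self.max_lifespan_years}, {self.maturity_years})"
            )


@dataclass
class SpeciesRegistry:
    """Per-species lifespan/maturity constants driving all age transforms."""

    species: Mapping[str, SpeciesInfo] = field(default_factory=dict)

    def __getitem__(self, name: str) -> SpeciesInfo:
        try:
            return self.species[name]
        except KeyError:
            raise KeyError(f"species {name!r} not in registry") from None

    def __contains__(self, name: str) -> bool:
        return name in self.species


def default_registry() -> SpeciesRegistry:
    """Registry with the study's constants.

    Maximum lifespans (anAge): X. laevis 30.3 y, X. tropicalis 16 y, human
    122.5 y.  Ages at sexual maturity: 1 y (laevis), 0.375 y (tropicalis),
    13.5 y (human; a documented package default, configurable).
    """
    return SpeciesRegistry(
        {
            "laevis": SpeciesInfo(30.3, 1.0),
            "tropicalis": SpeciesInfo(16.0, 0.375),
            "human": SpeciesInfo(122.5, 13.5),
        }
    )


@dataclass
class MethylationCohort:
    """Beta matrix plus sample metadata, columns aligned to records."""

    beta: BetaMatrix
    samples: list

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if ids != list(self.beta.sample_ids):
            raise ValidationError("beta columns and sample records are not aligned")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_cpgs(self) -> int:
        return len(self.beta.cpg_ids)

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age_years for s in self.samples], dtype=float)

    @property
    def species(self) -> np.ndarray:
        return np.array([s.species for s in self.samples], dtype=object)

    @property
    def cohorts(self) -> np.ndarray:
        return np.array([s.cohort for s in self.samples], dtype=object)

    @property
    def tissues(self) -> np.ndarray:
        return np.array([s.tissue for s in self.samples], dtype=object)

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "species": self.species,
                "tissue": self.tissues,
                "age_years": self.ages,
                "sex": [s.sex for s in self.samples],
                "cohort": self.cohorts,
            }
        )

    def select_samples(self, mask) -> "MethylationCohort":
        mask = np.asarray(mask, dtype=bool)
        kept = [s for s, m in zip(self.samples, mask) if m]
        return MethylationCohort(
            self.beta.subset_samples([s.sample_id for s in kept]), kept
        )

    def select_cpgs(self, cpg_ids: Iterable[str]) -> "MethylationCohort":
        return MethylationCohort(self.beta.subset_cpgs(cpg_ids), list(self.samples))


@dataclass
class AnnotationSets:
    """Named CpG sets (e.g. PRC2 targets, chromatin states) over a background."""

    background: set
    named_sets: Mapping[str, set]

    def __post_init__(self):
        self.background = set(self.background)
        self.named_sets = {k: set(v) for k, v in self.named_sets.items()}
        for name, members in self.named_sets.items():
            extra = members - self.background
            if extra:
                raise ValidationError(
                    f"set {name!r} has members outside the background: "
                    f"{sorted(extra)[:5]}"
                )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _shortest_repr(v) -> str:
    """Shortest lossless decimal form, so write -> read is exact and
    re-writing is byte-identical."""
    return repr(float(v))


def read_beta_matrix(path, delimiter: str | None = None) -> BetaMatrix:
    """Read a CpG-by-sample beta matrix (first column CpG ids, header samples)."""
    sep = _delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:  # malformed text / header
        raise FormatError(f"cannot parse beta matrix {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"beta matrix {path} has no sample columns")
    nonnum = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if nonnum:
        raise FormatError(f"non-numeric beta columns in {path}: {nonnum}")
    return BetaMatrix(df.index.tolist(), df.columns.tolist(), df.to_numpy(float))


def write_beta_matrix(bm: BetaMatrix, path, delimiter: str | None = None) -> None:
    bm.to_frame().to_csv(path, sep=_delimiter(path, delimiter),
                         index_label="cpg_id", float_format=_shortest_repr)


def read_sample_sheet(path, delimiter: str | None = None) -> list:
    """Read a sample sheet; required columns sample_id, species, tissue,
    age_years; optional sex (default unknown) and cohort."""
    sep = _delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str},
                     float_precision="round_trip")
    required = ["sample_id", "species", "tissue", "age_years"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet {path} missing columns {missing}")
    _check_unique(df["sample_id"].tolist(), "sample ids")
    records = []
    for _, row in df.iterrows():
        sex = row.get("sex", "unknown")
        if pd.isna(sex) or sex == "":
            sex = "unknown"
        cohort = row.get("cohort", "")
        if pd.isna(cohort):
            cohort = ""
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                species=str(row["species"]),
                tissue=str(row["tissue"]),
                age_years=float(row["age_years"]),
                sex=str(sex),
                cohort=str(cohort),
            )
        )
    return records


def write_sample_sheet(samples: Sequence[SampleRecord], path,
                       delimiter: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "species": [s.species for s in samples],
            "tissue": [s.tissue for s in samples],
            "age_years": [s.age_years for s in samples],
            "sex": [s.sex for s in samples],
            "cohort": [s.cohort for s in samples],
        }
    )
    df.to_csv(path, sep=_delimiter(path, delimiter), index=False,
              float_format=_shortest_repr)


def read_annotation_sets(sets_path, background_path,
                         delimiter: str | None = None) -> AnnotationSets:
    """Read named sets (two columns: set_name, cpg_id) and a one-column
    background file."""
    sep = _delimiter(sets_path, delimiter)
    sets_df = pd.read_csv(sets_path, sep=sep)
    if not {"set_name", "cpg_id"}.issubset(sets_df.columns):
        raise FormatError(f"{sets_path} must have columns set_name, cpg_id")
    bg = pd.read_csv(background_path, sep=_delimiter(background_path, delimiter))
    background = set(bg.iloc[:, 0].astype(str))
    named = {
        name: set(group["cpg_id"].astype(str))
        for name, group in sets_df.groupby("set_name", sort=True)
    }
    return AnnotationSets(background=background, named_sets=named)


def write_annotation_sets(sets: AnnotationSets, sets_path, background_path,
                          delimiter: str | None = None) -> None:
    rows = [
        {"set_name": name, "cpg_id": cpg}
        for name in sorted(sets.named_sets)
        for cpg in sorted(sets.named_sets[name])
    ]
    pd.DataFrame(rows, columns=["set_name", "cpg_id"]).to_csv(
        sets_path, sep=_delimiter(sets_path, delimiter), index=False
    )
    pd.DataFrame({"cpg_id": sorted(sets.background)}).to_csv(
        background_path, sep=_delimiter(background_path, delimiter), index=False
    )


def assemble_cohort(beta: BetaMatrix, samples: Sequence[SampleRecord]) -> MethylationCohort:
    """Join a beta matrix with a sample sheet.

    The sheet may be a superset of the matrix columns; the cohort is
    restricted to the intersection, in sheet order.  A beta column with no
    sheet record is an error.
    """
    sheet_ids = [s.sample_id for s in samples]
    _check_unique(sheet_ids, "sample ids")
    beta_set = set(beta.sample_ids)
    orphans = sorted(beta_set - set(sheet_ids))
    if orphans:
        raise ValidationError(f"beta columns without sample records: {orphans}")
    kept = [s for s in samples if s.sample_id in beta_set]
    return MethylationCohort(
        beta.subset_samples([s.sample_id for s in kept]), kept
    )


def handle_missing(cohort: MethylationCohort, policy: str = "drop") -> MethylationCohort:
    """Resolve missing betas: ``drop`` CpGs with any NaN, or ``impute`` the
    per-CpG mean."""
    values = cohort.beta.values
    nan_rows = np.isnan(values).any(axis=1)
    if not nan_rows.any():
        return cohort
    if policy == "drop":
        keep = [c for c, bad in zip(cohort.beta.cpg_ids, nan_rows) if not bad]
        return cohort.select_cpgs(keep)
    if policy == "impute":
        filled = values.copy()
        means = np.nanmean(values, axis=1)
        ii, jj = np.nonzero(np.isnan(values))
        filled[ii, jj] = means[ii]
        bm = BetaMatrix(list(cohort.beta.cpg_ids), list(cohort.beta.sample_ids), filled)
        return MethylationCohort(bm, list(cohort.samples))
    raise ValueError(f"unknown missing-data policy {policy!r}")
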