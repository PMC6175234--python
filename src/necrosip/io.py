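"""Readers, writers and validated containers for the pipeline's boundary formats.

Four kinds of input move through the pipeline: phylotype x sample read-count
tables (TSV), sample metadata describing the incubation design (TSV),
single-cell Raman spectra (CSV, one column per cell), and reaction-condition
files for the energetics module (YAML, see :mod:`necrosip.thermo`).  All
validation happens here, at the boundary; downstream code may assume the
invariants hold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CountTable",
    "SampleMetadata",
    "SpectrumSet",
    "AnalysisConfig",
    "read_count_table",
    "write_count_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_spectra",
    "write_spectra",
    "write_report",
    "read_report",
]

SUBSTRATES = ("none", "spirulina", "acetate")
ISOTOPES = ("none", "12C", "13C")
DOSES = ("none", "LD", "HD")
INHIBITORS = ("none", "molybdate")
MOLECULES = ("DNA", "RNA")

METADATA_COLUMNS = (
    "sample_id",
    "day",
    "substrate",
    "isotope",
    "dose",
    "inhibitor",
    "molecule",
    "replicate",
)


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True)
class CountTable:
    """Phylotype x sample table of non-negative integer read counts.

    Rows are phylotypes, columns are samples.  This is the unit of all
    abundance statistics in the pipeline.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("count table has no data rows or no samples")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate phylotype ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count table contains non-numeric cells")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("count table contains missing values")
        if (values < 0).any():
            raise ValidationError("negative read counts are not allowed")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("read counts must be integral")
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def phylotype_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_depths(self) -> pd.Series:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return CountTable(self.counts.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class SampleMetadata:
    """Design attributes of each sequencing library.

    One row per sample: incubation day, substrate amendment (none, spirulina
    necromass, or acetate), carbon isotope of the substrate, dose (low/high),
    sulfate-reduction inhibitor (molybdate) and the molecule sequenced
    (DNA = 16S rRNA genes, RNA = 16S rRNA transcripts).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        df = df.loc[:, list(METADATA_COLUMNS)].copy()
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        if df[list(METADATA_COLUMNS)].isna().any().any():
            raise ValidationError("missing metadata fields are errors, not defaults")
        for col, allowed in (
            ("substrate", SUBSTRATES),
            ("isotope", ISOTOPES),
            ("dose", DOSES),
            ("inhibitor", INHIBITORS),
            ("molecule", MOLECULES),
        ):
            bad = set(df[col]) - set(allowed)
            if bad:
                raise ValidationError(f"invalid {col} values: {sorted(bad)}")
        df["day"] = df["day"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate must be >= 1")
        none_rows = df["substrate"] == "none"
        if ((df.loc[none_rows, "isotope"] != "none") | (df.loc[none_rows, "dose"] != "none")).any():
            raise ValidationError("substrate=none requires isotope=none and dose=none")
        object.__setattr__(self, "table", df.set_index("sample_id", drop=False))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def validate_against(self, counts: CountTable) -> None:
        """Every sample in the count table must have exactly one metadata row."""
        missing = set(counts.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")

    def select(self, **criteria: Any) -> pd.DataFrame:
        """Rows matching all keyword criteria, e.g. select(substrate='acetate', molecule='RNA')."""
        df = self.table
        for key, value in criteria.items():
            df = df[df[key] == value]
        return df


@dataclass(frozen=True)
class SpectrumSet:
    """Single-cell Raman spectra on a common wavenumber grid.

    ``intensities`` has one row per cell; ``population`` labels each cell with
    its probe-targeted phylotype, "random" for randomly picked cells, or
    "negative" for unlabeled (12C) controls.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    cell_ids: list[str]
    population: list[str]

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise ValidationError("wavenumber grid must be a 1-D vector of length >= 2")
        if np.any(np.diff(wn) <= 0):
            raise ValidationError("wavenumbers not increasing")
        if inten.ndim != 2 or inten.shape[1] != wn.size:
            raise ValidationError(
                f"intensity matrix shape {inten.shape} does not match grid length {wn.size}"
            )
        if inten.shape[0] != len(self.cell_ids):
            raise ValidationError("one intensity row per cell id required")
        if len(self.population) != len(self.cell_ids):
            raise ValidationError("each cell needs exactly one population label")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "cell_ids", list(self.cell_ids))
        object.__setattr__(self, "population", list(self.population))

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p, None)
        return list(seen)

    def cells_in(self, population: str) -> np.ndarray:
        """Row indices of the cells in one population."""
        return np.flatnonzero(np.asarray(self.population) == population)


@dataclass
class AnalysisConfig:
    """Knobs shared across the abundance-statistics stages.

    alpha
        BH-corrected significance cutoff for enrichment calls (default 0.01).
    min_libraries
        A phylotype must be significantly enriched in at least this many
        treatment-vs-control library pairs to count as responsive (default 2).
    rarefaction_depth, n_resamples
        Re-sampling depth and replicate count for alpha diversity
        (defaults 3250 reads, 100 re-samples).
    """

    alpha: float = 0.01
    min_libraries: int = 2
    rarefaction_depth: int = 3250
    n_resamples: int = 100
    continuity_correction: bool = False
    min_abundance: float = 0.0  # optional prefilter on max relative abundance; off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.min_libraries < 1:
            raise ValidationError("min_libraries must be >= 1")
        if self.rarefaction_depth < 1:
            raise ValidationError("rarefaction_depth must be >= 1")
        if self.n_resamples < 1:
            raise ValidationError("n_resamples must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (first column ``phylotype_id``, one column per sample)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no data rows")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{path}: malformed numeric cell at phylotype {row!r}, sample {col!r}"
            )
        df[col] = coerced
    df.index = df.index.astype(str)
    df.index.name = "phylotype_id"
    return CountTable(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "phylotype_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# spectra

_POP_SEP = "|"


def read_spectra(path: str | Path) -> SpectrumSet:
    """Read a spectra CSV: first column ``wavenumber_cm1``, one column per cell.

    Cell columns are headed ``cell_id|population`` so the population label
    travels with the data.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need a wavenumber column and at least one cell")
    if df.columns[0] != "wavenumber_cm1":
        raise ValidationError(f"{path}: first column must be 'wavenumber_cm1'")
    if df.isna().any().any():
        raise ValidationError(f"{path}: mismatched column lengths or missing values")
    cell_ids, populations = [], []
    for col in df.columns[1:]:
        if _POP_SEP not in col:
            raise ValidationError(
                f"{path}: cell column {col!r} lacks a '|population' suffix"
            )
        cid, pop = col.rsplit(_POP_SEP, 1)
        cell_ids.append(cid)
        populations.append(pop)
    return SpectrumSet(
        wavenumbers=df["wavenumber_cm1"].to_numpy(float),
        intensities=df.iloc[:, 1:].to_numpy(float).T,
        cell_ids=cell_ids,
        population=populations,
    )


def write_spectra(spectra: SpectrumSet, path: str | Path) -> None:
    data = {"wavenumber_cm1": spectra.wavenumbers}
    for i, (cid, pop) in enumerate(zip(spectra.cell_ids, spectra.population)):
        data[f"{cid}{_POP_SEP}{pop}"] = spectra.intensities[i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and np.isinf(obj):
        return "Infinity" if obj > 0 else "-Infinity"
    return obj


def write_report(results: Any, path: str | Path) -> None:
    """Serialize a result collection to JSON with full double precision."""
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, allow_nan=True)
        fh.write("\n")


def read_report(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)


def write_table_report(df: pd.DataFrame, path: str | Path) -> None:
    """Flat TSV report for tabular results."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
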