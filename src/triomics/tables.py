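"""Feature-abundance tables, cohort metadata and KO-to-module maps.

The three omics layers (species relative abundances, KO functional
abundances, serum metabolite feature intensities) all travel through the
same container, :class:`AbundanceTable` — a dense features x samples
matrix with string identifiers.  Per-sample clinical information (the
ordered disease-stage label and continuous phenotypes such as Gensini,
Syntax, cTnI or TIMI scores) lives in :class:`CohortMetadata`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("triomics")

TABLE_KINDS = ("species", "ko", "metabolite")

#: Ordered disease-stage labels: healthy control < stable CAD < myocardial
#: infarction.  "CAD" is accepted as the pooled SCAD+MI contrast label.
GROUP_ORDER = ("HC", "SCAD", "MI")
POOLED_CAD = "CAD"


class IdentifierError(ValueError):
    """Duplicate or unknown feature/sample identifiers."""


class DegenerateSampleError(ValueError):
    """A sample column carries no signal (all zeros)."""


class TableFormatError(ValueError):
    """Malformed delimited input (ragged rows, non-numeric cells)."""


@dataclass
class AbundanceTable:
    """Dense features x samples non-negative matrix with identifiers.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id, columns are sample ids.
    kind:
        One of ``"species"``, ``"ko"``, ``"metabolite"``.
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in TABLE_KINDS:
            raise ValueError(f"unknown table kind {self.kind!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise IdentifierError(f"duplicate feature ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise IdentifierError(f"duplicate sample ids: {dups}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise ValueError(
                f"need at least 1 feature and 2 samples, got {self.data.shape}"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableFormatError("non-numeric cells in abundance table")
        if not np.isfinite(values).all():
            raise ValueError("non-finite values in abundance table")
        if (values < 0).any():
            raise ValueError("negative values in abundance table")
        self.data = self.data.astype(float)
        self.data.index.name = "feature_id"
        self.data.columns.name = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids: list[str]) -> "AbundanceTable":
        missing = set(feature_ids) - set(self.data.index)
        if missing:
            raise IdentifierError(f"unknown feature ids: {sorted(missing)}")
        return AbundanceTable(self.data.loc[feature_ids], self.kind)

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        missing = set(sample_ids) - set(self.data.columns)
        if missing:
            raise IdentifierError(f"unknown sample ids: {sorted(missing)}")
        return AbundanceTable(self.data[list(sample_ids)], self.kind)


@dataclass
class CohortMetadata:
    """Per-sample group label plus continuous clinical phenotypes.

    ``group`` values must come from ``group_order`` (default HC < SCAD <
    MI).  Phenotype columns may contain missing values; they are excluded
    pairwise downstream.
    """

    frame: pd.DataFrame
    group_order: tuple[str, ...] = GROUP_ORDER

    def __post_init__(self) -> None:
        if "group" not in self.frame.columns:
            raise ValueError("metadata must contain a 'group' column")
        if self.frame.index.duplicated().any():
            raise IdentifierError("duplicate sample ids in metadata")
        bad = set(self.frame["group"]) - set(self.group_order)
        if bad:
            raise ValueError(
                f"group labels {sorted(bad)} not in declared order {self.group_order}"
            )
        self.frame.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def group(self) -> pd.Series:
        return self.frame["group"]

    @property
    def phenotype_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != "group"]

    def phenotype(self, name: str) -> pd.Series:
        if name not in self.frame.columns or name == "group":
            raise KeyError(f"phenotype {name!r} not in metadata")
        return self.frame[name]

    def samples_in_group(self, label: str) -> list[str]:
        """Sample ids in one group; ``"CAD"`` pools SCAD and MI."""
        if label == POOLED_CAD:
            mask = self.group.isin([g for g in self.group_order if g != self.group_order[0]])
        else:
            if label not in self.group_order:
                raise ValueError(f"unknown group label {label!r}")
            mask = self.group == label
        return list(self.frame.index[mask])

    def group_index(self) -> pd.Series:
        """Integer stage index per sample (0 = first group in the order)."""
        mapping = {g: i for i, g in enumerate(self.group_order)}
        return self.group.map(mapping)


@dataclass
class ModuleMap:
    """Many-to-many KO -> KEGG-module membership."""

    entries: pd.DataFrame  # columns: ko_id, module_id
    module_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"ko_id", "module_id"}
        if not need.issubset(self.entries.columns):
            raise ValueError("module map needs ko_id and module_id columns")
        if self.entries.duplicated(subset=["ko_id", "module_id"]).any():
            raise ValueError("duplicate (ko_id, module_id) pairs in module map")

    @property
    def module_ids(self) -> list[str]:
        return list(pd.unique(self.entries["module_id"]))

    def kos_in_module(self, module_id: str) -> list[str]:
        sub = self.entries.loc[self.entries["module_id"] == module_id, "ko_id"]
        return list(sub)

    def as_dict(self) -> dict[str, list[str]]:
        """module_id -> list of member KO ids (one pass over the entries)."""
        out: dict[str, list[str]] = {}
        for ko, mod in zip(self.entries["ko_id"], self.entries["module_id"]):
            out.setdefault(mod, []).append(ko)
        return out


# ---------------------------------------------------------------------------
# I/O


def _check_header(path) -> None:
    # pandas silently mangles duplicate header labels; detect them first
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = [h for h in set(header[1:]) if header[1:].count(h) > 1]
    if dupes:
        raise IdentifierError(f"duplicate sample ids in header: {sorted(dupes)}")


def read_abundance_table(path, kind: str) -> AbundanceTable:
    """Read a TSV with feature ids in the first column, sample header row."""
    _check_header(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", index_col=0, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:  # ragged rows
        raise TableFormatError(f"malformed table {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            raise TableFormatError(f"non-numeric column {col!r} in {path}")
    return AbundanceTable(frame, kind)


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path, group_order: tuple[str, ...] = GROUP_ORDER) -> CohortMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    return CohortMetadata(frame, group_order)


def write_metadata(meta: CohortMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_module_map(path) -> ModuleMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise TableFormatError("module map needs at least 2 columns")
    frame = frame.rename(
        columns={frame.columns[0]: "ko_id", frame.columns[1]: "module_id"}
    )
    return ModuleMap(frame[["ko_id", "module_id"]])


def write_module_map(mmap: ModuleMap, path) -> None:
    mmap.entries.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transformations


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Close each sample column to sum 1.  Zeros are preserved."""
    sums = table.data.sum(axis=0)
    dead = sums[sums <= 0]
    if len(dead):
        raise DegenerateSampleError(
            f"all-zero sample column(s): {list(dead.index)}"
        )
    return AbundanceTable(table.data.div(sums, axis=1), table.kind)


def filter_prevalence(table: AbundanceTable, min_prevalence: float) -> AbundanceTable:
    """Keep features detected (non-zero) in strictly more than
    ``min_prevalence`` of samples.  Boundary features are dropped."""
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    prev = (table.data > 0).mean(axis=1)
    keep = prev > min_prevalence
    kept = table.data.loc[keep]
    if kept.shape[0] == 0:
        # empty result is allowed here even though a populated table
        # requires >= 1 feature; bypass validation for the empty carrier
        logger.warning("prevalence filter removed every feature")
        obj = AbundanceTable.__new__(AbundanceTable)
        obj.data = table.data.iloc[:0]
        obj.kind = table.kind
        return obj
    return AbundanceTable(kept, table.kind)


def align_samples(
    table: AbundanceTable, meta: CohortMetadata
) -> tuple[AbundanceTable, CohortMetadata]:
    """Intersect sample ids between a table and metadata.

    Non-overlap is logged; an empty intersection is an error.
    """
    shared = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    if not shared:
        raise IdentifierError("no shared samples between table and metadata")
    n_drop = (len(table.sample_ids) - len(shared)) + (len(meta.sample_ids) - len(shared))
    if n_drop:
        logger.warning("sample alignment dropped %d non-overlapping ids", n_drop)
    return (
        table.subset_samples(shared),
        CohortMetadata(meta.frame.loc[shared], meta.group_order),
    )
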