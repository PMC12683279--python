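"""Feature-table, taxonomy and sample-metadata handling.

Tables are tab-separated text: the first column holds taxon identifiers,
the header row holds sample identifiers, and cells are non-negative
numbers.  Metadata and taxonomy files are TSV with fixed column sets.
All transforms here are deterministic and operate on labelled matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNCLASSIFIED = "UNCLASSIFIED"
#: subject_id sentinel used for negative-control samples
CONTROL_SUBJECT = "none"


class ValidationError(ValueError):
    """Raised when an input file or table violates its contract."""


class SampleClass(str, Enum):
    SKIN = "skin"
    OBJECT = "object"
    NEGATIVE_CONTROL = "negative_control"


class Site(str, Enum):
    FOREHEAD = "forehead"
    LEFT_HAND = "left_hand"
    RIGHT_HAND = "right_hand"
    NONE = "none"


class TimePoint(str, Enum):
    T0 = "t0"
    T1 = "t1"
    T2 = "t2"
    NONE = "none"


class ObjectType(str, Enum):
    CELL_PHONE = "cell_phone"
    DOOR_HANDLE = "door_handle"
    FABRIC = "fabric"
    PLASTIC = "plastic"
    NONE = "none"


SITES: tuple[Site, ...] = (Site.FOREHEAD, Site.LEFT_HAND, Site.RIGHT_HAND)
TIME_POINTS: tuple[TimePoint, ...] = (TimePoint.T0, TimePoint.T1, TimePoint.T2)
OBJECT_TYPES: tuple[ObjectType, ...] = (
    ObjectType.CELL_PHONE,
    ObjectType.DOOR_HANDLE,
    ObjectType.FABRIC,
    ObjectType.PLASTIC,
)

RANKS = ("species", "family", "higher_rank")

METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "sample_class",
    "site",
    "time_point",
    "object_type",
)
TAXONOMY_COLUMNS = ("taxon_id", "species", "family", "higher_rank")


def _parse_enum(enum_cls: type[Enum], token: str, column: str) -> Enum:
    try:
        return enum_cls(token)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise ValidationError(
            f"unknown token {token!r} in column {column!r}; allowed: {allowed}"
        ) from None


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample study metadata.

    Skin samples carry a site and a time point; object samples carry an
    object type; negative controls carry the ``none`` subject sentinel.
    """

    sample_id: str
    subject_id: str
    sample_class: SampleClass
    site: Site = Site.NONE
    time_point: TimePoint = TimePoint.NONE
    object_type: ObjectType = ObjectType.NONE

    def __post_init__(self) -> None:
        sc = self.sample_class
        if sc is SampleClass.SKIN:
            if self.site is Site.NONE or self.time_point is TimePoint.NONE:
                raise ValidationError(
                    f"skin sample {self.sample_id!r} must have a site and a time point"
                )
            if self.object_type is not ObjectType.NONE:
                raise ValidationError(
                    f"skin sample {self.sample_id!r} must not carry an object type"
                )
            if self.subject_id == CONTROL_SUBJECT:
                raise ValidationError(
                    f"skin sample {self.sample_id!r} must name a subject"
                )
        elif sc is SampleClass.OBJECT:
            if self.object_type is ObjectType.NONE:
                raise ValidationError(
                    f"object sample {self.sample_id!r} must have an object type"
                )
            if self.site is not Site.NONE:
                raise ValidationError(
                    f"object sample {self.sample_id!r} must not carry a site"
                )
            if self.subject_id == CONTROL_SUBJECT:
                raise ValidationError(
                    f"object sample {self.sample_id!r} must name a subject"
                )
        elif sc is SampleClass.NEGATIVE_CONTROL:
            if self.subject_id != CONTROL_SUBJECT:
                raise ValidationError(
                    f"negative control {self.sample_id!r} must use subject_id "
                    f"{CONTROL_SUBJECT!r}"
                )


@dataclass(frozen=True)
class TaxonLineage:
    """Lineage labels for one taxon; ``UNCLASSIFIED`` marks unknown ranks."""

    taxon_id: str
    species: str
    family: str
    higher_rank: str

    def label(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; allowed: {RANKS}")
        return getattr(self, rank)


class Taxonomy:
    """A set of :class:`TaxonLineage` records keyed by taxon_id."""

    def __init__(self, lineages: Iterable[TaxonLineage]):
        self._by_id: dict[str, TaxonLineage] = {}
        for lin in lineages:
            if lin.taxon_id in self._by_id:
                raise ValidationError(f"duplicate taxon_id {lin.taxon_id!r} in taxonomy")
            self._by_id[lin.taxon_id] = lin

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._by_id

    def __getitem__(self, taxon_id: str) -> TaxonLineage:
        try:
            return self._by_id[taxon_id]
        except KeyError:
            raise ValidationError(f"taxon {taxon_id!r} missing from taxonomy") from None

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def rank_label(self, taxon_id: str, rank: str) -> str:
        return self[taxon_id].label(rank)

    def species_to_family(self) -> dict[str, str]:
        """Map each classified species label to its family label.

        Conflicting family assignments for the same species label keep the
        first one seen and emit a warning.
        """
        mapping: dict[str, str] = {}
        for lin in self:
            if lin.species == UNCLASSIFIED:
                continue
            if lin.species in mapping and mapping[lin.species] != lin.family:
                warnings.warn(
                    f"species {lin.species!r} maps to multiple families; "
                    f"keeping {mapping[lin.species]!r}",
                    stacklevel=2,
                )
                continue
            mapping[lin.species] = lin.family
        return mapping


class AbundanceTable:
    """A non-negative taxon-by-sample matrix with unique row/column labels."""

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        if validate:
            _check_labels(data.index, "taxon_id")
            _check_labels(data.columns, "sample_id")
            values = data.to_numpy()
            if values.size and not np.issubdtype(values.dtype, np.number):
                raise ValidationError("table cells must be numeric")
            if values.size and np.isnan(values.astype(float)).any():
                r, c = np.argwhere(np.isnan(values.astype(float)))[0]
                raise ValidationError(
                    f"missing value at taxon {data.index[r]!r}, sample {data.columns[c]!r}"
                )
            if values.size and (values < 0).any():
                r, c = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative value at taxon {data.index[r]!r}, "
                    f"sample {data.columns[c]!r}"
                )
        self.data = data

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def equals(self, other: "AbundanceTable") -> bool:
        return (
            self.taxa == other.taxa
            and self.samples == other.samples
            and np.allclose(self.values.astype(float), other.values.astype(float))
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<{type(self).__name__} {self.shape[0]} taxa x {self.shape[1]} samples>"


class PresenceMatrix(AbundanceTable):
    """Binary detection matrix; entries are exactly 0 or 1."""

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        super().__init__(data, validate=validate)
        if validate:
            values = self.values
            if values.size and not np.isin(values, (0, 1)).all():
                raise ValidationError("presence matrix entries must be 0 or 1")


def _check_labels(labels: Sequence, what: str) -> None:
    seen: set = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} {lab!r}")
        seen.add(lab)


# ---------------------------------------------------------------------------
# file I/O


def read_abundance_table(path: str | Path) -> AbundanceTable:
    """Read a TSV feature table (rows = taxa, columns = samples)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValidationError(f"{path}: header must name at least one sample")
    _check_labels(header[1:], "sample_id")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    _check_labels(raw.index, "taxon_id")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at taxon "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: empty cell at taxon {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if values.size and np.allclose(values, np.round(values)):
        numeric = numeric.astype(np.int64)
    return AbundanceTable(numeric)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV into validated records."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("none")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                subject_id=row.subject_id,
                sample_class=_parse_enum(SampleClass, row.sample_class, "sample_class"),
                site=_parse_enum(Site, row.site, "site"),
                time_point=_parse_enum(TimePoint, row.time_point, "time_point"),
                object_type=_parse_enum(ObjectType, row.object_type, "object_type"),
            )
        )
    _check_labels([r.sample_id for r in records], "sample_id")
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "subject_id": r.subject_id,
            "sample_class": r.sample_class.value,
            "site": r.site.value,
            "time_point": r.time_point.value,
            "object_type": r.object_type.value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing taxonomy columns {missing}")
    return Taxonomy(
        TaxonLineage(row.taxon_id, row.species, row.family, row.higher_rank)
        for row in df.itertuples(index=False)
    )


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    rows = [
        {
            "taxon_id": lin.taxon_id,
            "species": lin.species,
            "family": lin.family,
            "higher_rank": lin.higher_rank,
        }
        for lin in taxonomy
    ]
    pd.DataFrame(rows, columns=list(TAXONOMY_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# metadata helpers


def records_by_id(records: Sequence[SampleRecord]) -> dict[str, SampleRecord]:
    return {r.sample_id: r for r in records}


def skin_records(records: Sequence[SampleRecord]) -> list[SampleRecord]:
    return [r for r in records if r.sample_class is SampleClass.SKIN]


def object_records(records: Sequence[SampleRecord]) -> list[SampleRecord]:
    return [r for r in records if r.sample_class is SampleClass.OBJECT]


def control_records(records: Sequence[SampleRecord]) -> list[SampleRecord]:
    return [r for r in records if r.sample_class is SampleClass.NEGATIVE_CONTROL]


def subjects(records: Sequence[SampleRecord]) -> list[str]:
    """Sorted unique non-control subject identifiers."""
    return sorted(
        {r.subject_id for r in records if r.sample_class is not SampleClass.NEGATIVE_CONTROL}
    )


# ---------------------------------------------------------------------------
# table transforms


def binarize(table: AbundanceTable, min_count: int | float = 1) -> PresenceMatrix:
    """Threshold counts into a 0/1 detection matrix (count >= min_count -> 1)."""
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    data = (table.data >= min_count).astype(np.int64)
    return PresenceMatrix(data, validate=False)


def aggregate_to_rank(
    table: AbundanceTable,
    taxonomy: Taxonomy,
    rank: str,
    drop_unclassified: bool = True,
) -> AbundanceTable:
    """Sum rows that share the same lineage label at ``rank``.

    Taxa labelled ``UNCLASSIFIED`` at that rank are removed before summing
    when ``drop_unclassified`` is set.  Output rows are sorted by label.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; allowed: {RANKS}")
    labels = [taxonomy.rank_label(t, rank) for t in table.taxa]
    data = table.data.copy()
    data.index = pd.Index(labels, name=rank)
    if drop_unclassified:
        data = data.loc[data.index != UNCLASSIFIED]
    grouped = data.groupby(level=0, sort=True).sum()
    return AbundanceTable(grouped, validate=False)


def collapse_presence(
    presence: PresenceMatrix,
    taxonomy: Taxonomy,
    rank: str,
    drop_unclassified: bool = True,
) -> PresenceMatrix:
    """Collapse a presence matrix to ``rank``: detection is the OR over members."""
    summed = aggregate_to_rank(presence, taxonomy, rank, drop_unclassified)
    return binarize(summed, 1)


def relative_abundance(
    table: AbundanceTable, on_empty: str = "error"
) -> AbundanceTable:
    """Scale each sample column to proportions summing to 1.

    ``on_empty`` controls all-zero columns: ``"error"`` raises, ``"zero"``
    leaves the column at zero and warns.
    """
    totals = table.data.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        if on_empty == "error":
            raise ValidationError(f"all-zero sample column(s): {empty}")
        if on_empty != "zero":
            raise ValidationError(f"on_empty must be 'error' or 'zero', got {on_empty!r}")
        warnings.warn(f"all-zero sample column(s) left at zero: {empty}", stacklevel=2)
    safe = totals.replace(0, 1)
    return AbundanceTable(table.data.astype(float).div(safe, axis=1), validate=False)


def host_pooled_profile(
    table: AbundanceTable,
    metadata: Sequence[SampleRecord],
    subject_id: str,
) -> AbundanceTable:
    """Sum all of one subject's skin-sample columns into a single profile."""
    ids = [
        r.sample_id
        for r in skin_records(metadata)
        if r.subject_id == subject_id and r.sample_id in set(table.samples)
    ]
    if not ids:
        raise ValidationError(f"subject {subject_id!r} has no skin samples in the table")
    pooled = table.data[ids].sum(axis=1).to_frame(name=subject_id)
    return AbundanceTable(pooled, validate=False)


def top_k_features(table: AbundanceTable, k: int) -> list[str]:
    """The k taxa with the largest row sums, descending; ties break by label."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    sums = table.data.sum(axis=1)
    order = sorted(table.taxa, key=lambda t: (-sums[t], t))
    return order[:k]


def remove_control_taxa(
    presence: PresenceMatrix, metadata: Sequence[SampleRecord]
) -> PresenceMatrix:
    """Zero every taxon detected in any negative control; drop control columns."""
    control_ids = [
        r.sample_id for r in control_records(metadata) if r.sample_id in set(presence.samples)
    ]
    data = presence.data.copy()
    if control_ids:
        contaminated = data[control_ids].sum(axis=1) > 0
        data.loc[contaminated, :] = 0
    keep = [s for s in presence.samples if s not in set(control_ids)]
    return PresenceMatrix(data[keep], validate=False)
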