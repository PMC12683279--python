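"""Marker selection from presence/absence profiles.

Families that persist over time on a subject's skin (detected at a minimum
number of time points per anatomical site, across all three sites of at
least one subject) and that transfer to a minimum number of the subject's
contacted objects are intersected into marker families; the species of
those families become the candidate marker set.  Individual specificity is
quantified by comparing within-subject to between-subject Jaccard
distances with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import profiles as pf
from .profiles import (
    OBJECT_TYPES,
    SITES,
    AbundanceTable,
    PresenceMatrix,
    SampleRecord,
    Taxonomy,
    ValidationError,
)
from .stats import DissimilarityMatrix, TestResult, jaccard_matrix, wilcoxon_rank_sum


@dataclass(frozen=True)
class StabilityCall:
    """Detection count for one (subject, site, family) over the site's time points."""

    subject_id: str
    site: pf.Site
    family: str
    n_timepoints_detected: int
    stable: bool


@dataclass(frozen=True)
class TransferCall:
    """Detection count for one (subject, family) over the subject's objects."""

    subject_id: str
    family: str
    n_objects_detected: int
    transmissible: bool


@dataclass
class WithinBetweenResult:
    """Per-subject mean within/between distances plus the rank-sum test."""

    per_subject_within: dict[str, float]
    per_subject_between: dict[str, float]
    wilcoxon: TestResult

    def to_dict(self) -> dict:
        return {
            "per_subject_within": self.per_subject_within,
            "per_subject_between": self.per_subject_between,
            "wilcoxon": self.wilcoxon.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WithinBetweenResult":
        return cls(
            per_subject_within=dict(d["per_subject_within"]),
            per_subject_between=dict(d["per_subject_between"]),
            wilcoxon=TestResult(**d["wilcoxon"]),
        )


@dataclass
class MarkerConfig:
    """Thresholds and switches for the marker analysis."""

    min_count: int = 1
    min_timepoints: int = 2
    min_objects: int = 2
    min_subjects: int = 1
    require_all_sites: bool = True
    host_required: bool = True
    control_filter: bool = True
    drop_unclassified: bool = True
    wilcoxon_mode: str = "auto"
    per_subject_means: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MarkerReport:
    """Everything the marker analysis produces, JSON-serialisable."""

    stable_families: set[str] = field(default_factory=set)
    transmissible_families: set[str] = field(default_factory=set)
    marker_families: set[str] = field(default_factory=set)
    marker_species: set[str] = field(default_factory=set)
    occurrence_skin: pd.DataFrame | None = None
    occurrence_objects: pd.DataFrame | None = None
    transfer_profile: pd.DataFrame | None = None
    skin_comparison: WithinBetweenResult | None = None
    object_comparison: WithinBetweenResult | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def frame(df):
            if df is None:
                return None
            return {
                "index": list(df.index),
                "columns": list(df.columns),
                "values": df.to_numpy().tolist(),
            }

        return {
            "stable_families": sorted(self.stable_families),
            "transmissible_families": sorted(self.transmissible_families),
            "marker_families": sorted(self.marker_families),
            "marker_species": sorted(self.marker_species),
            "occurrence_skin": frame(self.occurrence_skin),
            "occurrence_objects": frame(self.occurrence_objects),
            "transfer_profile": frame(self.transfer_profile),
            "skin_comparison": self.skin_comparison.to_dict() if self.skin_comparison else None,
            "object_comparison": self.object_comparison.to_dict()
            if self.object_comparison
            else None,
            "config": self.config,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "MarkerReport":
        with open(path) as fh:
            d = json.load(fh)

        def unframe(obj):
            if obj is None:
                return None
            return pd.DataFrame(obj["values"], index=obj["index"], columns=obj["columns"])

        return cls(
            stable_families=set(d["stable_families"]),
            transmissible_families=set(d["transmissible_families"]),
            marker_families=set(d["marker_families"]),
            marker_species=set(d["marker_species"]),
            occurrence_skin=unframe(d["occurrence_skin"]),
            occurrence_objects=unframe(d["occurrence_objects"]),
            transfer_profile=unframe(d["transfer_profile"]),
            skin_comparison=WithinBetweenResult.from_dict(d["skin_comparison"])
            if d["skin_comparison"]
            else None,
            object_comparison=WithinBetweenResult.from_dict(d["object_comparison"])
            if d["object_comparison"]
            else None,
            config=d.get("config", {}),
        )


# ---------------------------------------------------------------------------
# stability


def site_stability(
    presence: PresenceMatrix,
    metadata: Sequence[SampleRecord],
    min_timepoints: int = 2,
) -> list[StabilityCall]:
    """Count, per (subject, site, family), the time points with a detection.

    ``presence`` must be collapsed to family rank.  Subject/site groups with
    no samples in the matrix are skipped with a warning.
    """
    if min_timepoints < 1:
        raise ValidationError("min_timepoints must be >= 1")
    cols = set(presence.samples)
    groups: dict[tuple[str, pf.Site], list[str]] = defaultdict(list)
    for rec in pf.skin_records(metadata):
        if rec.sample_id in cols:
            groups[(rec.subject_id, rec.site)].append(rec.sample_id)
    calls: list[StabilityCall] = []
    for (subject, site), ids in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        if not ids:  # pragma: no cover - defensive
            warnings.warn(f"no time points for {subject}/{site.value}; skipped", stacklevel=2)
            continue
        counts = presence.data[ids].sum(axis=1)
        for family, c in counts.items():
            calls.append(
                StabilityCall(
                    subject_id=subject,
                    site=site,
                    family=str(family),
                    n_timepoints_detected=int(c),
                    stable=bool(c >= min_timepoints),
                )
            )
    return calls


def stable_families(
    calls: Sequence[StabilityCall],
    require_all_sites: bool = True,
    min_subjects: int = 1,
) -> set[str]:
    """Families stable across all three anatomical sites.

    Default (strict) reading: a family qualifies when at least
    ``min_subjects`` subjects have it stable at all three of their own
    sites.  With ``require_all_sites=False`` the looser per-site reading is
    used: at each site at least ``min_subjects`` subjects (not necessarily
    the same ones) must have the family stable.
    """
    if min_subjects < 1:
        raise ValidationError("min_subjects must be >= 1")
    if require_all_sites:
        sites_stable: dict[tuple[str, str], set[pf.Site]] = defaultdict(set)
        for c in calls:
            if c.stable:
                sites_stable[(c.subject_id, c.family)].add(c.site)
        per_family: dict[str, int] = defaultdict(int)
        for (subject, family), sites in sites_stable.items():
            if len(sites & set(SITES)) == len(SITES):
                per_family[family] += 1
        return {f for f, n in per_family.items() if n >= min_subjects}
    per_site: dict[pf.Site, dict[str, int]] = {s: defaultdict(int) for s in SITES}
    for c in calls:
        if c.stable and c.site in per_site:
            per_site[c.site][c.family] += 1
    qualified = [
        {f for f, n in counts.items() if n >= min_subjects} for counts in per_site.values()
    ]
    return set.intersection(*qualified) if qualified else set()


# ---------------------------------------------------------------------------
# transmissibility


def transmissible_families(
    presence: PresenceMatrix,
    metadata: Sequence[SampleRecord],
    min_objects: int = 2,
    min_subjects: int = 1,
    host_required: bool = True,
) -> tuple[set[str], list[TransferCall]]:
    """Families detected on enough of a subject's objects (and, by default,
    also on that subject's skin).

    Returns the qualifying family set and the per-(subject, family) calls.
    """
    if min_objects < 1:
        raise ValidationError("min_objects must be >= 1")
    if min_subjects < 1:
        raise ValidationError("min_subjects must be >= 1")
    cols = set(presence.samples)
    obj_by_subject: dict[str, list[str]] = defaultdict(list)
    for rec in pf.object_records(metadata):
        if rec.sample_id in cols:
            obj_by_subject[rec.subject_id].append(rec.sample_id)
    skin_by_subject: dict[str, list[str]] = defaultdict(list)
    for rec in pf.skin_records(metadata):
        if rec.sample_id in cols:
            skin_by_subject[rec.subject_id].append(rec.sample_id)

    calls: list[TransferCall] = []
    per_family: dict[str, int] = defaultdict(int)
    for subject in sorted(obj_by_subject):
        obj_ids = obj_by_subject[subject]
        if len(obj_ids) < len(OBJECT_TYPES):
            warnings.warn(
                f"subject {subject!r} has {len(obj_ids)} object samples; "
                "counting over available objects",
                stacklevel=2,
            )
        counts = presence.data[obj_ids].sum(axis=1)
        if host_required:
            skin_ids = skin_by_subject.get(subject, [])
            on_skin = (
                presence.data[skin_ids].sum(axis=1) > 0
                if skin_ids
                else pd.Series(False, index=presence.data.index)
            )
        else:
            on_skin = pd.Series(True, index=presence.data.index)
        for family, c in counts.items():
            ok = bool(c >= min_objects and on_skin[family])
            calls.append(
                TransferCall(
                    subject_id=subject,
                    family=str(family),
                    n_objects_detected=int(c),
                    transmissible=ok,
                )
            )
            if ok:
                per_family[str(family)] += 1
    families = {f for f, n in per_family.items() if n >= min_subjects}
    return families, calls


def object_transfer_profile(
    calls: Sequence[TransferCall],
    presence: PresenceMatrix,
    metadata: Sequence[SampleRecord],
) -> pd.DataFrame:
    """Per transmissible family, the share of its object detections on each
    object type (rows sum to 1 for families with any detection)."""
    families = sorted({c.family for c in calls if c.transmissible})
    cols = set(presence.samples)
    tallies = pd.DataFrame(
        0.0, index=families, columns=[o.value for o in OBJECT_TYPES]
    )
    for rec in pf.object_records(metadata):
        if rec.sample_id not in cols:
            continue
        detected = presence.data[rec.sample_id]
        for fam in families:
            if fam in detected.index and detected[fam] > 0:
                tallies.loc[fam, rec.object_type.value] += 1
    totals = tallies.sum(axis=1)
    out = tallies.div(totals.replace(0, 1), axis=0)
    return out


# ---------------------------------------------------------------------------
# marker selection


def select_markers(
    stable: set[str],
    transmissible: set[str],
    presence_species: PresenceMatrix,
    taxonomy: Taxonomy,
) -> tuple[set[str], set[str]]:
    """Intersect the two family sets and pull the detected species they contain.

    ``presence_species`` has species labels as rows.  Returns
    (marker_families, marker_species).
    """
    marker_families = stable & transmissible
    if not marker_families:
        warnings.warn("empty stable/transmissible intersection; no markers", stacklevel=2)
        return set(), set()
    sp2fam = taxonomy.species_to_family()
    detected = presence_species.data.sum(axis=1) > 0
    marker_species = {
        str(sp)
        for sp, det in detected.items()
        if det and sp2fam.get(str(sp)) in marker_families
    }
    return marker_families, marker_species


def occurrence_matrix(
    presence_species: PresenceMatrix,
    metadata: Sequence[SampleRecord],
    markers: set[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per subject and marker species, the detection rate (0-100 %).

    The skin matrix pools all sites and time points; the object matrix
    pools the subject's contacted objects.  Returns (skin, objects) frames
    with subjects as rows and sorted marker species as columns.
    """
    if not markers:
        raise ValidationError("marker set is empty")
    marker_list = sorted(markers)
    missing = [m for m in marker_list if m not in set(presence_species.taxa)]
    if missing:
        raise ValidationError(f"markers missing from species matrix: {missing}")
    cols = set(presence_species.samples)
    subj = pf.subjects(metadata)

    def rate_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
        out = pd.DataFrame(0.0, index=subj, columns=marker_list)
        by_subject: dict[str, list[str]] = defaultdict(list)
        for rec in records:
            if rec.sample_id in cols:
                by_subject[rec.subject_id].append(rec.sample_id)
        for s in subj:
            ids = by_subject.get(s, [])
            if ids:
                out.loc[s] = (
                    100.0 * presence_species.data.loc[marker_list, ids].mean(axis=1)
                ).to_numpy()
        return out

    return rate_frame(pf.skin_records(metadata)), rate_frame(pf.object_records(metadata))


# ---------------------------------------------------------------------------
# within/between comparisons


def _within_between(
    dist: DissimilarityMatrix,
    records: Sequence[SampleRecord],
    wilcoxon_mode: str,
    per_subject_means: bool,
) -> WithinBetweenResult:
    ids_in = set(dist.ids)
    by_subject: dict[str, list[str]] = defaultdict(list)
    for rec in records:
        if rec.sample_id in ids_in:
            by_subject[rec.subject_id].append(rec.sample_id)
    kept = {}
    for s, ids in sorted(by_subject.items()):
        if len(ids) < 2:
            warnings.warn(
                f"subject {s!r} has fewer than two samples; dropped from comparison",
                stacklevel=3,
            )
            continue
        kept[s] = ids
    if len(kept) < 2:
        raise ValidationError("need at least two subjects with >= 2 samples each")

    within_means: dict[str, float] = {}
    between_means: dict[str, float] = {}
    within_pool: list[float] = []
    between_pool: list[float] = []
    all_ids_by_subject = by_subject  # between uses every sample, even singletons
    for s, ids in kept.items():
        sub = dist.subset(ids)
        pairs = sub.condensed()
        within_means[s] = float(pairs.mean())
        within_pool.extend(pairs.tolist())
        others = [
            i for s2, ids2 in all_ids_by_subject.items() if s2 != s for i in ids2
        ]
        cross = dist.between(ids, others)
        between_means[s] = float(cross.mean())
        between_pool.extend(cross.ravel().tolist())
    if per_subject_means:
        x = [within_means[s] for s in sorted(kept)]
        y = [between_means[s] for s in sorted(kept)]
    else:
        x, y = within_pool, between_pool
    test = wilcoxon_rank_sum(x, y, alternative="two_sided", mode=wilcoxon_mode)
    return WithinBetweenResult(
        per_subject_within=within_means,
        per_subject_between=between_means,
        wilcoxon=test,
    )


def within_between_skin(
    dist: DissimilarityMatrix,
    metadata: Sequence[SampleRecord],
    wilcoxon_mode: str = "auto",
    per_subject_means: bool = True,
) -> WithinBetweenResult:
    """Within-subject vs between-subject mean distances over skin samples."""
    return _within_between(
        dist, pf.skin_records(metadata), wilcoxon_mode, per_subject_means
    )


def within_between_objects(
    dist: DissimilarityMatrix,
    metadata: Sequence[SampleRecord],
    wilcoxon_mode: str = "auto",
    per_subject_means: bool = True,
) -> WithinBetweenResult:
    """Within-subject vs between-subject mean distances over object samples."""
    return _within_between(
        dist, pf.object_records(metadata), wilcoxon_mode, per_subject_means
    )


# ---------------------------------------------------------------------------
# orchestration


def run_marker_analysis(
    table: AbundanceTable,
    taxonomy: Taxonomy,
    metadata: Sequence[SampleRecord],
    config: MarkerConfig | None = None,
) -> MarkerReport:
    """Full marker analysis: binarize, control-filter, select, compare."""
    cfg = config or MarkerConfig()
    report = MarkerReport(config=cfg.to_dict())
    if table.shape[0] == 0 or table.shape[1] == 0:
        warnings.warn("empty abundance table; returning empty report", stacklevel=2)
        return report

    presence = pf.binarize(table, cfg.min_count)
    if cfg.control_filter:
        presence = pf.remove_control_taxa(presence, metadata)
    fam = pf.collapse_presence(presence, taxonomy, "family", cfg.drop_unclassified)
    spp = pf.collapse_presence(presence, taxonomy, "species", cfg.drop_unclassified)

    calls = site_stability(fam, metadata, cfg.min_timepoints)
    report.stable_families = stable_families(
        calls, cfg.require_all_sites, cfg.min_subjects
    )
    report.transmissible_families, tcalls = transmissible_families(
        fam, metadata, cfg.min_objects, cfg.min_subjects, cfg.host_required
    )
    report.transfer_profile = object_transfer_profile(tcalls, fam, metadata)
    report.marker_families, report.marker_species = select_markers(
        report.stable_families, report.transmissible_families, spp, taxonomy
    )
    if not report.marker_species:
        return report

    markers = sorted(report.marker_species)
    report.occurrence_skin, report.occurrence_objects = occurrence_matrix(
        spp, metadata, report.marker_species
    )
    marker_presence = PresenceMatrix(spp.data.loc[markers], validate=False)
    cols = set(marker_presence.samples)
    skin_ids = [r.sample_id for r in pf.skin_records(metadata) if r.sample_id in cols]
    obj_ids = [r.sample_id for r in pf.object_records(metadata) if r.sample_id in cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-profile pairs are routine here
        if len(skin_ids) >= 2:
            skin_dist = jaccard_matrix(
                PresenceMatrix(marker_presence.data[skin_ids], validate=False)
            )
            try:
                report.skin_comparison = within_between_skin(
                    skin_dist, metadata, cfg.wilcoxon_mode, cfg.per_subject_means
                )
            except ValidationError as exc:
                warnings.warn(f"skin comparison skipped: {exc}", stacklevel=2)
        if len(obj_ids) >= 2:
            obj_dist = jaccard_matrix(
                PresenceMatrix(marker_presence.data[obj_ids], validate=False)
            )
            try:
                report.object_comparison = within_between_objects(
                    obj_dist, metadata, cfg.wilcoxon_mode, cfg.per_subject_means
                )
            except ValidationError as exc:
                warnings.warn(f"object comparison skipped: {exc}", stacklevel=2)
    return report
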