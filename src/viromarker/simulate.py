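"""Synthetic study generator.

Emits a complete study — abundance table, taxonomy, sample metadata and the
planted ground truth — shaped like the real design: 8 subjects x 3 skin
sites x 3 time points, 4 contacted objects per subject, plus negative
controls.  Subjects carry disjoint persistent signature species; shared
(cosmopolitan) species appear everywhere; transient species are sprinkled
into skin samples; detection dropout and per-object transfer probabilities
thin the latent profiles.  Everything is driven by one seeded generator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import profiles as pf
from .profiles import (
    OBJECT_TYPES,
    SITES,
    TIME_POINTS,
    UNCLASSIFIED,
    AbundanceTable,
    ObjectType,
    SampleClass,
    SampleRecord,
    Site,
    TaxonLineage,
    Taxonomy,
    TimePoint,
    ValidationError,
)

HIGHER_RANKS = ("Caudoviricetes", "Papovaviricetes", "Megaviricetes")


@dataclass
class StudyConfig:
    """Knobs for :func:`generate_study`.

    ``detection_prob`` applies per skin sampling event; ``transfer_prob``
    applies per object contact and may be a single float or a per-object
    mapping keyed by object-type token.
    """

    n_subjects: int = 8
    n_signature_families: int = 15
    n_signature_species: int = 54
    n_shared_families: int = 3
    n_shared_species: int = 6
    n_transient_species: int = 8
    n_contaminant_species: int = 3
    detection_prob: float = 0.95
    transfer_prob: float | Mapping[str, float] = 0.85
    shared_prevalence: float = 0.9
    transient_rate: float = 0.05
    contamination_rate: float = 0.5
    unclassified_fraction: float = 0.0
    signature_overlap: float = 0.0
    null_model: bool = False
    count_model: str = "lognormal"  # or "negative_binomial"
    count_log_mean: float = 3.0
    count_log_sd: float = 1.0
    nb_mean: float = 25.0
    nb_dispersion: float = 2.0
    n_controls: int = 2
    contact_time_point: TimePoint = TimePoint.T2
    seed: int = 0

    def transfer_prob_for(self, obj: ObjectType) -> float:
        if isinstance(self.transfer_prob, Mapping):
            return float(self.transfer_prob[obj.value])
        return float(self.transfer_prob)

    def validate(self) -> None:
        probs = [
            self.detection_prob,
            self.shared_prevalence,
            self.transient_rate,
            self.contamination_rate,
            self.unclassified_fraction,
            self.signature_overlap,
        ] + [self.transfer_prob_for(o) for o in OBJECT_TYPES]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        for name in (
            "n_subjects",
            "n_signature_families",
            "n_signature_species",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.n_signature_species < self.n_signature_families:
            raise ValidationError("need at least one species per signature family")
        if self.count_model not in ("lognormal", "negative_binomial"):
            raise ValidationError("count_model must be lognormal or negative_binomial")


@dataclass
class GroundTruth:
    """What was planted: who owns which species, and pre-dropout presence."""

    subject_signatures: dict[str, set[str]]  # subject -> signature species labels
    signature_families: set[str]
    signature_species: set[str]
    shared_species: set[str]
    transient_species: set[str]
    contaminant_species: set[str]
    latent_presence: pd.DataFrame  # species x samples, before dropout/transfer

    def to_dict(self) -> dict:
        return {
            "subject_signatures": {
                s: sorted(v) for s, v in self.subject_signatures.items()
            },
            "signature_families": sorted(self.signature_families),
            "signature_species": sorted(self.signature_species),
            "shared_species": sorted(self.shared_species),
            "transient_species": sorted(self.transient_species),
            "contaminant_species": sorted(self.contaminant_species),
            "latent_presence": {
                "index": list(self.latent_presence.index),
                "columns": list(self.latent_presence.columns),
                "values": self.latent_presence.to_numpy().astype(int).tolist(),
            },
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        lp = d["latent_presence"]
        return cls(
            subject_signatures={s: set(v) for s, v in d["subject_signatures"].items()},
            signature_families=set(d["signature_families"]),
            signature_species=set(d["signature_species"]),
            shared_species=set(d["shared_species"]),
            transient_species=set(d["transient_species"]),
            contaminant_species=set(d["contaminant_species"]),
            latent_presence=pd.DataFrame(
                lp["values"], index=lp["index"], columns=lp["columns"]
            ),
        )


def _species_label(kind: str, i: int) -> str:
    return f"{kind}_species_{i:03d}"


def generate_taxonomy(config: StudyConfig, rng: np.random.Generator | None = None) -> Taxonomy:
    """Deterministic taxonomy for the configured study universe.

    Signature species are spread over the signature families (each family
    gets at least one); a configurable fraction of species is relabelled
    UNCLASSIFIED at family rank.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    lineages: list[TaxonLineage] = []

    def fam_label(kind: str, j: int) -> str:
        return f"{kind}_family_{j:02d}"

    # round-robin guarantees every signature family holds >= 1 species
    for i in range(config.n_signature_species):
        fam = fam_label("sig", i % config.n_signature_families)
        lineages.append(
            TaxonLineage(
                taxon_id=f"sig{i:03d}",
                species=_species_label("sig", i),
                family=fam,
                higher_rank=HIGHER_RANKS[i % len(HIGHER_RANKS)],
            )
        )
    for i in range(config.n_shared_species):
        fam = fam_label("shared", i % max(config.n_shared_families, 1))
        lineages.append(
            TaxonLineage(
                taxon_id=f"shr{i:03d}",
                species=_species_label("shared", i),
                family=fam,
                higher_rank=HIGHER_RANKS[i % len(HIGHER_RANKS)],
            )
        )
    for i in range(config.n_transient_species):
        lineages.append(
            TaxonLineage(
                taxon_id=f"trn{i:03d}",
                species=_species_label("transient", i),
                family=fam_label("transient", i),
                higher_rank=HIGHER_RANKS[i % len(HIGHER_RANKS)],
            )
        )
    for i in range(config.n_contaminant_species):
        lineages.append(
            TaxonLineage(
                taxon_id=f"ctm{i:03d}",
                species=_species_label("contam", i),
                family=fam_label("contam", i),
                higher_rank=HIGHER_RANKS[i % len(HIGHER_RANKS)],
            )
        )
    if config.unclassified_fraction > 0:
        n = len(lineages)
        n_unc = int(round(config.unclassified_fraction * n))
        picks = rng.choice(n, size=n_unc, replace=False)
        for idx in picks:
            old = lineages[idx]
            lineages[idx] = TaxonLineage(
                taxon_id=old.taxon_id,
                species=old.species,
                family=UNCLASSIFIED,
                higher_rank=old.higher_rank,
            )
    return Taxonomy(lineages)


def _build_metadata(config: StudyConfig) -> list[SampleRecord]:
    records: list[SampleRecord] = []
    for s in range(1, config.n_subjects + 1):
        subject = f"S{s}"
        for site in SITES:
            for tp in TIME_POINTS:
                records.append(
                    SampleRecord(
                        sample_id=f"{subject}_{site.value}_{tp.value}",
                        subject_id=subject,
                        sample_class=SampleClass.SKIN,
                        site=site,
                        time_point=tp,
                    )
                )
        for obj in OBJECT_TYPES:
            records.append(
                SampleRecord(
                    sample_id=f"{subject}_{obj.value}",
                    subject_id=subject,
                    sample_class=SampleClass.OBJECT,
                    object_type=obj,
                )
            )
    for c in range(1, config.n_controls + 1):
        records.append(
            SampleRecord(
                sample_id=f"NC{c}",
                subject_id=pf.CONTROL_SUBJECT,
                sample_class=SampleClass.NEGATIVE_CONTROL,
            )
        )
    return records


def _draw_counts(
    config: StudyConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Positive integer read counts for present taxa (minimum 1)."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if config.count_model == "lognormal":
        raw = rng.lognormal(config.count_log_mean, config.count_log_sd, size=n)
        return np.maximum(np.ceil(raw), 1).astype(np.int64)
    p = config.nb_dispersion / (config.nb_dispersion + config.nb_mean)
    return rng.negative_binomial(config.nb_dispersion, p, size=n).astype(np.int64) + 1


def generate_study(
    config: StudyConfig,
) -> tuple[AbundanceTable, list[SampleRecord], Taxonomy, GroundTruth]:
    """Sample a full study from the configured generative model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    taxonomy = generate_taxonomy(config, rng)
    metadata = _build_metadata(config)

    species_of = {lin.taxon_id: lin.species for lin in taxonomy}
    sig_ids = [f"sig{i:03d}" for i in range(config.n_signature_species)]
    shared_ids = [f"shr{i:03d}" for i in range(config.n_shared_species)]
    transient_ids = [f"trn{i:03d}" for i in range(config.n_transient_species)]
    contam_ids = [f"ctm{i:03d}" for i in range(config.n_contaminant_species)]
    all_ids = sig_ids + shared_ids + transient_ids + contam_ids

    subject_ids = [f"S{s}" for s in range(1, config.n_subjects + 1)]
    owners: dict[str, set[str]] = {s: set() for s in subject_ids}
    if config.null_model:
        for s in subject_ids:
            owners[s] = set(sig_ids)
    else:
        assignment = rng.integers(0, config.n_subjects, size=len(sig_ids))
        for tid, a in zip(sig_ids, assignment):
            owners[subject_ids[a]].add(tid)
        if config.signature_overlap > 0:
            for tid in sig_ids:
                if rng.random() < config.signature_overlap:
                    extra = subject_ids[rng.integers(0, config.n_subjects)]
                    owners[extra].add(tid)

    sample_ids = [r.sample_id for r in metadata]
    presence = pd.DataFrame(0, index=all_ids, columns=sample_ids, dtype=np.int64)
    latent = pd.DataFrame(0, index=all_ids, columns=sample_ids, dtype=np.int64)

    for rec in metadata:
        col = rec.sample_id
        if rec.sample_class is SampleClass.SKIN:
            own = sorted(owners[rec.subject_id])
            latent.loc[own, col] = 1
            keep = [t for t in own if rng.random() < config.detection_prob]
            presence.loc[keep, col] = 1
            shared_hit = [t for t in shared_ids if rng.random() < config.shared_prevalence]
            presence.loc[shared_hit, col] = 1
            latent.loc[shared_hit, col] = 1
            trans_hit = [t for t in transient_ids if rng.random() < config.transient_rate]
            presence.loc[trans_hit, col] = 1
            contam_hit = [t for t in contam_ids if rng.random() < config.contamination_rate]
            presence.loc[contam_hit, col] = 1
        elif rec.sample_class is SampleClass.OBJECT:
            tau = config.transfer_prob_for(rec.object_type)
            own = sorted(owners[rec.subject_id])  # latent skin profile at contact
            latent.loc[own, col] = 1
            keep = [t for t in own if rng.random() < tau]
            presence.loc[keep, col] = 1
            shared_hit = [t for t in shared_ids if rng.random() < config.shared_prevalence]
            presence.loc[shared_hit, col] = 1
            latent.loc[shared_hit, col] = 1
            contam_hit = [t for t in contam_ids if rng.random() < config.contamination_rate]
            presence.loc[contam_hit, col] = 1
        else:  # negative control
            contam_hit = [t for t in contam_ids if rng.random() < config.contamination_rate]
            presence.loc[contam_hit, col] = 1

    counts = pd.DataFrame(0, index=all_ids, columns=sample_ids, dtype=np.int64)
    mask = presence.to_numpy() == 1
    values = _draw_counts(config, rng, int(mask.sum()))
    arr = counts.to_numpy()
    arr[mask] = values
    counts = pd.DataFrame(arr, index=all_ids, columns=sample_ids)

    sig_families = {
        taxonomy[t].family for t in sig_ids if taxonomy[t].family != UNCLASSIFIED
    }
    truth = GroundTruth(
        subject_signatures={
            s: {species_of[t] for t in tids} for s, tids in owners.items()
        },
        signature_families=sig_families,
        signature_species={species_of[t] for t in sig_ids},
        shared_species={species_of[t] for t in shared_ids},
        transient_species={species_of[t] for t in transient_ids},
        contaminant_species={species_of[t] for t in contam_ids},
        latent_presence=latent,
    )
    return AbundanceTable(counts, validate=False), metadata, taxonomy, truth


def recovery_metrics(planted: set[str], selected: set[str]) -> dict[str, float]:
    """Precision/recall of a selected set against a planted set."""
    inter = len(planted & selected)
    precision = inter / len(selected) if selected else (1.0 if not planted else 0.0)
    recall = inter / len(planted) if planted else 1.0
    return {"precision": precision, "recall": recall}


def report_recovery(truth: GroundTruth, report) -> dict[str, dict[str, float]]:
    """Family- and species-level recovery of the planted signature sets."""
    return {
        "families": recovery_metrics(truth.signature_families, report.marker_families),
        "species": recovery_metrics(truth.signature_species, report.marker_species),
    }
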