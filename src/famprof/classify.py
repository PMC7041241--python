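"""Occupancy-abundance profiling and core-symbiont / FAM classification.

The classification plots each OTU by two frequencies over a sample set:

* occurrence: fraction of samples where the OTU is present;
* frequency of high abundance: fraction of samples where its relative
  abundance exceeds a threshold (default 0.1%).

OTUs occurring in strictly more than the occurrence cut-off (default 70%)
of samples are split into the core symbiont (high-abundance frequency
strictly above 90%: abundant essentially whenever present, the signature
of the obligate Xenorhabdus partner) and the frequently associated
microbiota, FAM (high occurrence but only intermittently abundant).
Everything else is "other".  Classifications from two metabarcoding
markers are reconciled at taxon level (genus, falling back to family),
never by OTU id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    OtuTable,
    OtuTableError,
    TaxonAssignment,
    aggregate_by_rank,
    relative_abundance,
)

CORE_SYMBIONT = "core_symbiont"
FAM = "FAM"
OTHER = "other"


@dataclass
class OccupancyProfile:
    otu_id: str
    occurrence_freq: float
    high_abundance_freq: float
    n_samples: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.high_abundance_freq <= self.occurrence_freq <= 1.0):
            raise OtuTableError(
                f"invalid occupancy profile for {self.otu_id!r}: "
                f"occurrence={self.occurrence_freq}, "
                f"high_abundance={self.high_abundance_freq}"
            )


@dataclass
class FamClassification:
    labels: dict[str, str]
    high_abund_threshold: float
    occurrence_cutoff: float
    core_cutoff: float

    def of(self, role: str) -> list[str]:
        return [o for o, lab in self.labels.items() if lab == role]


def occupancy_profiles(
    table: OtuTable,
    samples: Sequence[str] | None = None,
    high_abund_threshold: float = 0.001,
    presence: str = "nonzero",
) -> list[OccupancyProfile]:
    """Per-OTU occurrence and high-abundance frequencies over ``samples``.

    ``presence='nonzero'`` (default) counts any nonzero read count as
    present; ``presence='above-threshold'`` counts only samples where the
    OTU exceeds the high-abundance threshold, collapsing the two axes'
    numerators onto the same rule.
    """
    if samples is None:
        samples = list(table.sample_ids)
    samples = list(samples)
    if not samples:
        raise OtuTableError("occupancy_profiles: empty sample subset")
    if presence not in ("nonzero", "above-threshold"):
        raise OtuTableError(f"unknown presence rule {presence!r}")
    sub = table.select_samples(samples)
    props = relative_abundance(sub).to_numpy()
    high = (props > high_abund_threshold).mean(axis=1)
    if presence == "nonzero":
        occ = (sub.counts > 0).mean(axis=1)
    else:
        occ = high
    return [
        OccupancyProfile(
            otu_id=o,
            occurrence_freq=float(occ[i]),
            high_abundance_freq=float(high[i]),
            n_samples=len(samples),
        )
        for i, o in enumerate(table.otu_ids)
    ]


def classify_fam(
    profiles: Sequence[OccupancyProfile],
    occurrence_cutoff: float = 0.70,
    core_cutoff: float = 0.90,
    high_abund_threshold: float = 0.001,
) -> FamClassification:
    """Threshold occupancy profiles into core symbiont / FAM / other.

    Strict inequalities: an OTU at exactly the occurrence cut-off is
    "other"; one at exactly the core cut-off is FAM.  Monotone in the
    high-abundance frequency.
    """
    labels: dict[str, str] = {}
    for p in profiles:
        if p.occurrence_freq <= occurrence_cutoff:
            labels[p.otu_id] = OTHER
        elif p.high_abundance_freq > core_cutoff:
            labels[p.otu_id] = CORE_SYMBIONT
        else:
            labels[p.otu_id] = FAM
    return FamClassification(
        labels=labels,
        high_abund_threshold=high_abund_threshold,
        occurrence_cutoff=occurrence_cutoff,
        core_cutoff=core_cutoff,
    )


@dataclass
class ConsensusResult:
    """Taxon labels supported by both markers, per role."""

    core: set[str]
    fam: set[str]
    unresolved: dict[str, list[str]] = field(default_factory=dict)
    per_marker: dict[str, dict[str, set[str]]] = field(default_factory=dict)


def _taxon_label(
    tax: TaxonAssignment, min_confidence: float
) -> str | None:
    """Genus label if confidently assigned, else family, else None."""
    if tax.is_assigned("genus", min_confidence):
        return tax.label_at("genus")
    if tax.is_assigned("family", min_confidence):
        return tax.label_at("family")
    return None


def marker_consensus(
    class_a: FamClassification,
    taxonomy_a: Mapping[str, TaxonAssignment],
    class_b: FamClassification,
    taxonomy_b: Mapping[str, TaxonAssignment],
    exclude: set[str] | frozenset[str] = frozenset(),
    min_confidence: float = 0.9,
    marker_names: tuple[str, str] = ("A", "B"),
) -> ConsensusResult:
    """Intersect two markers' core/FAM calls at taxon level.

    Each called OTU maps to its lowest confidently assigned rank at genus
    or family; OTUs resolvable at neither rank are reported as unresolved
    rather than silently dropped.  The consensus sets are labels present
    in both markers, minus ``exclude`` (e.g. genera flagged by the
    negative controls).
    """
    per_marker: dict[str, dict[str, set[str]]] = {}
    unresolved: dict[str, list[str]] = {}
    for name, cls, taxonomy in (
        (marker_names[0], class_a, taxonomy_a),
        (marker_names[1], class_b, taxonomy_b),
    ):
        sets: dict[str, set[str]] = {CORE_SYMBIONT: set(), FAM: set()}
        missing: list[str] = []
        for role in (CORE_SYMBIONT, FAM):
            for otu in cls.of(role):
                tax = taxonomy.get(otu)
                if tax is None:
                    missing.append(otu)
                    continue
                label = _taxon_label(tax, min_confidence)
                if label is None:
                    missing.append(otu)
                else:
                    sets[role].add(label)
        per_marker[name] = sets
        if missing:
            unresolved[name] = sorted(missing)
    a, b = marker_names
    exclude = set(exclude)
    return ConsensusResult(
        core=(per_marker[a][CORE_SYMBIONT] & per_marker[b][CORE_SYMBIONT]) - exclude,
        fam=(per_marker[a][FAM] & per_marker[b][FAM]) - exclude,
        unresolved=unresolved,
        per_marker=per_marker,
    )


def top_n_taxa(
    table: OtuTable,
    n: int = 30,
    rank: str = "genus",
    min_confidence: float = 0.9,
) -> tuple[list[str], pd.DataFrame]:
    """Top-N taxon labels by total relative abundance, with their matrix.

    Aggregates the table at ``rank``, ranks labels by relative abundance
    summed over samples (ties broken lexicographically), and returns the
    ranked labels with the label x sample relative-abundance matrix in
    rank order.  This is the table behind "Top-30 genus" heatmaps.
    """
    if n < 1:
        raise OtuTableError("top_n_taxa: n must be >= 1")
    agg = aggregate_by_rank(table, rank, min_confidence)
    props = relative_abundance(agg)
    totals = props.sum(axis=1)
    order = sorted(totals.index, key=lambda lab: (-totals[lab], lab))
    top = order[:n]
    return top, props.loc[top]
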