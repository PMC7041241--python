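"""End-to-end profiling workflow: filter, decontaminate, classify, reconcile.

Chains the module operations in the order the analysis runs on real
multi-marker data:

1. global low-abundance cluster filter (0.005% of all reads) per marker;
2. replicate core sets for the IJ samples and the negative controls,
   and removal of taxa shared between the two (kitome decontamination),
   matched at genus level;
3. occupancy-abundance profiling and core-symbiont / FAM classification
   per marker;
4. two-marker consensus of the called taxon sets.

`run_pipeline` operates on any pair of marker tables; `run_synthetic`
generates a planted community first and scores recovery against the
truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .classify import (
    CORE_SYMBIONT,
    FAM,
    ConsensusResult,
    FamClassification,
    classify_fam,
    marker_consensus,
    occupancy_profiles,
)
from .decontam import (
    CoreSet,
    RemovalRecord,
    global_cluster_filter,
    remove_control_taxa,
    replicate_core_set,
)
from .simulate import SyntheticSpec, simulate_community, simulate_controls
from .tables import OtuTable


@dataclass
class MarkerResult:
    table: OtuTable                      # filtered + decontaminated
    sample_core: CoreSet
    control_core: CoreSet
    removed: list[RemovalRecord]
    classification: FamClassification


@dataclass
class PipelineResult:
    markers: dict[str, MarkerResult]
    consensus: ConsensusResult

    def removed_labels(self, marker: str) -> set[str]:
        return {r.matched_label for r in self.markers[marker].removed}


def run_marker(
    table: OtuTable,
    control_table: OtuTable,
    min_total_fraction: float = 5e-5,
    core_freq_cutoff: float = 0.8,
    core_abund_cutoff: float = 1e-4,
    decontam_level: str = "genus",
    high_abund_threshold: float = 0.001,
    occurrence_cutoff: float = 0.70,
    core_cutoff: float = 0.90,
    presence: str = "nonzero",
) -> MarkerResult:
    """Filter + decontaminate + classify one marker's table."""
    filtered = global_cluster_filter(table, min_total_fraction)
    sample_core = replicate_core_set(
        filtered, filtered.sample_ids, label="IJ",
        freq_cutoff=core_freq_cutoff, abund_cutoff=core_abund_cutoff,
    )
    control_core = replicate_core_set(
        control_table, control_table.sample_ids, label="control",
        freq_cutoff=core_freq_cutoff, abund_cutoff=core_abund_cutoff,
    )
    cleaned, removed = remove_control_taxa(
        filtered, control_core, sample_core,
        level=decontam_level, control_taxonomy=control_table.taxonomy,
    )
    profiles = occupancy_profiles(
        cleaned, high_abund_threshold=high_abund_threshold, presence=presence
    )
    classification = classify_fam(
        profiles,
        occurrence_cutoff=occurrence_cutoff,
        core_cutoff=core_cutoff,
        high_abund_threshold=high_abund_threshold,
    )
    return MarkerResult(
        table=cleaned,
        sample_core=sample_core,
        control_core=control_core,
        removed=removed,
        classification=classification,
    )


def run_pipeline(
    tables: Mapping[str, OtuTable],
    controls: Mapping[str, OtuTable],
    exclude: set[str] | frozenset[str] = frozenset(),
    min_confidence: float = 0.9,
    **marker_kwargs,
) -> PipelineResult:
    """Run the per-marker workflow on each marker and reconcile the calls.

    ``tables`` and ``controls`` map the same two marker names to sample
    and negative-control OTU tables.
    """
    names = sorted(tables)
    if len(names) != 2 or sorted(controls) != names:
        raise ValueError(
            "run_pipeline expects the same two marker names in tables and controls"
        )
    per_marker = {
        m: run_marker(tables[m], controls[m], **marker_kwargs) for m in names
    }
    a, b = names
    consensus = marker_consensus(
        per_marker[a].classification, per_marker[a].table.taxonomy,
        per_marker[b].classification, per_marker[b].table.taxonomy,
        exclude=exclude, min_confidence=min_confidence,
        marker_names=(a, b),
    )
    return PipelineResult(markers=per_marker, consensus=consensus)


@dataclass
class RecoveryScore:
    """How well one synthetic run was recovered against the planted truth."""

    contaminants_removed: bool
    one_core_symbiont: bool
    core_label_correct: bool
    fam_set_recovered: bool
    consensus: ConsensusResult
    expected_fam: set[str] = field(default_factory=set)

    @property
    def success(self) -> bool:
        return (
            self.contaminants_removed
            and self.one_core_symbiont
            and self.core_label_correct
            and self.fam_set_recovered
        )


def run_synthetic(spec: SyntheticSpec, n_controls: int = 6) -> tuple[PipelineResult, RecoveryScore]:
    """Simulate a planted community, run the pipeline, score the recovery.

    Success requires: every planted contaminant label shared with the IJ
    core is removed (and no planted FAM/symbiont label is), exactly one
    core-symbiont taxon is called per marker with the planted symbiont's
    label, and the consensus FAM label set equals the planted FAM set.
    """
    tables, _metas, truth = simulate_community(spec)
    controls, _cmetas = simulate_controls(spec, n_controls=n_controls)
    result = run_pipeline(tables, controls)

    expected_fam = truth.expected_labels("fam")
    expected_core = truth.expected_labels("core_symbiont")
    contaminant_labels = truth.expected_labels("contaminant")
    protected = expected_fam | expected_core

    removed_ok = True
    for m, mr in result.markers.items():
        removed = {r.matched_label for r in mr.removed}
        if removed & protected:          # a planted genuine taxon was removed
            removed_ok = False
        if removed - contaminant_labels:  # something not planted as kitome
            removed_ok = False
        # the infiltrating contaminant must actually have been caught
        still_there = {
            mr.table.taxonomy[o].label_at("genus")
            for o in mr.table.otu_ids
        }
        core_members = set(mr.sample_core.members) & set(mr.table.otu_ids)
        core_labels = {
            mr.table.taxonomy[o].label_at("genus") for o in core_members
        }
        if core_labels & contaminant_labels & still_there:
            removed_ok = False

    n_core_calls = [
        len(mr.classification.of(CORE_SYMBIONT)) for mr in result.markers.values()
    ]
    one_core = all(n == 1 for n in n_core_calls)
    core_ok = result.consensus.core == expected_core
    fam_ok = result.consensus.fam == expected_fam

    score = RecoveryScore(
        contaminants_removed=removed_ok,
        one_core_symbiont=one_core,
        core_label_correct=core_ok,
        fam_set_recovered=fam_ok,
        consensus=result.consensus,
        expected_fam=expected_fam,
    )
    return result, score
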