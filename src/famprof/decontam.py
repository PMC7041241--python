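"""Abundance filtering and kitome decontamination by set logic.

Four operations, mirroring the usual negative-control workflow for
low-biomass amplicon data:

* :func:`global_cluster_filter` drops OTUs whose total read count falls
  below a fraction of all reads (default 0.005%).
* :func:`replicate_core_set` computes, for a replicate group, the set of
  OTUs exceeding an abundance cut-off in strictly more than a frequency
  cut-off of the group's samples (defaults: > 0.01% abundance in > 80%
  of replicates).
* :func:`venn_partition` splits core sets into Venn regions plus a
  ``non_core`` catch-all.
* :func:`remove_control_taxa` removes OTUs shared between a control
  (kitome) core set and a sample core set, matched at OTU or genus level.

All cut-offs are strict inequalities.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .tables import OtuTable, OtuTableError, TaxonAssignment, relative_abundance


@dataclass
class CoreSet:
    """OTUs (or taxon labels) robustly present across a replicate group."""

    label: str
    members: tuple[str, ...]
    freq_cutoff: float
    abund_cutoff: float

    def __contains__(self, item: str) -> bool:
        return item in set(self.members)


@dataclass
class RemovalRecord:
    otu_id: str
    matched_label: str
    level: str


def global_cluster_filter(
    table: OtuTable, min_total_fraction: float = 5e-5
) -> OtuTable:
    """Drop OTUs with total reads below ``min_total_fraction`` of all reads.

    An OTU is kept iff its total count >= threshold = fraction x grand
    total ("less than" the threshold is removed).  Idempotent at a fixed
    fraction: survivors' totals stay above the (shrunken) new threshold.
    """
    if table.n_otus == 0 or table.grand_total() == 0:
        warnings.warn("global_cluster_filter: empty table, returned unchanged")
        return table.copy()
    threshold = min_total_fraction * table.grand_total()
    totals = table.counts.sum(axis=1)
    keep = [o for o, t in zip(table.otu_ids, totals) if t >= threshold]
    return table.select_otus(keep)


def replicate_core_set(
    table: OtuTable,
    group: Sequence[str],
    label: str = "core",
    freq_cutoff: float = 0.8,
    abund_cutoff: float = 1e-4,
) -> CoreSet:
    """Core OTUs of a replicate group.

    Membership: relative abundance (computed per sample on the table as
    given) exceeds ``abund_cutoff`` in strictly more than ``freq_cutoff``
    of the group's samples.  Order-invariant in the group.
    """
    group = list(group)
    if not group:
        raise OtuTableError("replicate_core_set: empty sample group")
    unknown = set(group) - set(table.sample_ids)
    if unknown:
        raise OtuTableError(f"replicate_core_set: unknown sample ids {sorted(unknown)}")
    props = relative_abundance(table)[group].to_numpy()
    freq = (props > abund_cutoff).mean(axis=1)
    members = tuple(
        o for o, f in zip(table.otu_ids, freq) if f > freq_cutoff
    )
    return CoreSet(
        label=label, members=members,
        freq_cutoff=freq_cutoff, abund_cutoff=abund_cutoff,
    )


def venn_partition(
    core_sets: Sequence[CoreSet],
    universe: Iterable[str] | None = None,
) -> dict[str, set[str]]:
    """Partition core-set members into Venn regions.

    Region keys are '&'-joined sorted core-set labels ("A", "A&B", ...);
    all 2^k - 1 regions are present (possibly empty).  If ``universe`` is
    given, ids in it that belong to no core set land in ``non_core``.
    Every id appears in exactly one region.
    """
    if len(core_sets) < 2:
        raise OtuTableError("venn_partition needs at least two core sets")
    labels = [cs.label for cs in core_sets]
    if len(set(labels)) != len(labels):
        raise OtuTableError("core-set labels must be unique for a Venn partition")
    membership = {cs.label: set(cs.members) for cs in core_sets}
    regions: dict[str, set[str]] = {}
    for k in range(1, len(labels) + 1):
        for combo in itertools.combinations(sorted(labels), k):
            regions["&".join(combo)] = set()
    all_members = set().union(*membership.values())
    for item in all_members:
        inside = sorted(lab for lab in labels if item in membership[lab])
        regions["&".join(inside)].add(item)
    non_core = (set(universe) - all_members) if universe is not None else set()
    regions["non_core"] = non_core
    return regions


def remove_control_taxa(
    table: OtuTable,
    control_core: CoreSet,
    sample_core: CoreSet,
    level: str = "otu",
    control_taxonomy: Mapping[str, TaxonAssignment] | None = None,
    min_confidence: float = 0.0,
) -> tuple[OtuTable, list[RemovalRecord]]:
    """Remove OTUs shared between control and sample core sets.

    ``level='otu'`` matches identifiers directly (valid within a marker).
    ``level='genus'`` matches the genus labels of the two cores' members
    and removes *every* OTU of the table affiliated to a shared genus,
    the conservative rule used when a kitome genus is detected.
    ``control_taxonomy`` supplies taxonomy for the control core's members
    when the control table is a different object (defaults to the
    table's own taxonomy).
    """
    if level not in ("otu", "genus"):
        raise OtuTableError(f"unknown matching level {level!r}")
    report: list[RemovalRecord] = []
    if level == "otu":
        shared = set(control_core.members) & set(sample_core.members)
        remove = [o for o in table.otu_ids if o in shared]
        report = [RemovalRecord(o, o, "otu") for o in remove]
    else:
        ctl_tax = control_taxonomy if control_taxonomy is not None else table.taxonomy
        ctl_genera = {
            ctl_tax[o].label_at("genus")
            for o in control_core.members
            if o in ctl_tax and ctl_tax[o].is_assigned("genus", min_confidence)
        }
        smp_genera = {
            table.taxonomy[o].label_at("genus")
            for o in sample_core.members
            if o in table.taxonomy
            and table.taxonomy[o].is_assigned("genus", min_confidence)
        }
        shared_genera = ctl_genera & smp_genera
        remove = []
        for o in table.otu_ids:
            tax = table.taxonomy[o]
            if tax.is_assigned("genus") and tax.label_at("genus") in shared_genera:
                remove.append(o)
                report.append(RemovalRecord(o, tax.label_at("genus"), "genus"))
    keep = [o for o in table.otu_ids if o not in set(remove)]
    return table.select_otus(keep), report
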