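"""Synthetic paired-marker OTU tables with planted community roles.

The generative model is deliberately simple — the smallest model that
decouples occupancy from abundance the way infective-juvenile (IJ)
microbiota do:

* each taxon has a per-sample presence probability theta (occupancy) and
  a log-normal abundance weight exp(Normal(mu + delta, sigma)) when
  present, where delta ~ Normal(0, tau) is a per-(taxon, batch) shift
  that creates between-batch compositional structure;
* per-sample proportions are the normalized weights of present taxa, and
  read counts are Multinomial(depth, proportions), so column sums equal
  the realized depths exactly;
* two metabarcoding markers observe the SAME realized proportions but
  with their own OTU identifiers and their own taxonomic resolution:
  each (marker, taxon) keeps its genus (and species) label with the
  marker's assignment probability, otherwise the rank is masked as
  unassigned.

Planted roles (core symbiont, FAM, transient, contaminant) are returned
as :class:`TruthLabels` so downstream recovery can be scored.  Negative
controls contain only contaminant-role taxa.  One global seed fixes every
byte of output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from skbio import TreeNode

from .phylo import Alignment, PhyloError
from .tables import OtuTable, SampleMeta, TaxonAssignment

logger = logging.getLogger(__name__)

ROLES = ("core_symbiont", "fam", "transient", "contaminant")


class SyntheticSpecError(ValueError):
    pass


@dataclass
class TaxonSpec:
    """One community member: identity, planted role, occupancy, abundance."""

    name: str
    role: str
    occupancy: float                 # per-sample presence probability theta
    mean_log_weight: float           # mu of the log-normal abundance weight
    sd_log_weight: float = 1.0       # sigma >= 0
    genus: str | None = None
    family: str = "unassigned"
    lineage: tuple[str, str, str, str] = (
        "Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
    )                                # domain, phylum, class, order
    host_species: str | None = None  # restrict presence to one host (symbionts)
    control_occupancy: float | None = None  # presence prob. in control samples

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SyntheticSpecError(f"unknown role {self.role!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise SyntheticSpecError(f"occupancy not in [0,1]: {self.occupancy}")
        if self.sd_log_weight < 0:
            raise SyntheticSpecError("sd_log_weight must be >= 0")
        if self.control_occupancy is not None and not (
            0.0 <= self.control_occupancy <= 1.0
        ):
            raise SyntheticSpecError("control_occupancy not in [0,1]")

    def taxon_label(self) -> str:
        """Genus if the taxon has one, else family: the label used when
        reconciling markers."""
        return self.genus if self.genus is not None else self.family


@dataclass
class SampleGroup:
    host_species: str
    strain: str
    batch: str
    laboratory: str
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise SyntheticSpecError("n_replicates must be >= 1")


@dataclass
class MarkerSpec:
    genus_assignment_prob: float
    species_assignment_prob: float

    def __post_init__(self) -> None:
        for p in (self.genus_assignment_prob, self.species_assignment_prob):
            if not 0.0 <= p <= 1.0:
                raise SyntheticSpecError(f"assignment probability not in [0,1]: {p}")


@dataclass
class SyntheticSpec:
    groups: list[SampleGroup]
    taxa: list[TaxonSpec]
    markers: dict[str, MarkerSpec]
    depth: int = 20000
    depth_log_sd: float = 0.0        # 0 = fixed depth; else log-normal
    control_depth: int = 2000
    batch_effect_sd: float = 0.8     # tau
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.control_depth < 1:
            raise SyntheticSpecError("sequencing depth must be >= 1")
        if self.batch_effect_sd < 0:
            raise SyntheticSpecError("batch_effect_sd must be >= 0")
        if not self.groups:
            raise SyntheticSpecError("spec needs at least one sample group")
        if not self.taxa:
            raise SyntheticSpecError("spec needs at least one taxon")
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise SyntheticSpecError("duplicate taxon names")
        for host in {g.host_species for g in self.groups}:
            symbionts = [
                t for t in self.taxa
                if t.role == "core_symbiont"
                and t.host_species in (None, host)
            ]
            if len(symbionts) != 1:
                raise SyntheticSpecError(
                    f"host {host!r} must have exactly one core symbiont, "
                    f"found {len(symbionts)}"
                )

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        doc = asdict(self)
        for t in doc["taxa"]:
            t["lineage"] = list(t["lineage"])
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticSpec":
        return cls(
            groups=[SampleGroup(**g) for g in doc["groups"]],
            taxa=[
                TaxonSpec(**{**t, "lineage": tuple(t["lineage"])})
                for t in doc["taxa"]
            ],
            markers={k: MarkerSpec(**m) for k, m in doc["markers"].items()},
            depth=doc.get("depth", 20000),
            depth_log_sd=doc.get("depth_log_sd", 0.0),
            control_depth=doc.get("control_depth", 2000),
            batch_effect_sd=doc.get("batch_effect_sd", 0.8),
            seed=doc.get("seed", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TruthLabels:
    """Planted roles and the (marker, otu_id) -> taxon name mapping."""

    roles: dict[str, str]
    otu_to_taxon: dict[tuple[str, str], str]
    taxon_labels: dict[str, str] = field(default_factory=dict)

    def taxa_with_role(self, role: str) -> list[str]:
        return [name for name, r in self.roles.items() if r == role]

    def expected_labels(self, role: str) -> set[str]:
        """Genus-or-family labels of the taxa planted with ``role``."""
        return {self.taxon_labels[name] for name in self.taxa_with_role(role)}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("marker\totu_id\ttaxon\trole\tlabel\n")
            for (marker, otu), name in sorted(self.otu_to_taxon.items()):
                fh.write(
                    f"{marker}\t{otu}\t{name}\t{self.roles[name]}"
                    f"\t{self.taxon_labels[name]}\n"
                )


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------

def _streams(seed: int) -> dict[str, np.random.Generator]:
    layout, batch, community, controls = np.random.SeedSequence(seed).spawn(4)
    return {
        "layout": np.random.default_rng(layout),
        "batch": np.random.default_rng(batch),
        "community": np.random.default_rng(community),
        "controls": np.random.default_rng(controls),
    }


def _marker_layouts(
    spec: SyntheticSpec, rng: np.random.Generator
) -> dict[str, tuple[list[str], dict[str, TaxonAssignment]]]:
    """Per marker: OTU ids (one per taxon, in spec order) and masked taxonomy.

    Drawn from the layout stream only, so community and control tables of
    the same spec share identifiers and taxonomy.
    """
    layouts = {}
    for marker in sorted(spec.markers):
        mspec = spec.markers[marker]
        otu_ids, taxonomy = [], {}
        for k, taxon in enumerate(spec.taxa):
            otu = f"{marker}_OTU_{k + 1:03d}"
            otu_ids.append(otu)
            ranks = {
                "domain": taxon.lineage[0],
                "phylum": taxon.lineage[1],
                "class": taxon.lineage[2],
                "order": taxon.lineage[3],
                "family": taxon.family,
            }
            conf = {r: float(rng.uniform(0.95, 1.0)) for r in ranks}
            genus_kept = (
                taxon.genus is not None
                and rng.random() < mspec.genus_assignment_prob
            )
            species_kept = genus_kept and (
                rng.random() < mspec.species_assignment_prob
            )
            if genus_kept:
                ranks["genus"] = taxon.genus
                conf["genus"] = float(rng.uniform(0.9, 1.0))
            if species_kept:
                ranks["species"] = taxon.name
                conf["species"] = float(rng.uniform(0.9, 1.0))
            taxonomy[otu] = TaxonAssignment(ranks=ranks, confidence=conf)
        layouts[marker] = (otu_ids, taxonomy)
    return layouts


def _draw_depth(spec: SyntheticSpec, rng: np.random.Generator, base: int) -> int:
    if spec.depth_log_sd == 0.0:
        return base
    return max(1, int(round(np.exp(rng.normal(np.log(base), spec.depth_log_sd)))))


def _sample_counts(
    weights: np.ndarray,
    present: np.ndarray,
    depth: int,
    markers: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    w = np.where(present, weights, 0.0)
    props = w / w.sum()
    return {m: rng.multinomial(depth, props) for m in markers}


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_community(
    spec: SyntheticSpec,
) -> tuple[dict[str, OtuTable], dict[str, SampleMeta], TruthLabels]:
    """Generate one IJ-sample table per marker, sample metadata and truth.

    Both markers are built from the same realized per-sample proportions;
    only the multinomial read draws and the taxonomy masking differ.
    Samples where every Bernoulli presence draw fails are redrawn (and
    logged), so each sample contains at least one taxon.
    """
    streams = _streams(spec.seed)
    layouts = _marker_layouts(spec, streams["layout"])
    markers = sorted(spec.markers)
    n_taxa = len(spec.taxa)

    batches = sorted({g.batch for g in spec.groups})
    tau = spec.batch_effect_sd
    delta = {
        b: streams["batch"].normal(0.0, tau, size=n_taxa) if tau > 0
        else np.zeros(n_taxa)
        for b in batches
    }

    theta = np.array([t.occupancy for t in spec.taxa])
    mu = np.array([t.mean_log_weight for t in spec.taxa])
    sigma = np.array([t.sd_log_weight for t in spec.taxa])

    rng = streams["community"]
    metas: dict[str, SampleMeta] = {}
    columns: dict[str, list[np.ndarray]] = {m: [] for m in markers}
    sample_ids: list[str] = []
    for group in spec.groups:
        host_ok = np.array([
            t.host_species in (None, group.host_species) for t in spec.taxa
        ])
        eligible = theta * host_ok
        for rep in range(1, group.n_replicates + 1):
            sid = f"{group.strain}_{group.batch}_r{rep}"
            if sid in metas:
                raise SyntheticSpecError(f"duplicate generated sample id {sid!r}")
            present = rng.random(n_taxa) < eligible
            while not present.any():
                logger.info("resampling presence for empty sample %s", sid)
                present = rng.random(n_taxa) < eligible
            weights = np.exp(rng.normal(mu + delta[group.batch], sigma))
            depth = _draw_depth(spec, rng, spec.depth)
            counts = _sample_counts(weights, present, depth, markers, rng)
            for m in markers:
                columns[m].append(counts[m])
            sample_ids.append(sid)
            metas[sid] = SampleMeta(
                sample_id=sid,
                sample_class="IJ",
                host_species=group.host_species,
                strain=group.strain,
                batch=group.batch,
                laboratory=group.laboratory,
                marker="multi",
                replicate=rep,
            )

    tables = {}
    truth_map: dict[tuple[str, str], str] = {}
    for m in markers:
        otu_ids, taxonomy = layouts[m]
        tables[m] = OtuTable(
            otu_ids=list(otu_ids),
            sample_ids=list(sample_ids),
            counts=np.column_stack(columns[m]),
            taxonomy=dict(taxonomy),
            marker=m,
        )
        for otu, taxon in zip(otu_ids, spec.taxa):
            truth_map[(m, otu)] = taxon.name
    truth = TruthLabels(
        roles={t.name: t.role for t in spec.taxa},
        otu_to_taxon=truth_map,
        taxon_labels={t.name: t.taxon_label() for t in spec.taxa},
    )
    return tables, metas, truth


def simulate_controls(
    spec: SyntheticSpec, n_controls: int = 4
) -> tuple[dict[str, OtuTable], dict[str, SampleMeta]]:
    """Negative-control (kitome) tables: contaminant-role taxa only.

    Contaminants appear with their ``control_occupancy`` (defaulting to
    their sample occupancy); OTU ids and taxonomy match the community
    tables of the same spec.
    """
    contaminants = [t for t in spec.taxa if t.role == "contaminant"]
    if not contaminants:
        raise SyntheticSpecError("spec has no contaminant taxa")
    if n_controls < 1:
        raise SyntheticSpecError("n_controls must be >= 1")
    streams = _streams(spec.seed)
    layouts = _marker_layouts(spec, streams["layout"])
    markers = sorted(spec.markers)
    n_taxa = len(spec.taxa)

    contaminant_mask = np.array([t.role == "contaminant" for t in spec.taxa])
    theta = np.array([
        (t.control_occupancy if t.control_occupancy is not None else t.occupancy)
        if t.role == "contaminant" else 0.0
        for t in spec.taxa
    ])
    mu = np.array([t.mean_log_weight for t in spec.taxa])
    sigma = np.array([t.sd_log_weight for t in spec.taxa])

    rng = streams["controls"]
    metas: dict[str, SampleMeta] = {}
    columns: dict[str, list[np.ndarray]] = {m: [] for m in markers}
    sample_ids = []
    for k in range(1, n_controls + 1):
        sid = f"Control_r{k}"
        present = rng.random(n_taxa) < theta
        while not present.any():
            logger.info("resampling presence for empty control %s", sid)
            present = rng.random(n_taxa) < theta
        weights = np.exp(rng.normal(mu, sigma))
        depth = _draw_depth(spec, rng, spec.control_depth)
        counts = _sample_counts(weights, present, depth, markers, rng)
        for m in markers:
            columns[m].append(counts[m])
        sample_ids.append(sid)
        metas[sid] = SampleMeta(
            sample_id=sid, sample_class="control", marker="multi", replicate=k
        )

    tables = {}
    for m in markers:
        otu_ids, taxonomy = layouts[m]
        keep = [otu_ids[i] for i in range(n_taxa) if contaminant_mask[i]]
        full = OtuTable(
            otu_ids=list(otu_ids),
            sample_ids=list(sample_ids),
            counts=np.column_stack(columns[m]),
            taxonomy=dict(taxonomy),
            marker=m,
        )
        tables[m] = full.select_otus(keep)
    return tables, metas


# ---------------------------------------------------------------------------
# sequence evolution under the K2P process (test input for phylo)
# ---------------------------------------------------------------------------

def simulate_alignment(
    tree: TreeNode | str,
    seq_length: int,
    transition_rate: float = 0.5,
    transversion_rate: float = 0.25,
    seed: int | None = None,
) -> Alignment:
    """Evolve sequences along a tree under the Kimura two-parameter process.

    ``transition_rate`` (alpha) and ``transversion_rate`` (beta, the rate
    to *each* of the two transversion alternatives) define the process;
    with alpha + 2 beta = 1 a branch length equals its expected number of
    substitutions per site, so K2P distances estimate path lengths.  Root
    states are uniform over {A, C, G, T}; sites evolve independently.
    """
    if isinstance(tree, str):
        tree = TreeNode.read([tree], format="newick")
    if transition_rate <= 0 or transversion_rate <= 0:
        raise SyntheticSpecError("substitution rates must be > 0")
    if seq_length < 1:
        raise SyntheticSpecError("seq_length must be >= 1")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise SyntheticSpecError(
                f"negative branch length {node.length} on {node.name!r}"
            )

    alpha, beta = transition_rate, transversion_rate
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length)
    states = {id(tree): root_seq}
    names, rows = [], []
    for node in tree.preorder(include_self=False):
        t = node.length or 0.0
        parent = states[id(node.parent)]
        e1 = np.exp(-4.0 * beta * t)
        e2 = np.exp(-2.0 * (alpha + beta) * t)
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        p_tv_each = 0.25 - 0.25 * e1
        u = rng.random(seq_length)
        child = parent.copy()
        ts_mask = u < p_ts
        tv_mask = (u >= p_ts) & (u < p_ts + 2.0 * p_tv_each)
        child[ts_mask] = (parent[ts_mask] + 2) % 4
        which = rng.integers(0, 2, size=seq_length)  # first or second transversion
        tv_target = (parent + np.where(which == 0, 1, 3)) % 4
        child[tv_mask] = tv_target[tv_mask]
        states[id(node)] = child
        if node.is_tip():
            names.append(str(node.name))
            rows.append("".join("ACGT"[c] for c in child))
    return Alignment(names=names, seqs=rows)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

_DEFAULT_TAXA: list[TaxonSpec] = [
    TaxonSpec(
        name="Xenorhabdus nematophila", role="core_symbiont",
        occupancy=0.98, mean_log_weight=4.5, sd_log_weight=0.6,
        genus="Xenorhabdus", family="Morganellaceae",
        lineage=("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                 "Enterobacterales"),
    ),
    # FAM: high occupancy, intermittently abundant Proteobacteria
    TaxonSpec("Alcaligenes faecalis", "fam", 0.90, -1.3, 1.0,
              genus="Alcaligenes", family="Alcaligenaceae",
              lineage=("Bacteria", "Proteobacteria", "Betaproteobacteria",
                       "Burkholderiales")),
    TaxonSpec("Stenotrophomonas maltophilia", "fam", 0.88, -1.3, 1.0,
              genus="Stenotrophomonas", family="Xanthomonadaceae",
              lineage=("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                       "Xanthomonadales")),
    TaxonSpec("Pseudomonas protegens", "fam", 0.86, -1.3, 1.0,
              genus="Pseudomonas", family="Pseudomonadaceae",
              lineage=("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                       "Pseudomonadales")),
    TaxonSpec("Ochrobactrum sp.", "fam", 0.85, -1.3, 1.0,
              genus="Ochrobactrum", family="Brucellaceae",
              lineage=("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                       "Rhizobiales")),
    TaxonSpec("Achromobacter sp.", "fam", 0.85, -1.3, 1.0,
              genus="Achromobacter", family="Alcaligenaceae",
              lineage=("Bacteria", "Proteobacteria", "Betaproteobacteria",
                       "Burkholderiales")),
    TaxonSpec("Brevundimonas sp.", "fam", 0.84, -1.3, 1.0,
              genus="Brevundimonas", family="Caulobacteraceae",
              lineage=("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                       "Caulobacterales")),
    TaxonSpec("Pseudochrobactrum sp.", "fam", 0.83, -1.3, 1.0,
              genus="Pseudochrobactrum", family="Brucellaceae",
              lineage=("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                       "Rhizobiales")),
    TaxonSpec("Rhizobiaceae taxon", "fam", 0.82, -1.3, 1.0,
              genus=None, family="Rhizobiaceae",
              lineage=("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                       "Rhizobiales")),
    # kitome contaminants; Sphingomonas also infiltrates the IJ samples
    TaxonSpec("Sphingomonas sp.", "contaminant", 0.90, -0.5, 0.8,
              genus="Sphingomonas", family="Sphingomonadaceae",
              lineage=("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                       "Sphingomonadales"),
              control_occupancy=0.98),
    TaxonSpec("Ralstonia sp.", "contaminant", 0.12, 0.0, 0.8,
              genus="Ralstonia", family="Burkholderiaceae",
              lineage=("Bacteria", "Proteobacteria", "Betaproteobacteria",
                       "Burkholderiales"),
              control_occupancy=0.95),
    TaxonSpec("Cutibacterium sp.", "contaminant", 0.08, -0.5, 0.8,
              genus="Cutibacterium", family="Propionibacteriaceae",
              lineage=("Bacteria", "Actinobacteria", "Actinomycetia",
                       "Propionibacteriales"),
              control_occupancy=0.90),
    # rare transients
    TaxonSpec("Enterococcus sp.", "transient", 0.30, -1.5, 1.0,
              genus="Enterococcus", family="Enterococcaceae",
              lineage=("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales")),
    TaxonSpec("Serratia sp.", "transient", 0.25, -1.5, 1.0,
              genus="Serratia", family="Yersiniaceae",
              lineage=("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                       "Enterobacterales")),
    TaxonSpec("Acinetobacter sp.", "transient", 0.20, -1.5, 1.0,
              genus="Acinetobacter", family="Moraxellaceae",
              lineage=("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                       "Pseudomonadales")),
    TaxonSpec("Delftia sp.", "transient", 0.20, -1.5, 1.0,
              genus="Delftia", family="Comamonadaceae",
              lineage=("Bacteria", "Proteobacteria", "Betaproteobacteria",
                       "Burkholderiales")),
    TaxonSpec("Bacillus sp.", "transient", 0.15, -1.5, 1.0,
              genus="Bacillus", family="Bacillaceae",
              lineage=("Bacteria", "Firmicutes", "Bacilli", "Bacillales")),
    TaxonSpec("Chryseobacterium sp.", "transient", 0.10, -1.5, 1.0,
              genus="Chryseobacterium", family="Weeksellaceae",
              lineage=("Bacteria", "Bacteroidetes", "Flavobacteriia",
                       "Flavobacteriales")),
]

_DEFAULT_GROUPS = [
    # strain, batch, laboratory; 6 technical replicates per batch
    ("SK27", "23_08_16", "DGIMI"),
    ("SK27", "27_04_16", "DGIMI"),
    ("SK27", "09_06_15", "DGIMI"),
    ("SK27", "11_08_16", "DGIMI"),
    ("B10", "B10_27_04_16", "DGIMI"),
    ("EGY03", "EGY03_16", "DGIMI"),
    ("CREA", "CREA_16", "DGIMI"),
    ("All", "All_DGIMI_16", "DGIMI"),
    ("DD136", "DD136_DGIMI_16", "DGIMI"),
    ("All", "All_USDA_t0", "USDA"),
    ("DD136", "DD136_USDA_t0", "USDA"),
]

# genus/species assignment rates observed for the two markers
DEFAULT_MARKERS = {
    "V3V4": MarkerSpec(genus_assignment_prob=0.57, species_assignment_prob=0.12),
    "rpoB": MarkerSpec(genus_assignment_prob=0.56, species_assignment_prob=0.32),
}


def default_spec(seed: int = 0, n_replicates: int = 6) -> SyntheticSpec:
    """The default laboratory-rearing study: one host species, 11 batches
    across 6 strains and two laboratories, paired V3V4/rpoB markers."""
    groups = [
        SampleGroup(
            host_species="S_carpocapsae", strain=s, batch=b,
            laboratory=lab, n_replicates=n_replicates,
        )
        for s, b, lab in _DEFAULT_GROUPS
    ]
    return SyntheticSpec(
        groups=groups,
        taxa=[TaxonSpec(**asdict(t)) for t in _DEFAULT_TAXA],
        markers={k: MarkerSpec(**asdict(v)) for k, v in DEFAULT_MARKERS.items()},
        seed=seed,
    )


def recovery_spec(seed: int = 0, n_replicates: int = 6) -> SyntheticSpec:
    """Default community with full genus-level assignment on both markers,
    so the planted FAM genus set is a well-defined recovery target."""
    spec = default_spec(seed=seed, n_replicates=n_replicates)
    spec.markers = {
        "V3V4": MarkerSpec(genus_assignment_prob=1.0, species_assignment_prob=0.12),
        "rpoB": MarkerSpec(genus_assignment_prob=1.0, species_assignment_prob=0.32),
    }
    return spec
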