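# Methods

This note documents the models, rules and numerical choices behind
`famprof`, and what its synthetic-data tests do and do not demonstrate.

## Data model

An `OtuTable` is an integer OTU × sample count matrix with a marker tag
and per-OTU taxonomy. Taxonomy carries a label and a confidence in
[0, 1] for each of seven ranks (domain … species); a lineage may not
resume below an unassigned rank. Counts are strictly integral —
fractional cells are rejected rather than rounded — so that every
aggregation step can be checked for *exact* read conservation.
Serialization is TSV with a trailing `taxonomy` column in a
`d__label(conf);p__…` dialect; a permissive reader accepts Silva-style
`k__;p__;…` strings (confidence defaults to 1.0). A minimal sparse
BIOM-1.0-style JSON reader/writer is included for interoperability;
sample and OTU input order is preserved everywhere, with lexicographic
tie-breaking where an ordering must be invented.

## Filtering and decontamination rules

* **Global cluster filter.** An OTU is dropped when its total read count
  is below `min_total_fraction` (default 5 × 10⁻⁵, i.e. 0.005%) of the
  grand total. Survivors' counts are untouched, so the operation is
  idempotent at a fixed fraction.
* **Replicate core set.** An OTU belongs to a group's core set when its
  per-sample relative abundance exceeds the abundance cut-off (default
  10⁻⁴) in strictly more than the frequency cut-off (default 0.8) of the
  group's samples. All cut-offs are strict `>` comparisons, which makes
  boundary behaviour (e.g. 4 of 5 replicates = frequency 0.8, excluded)
  well defined and testable. Relative abundance is computed on the table
  as passed in; in the CLI workflow that is the post-filter table,
  matching the order in which the operations are chained.
* **Venn partition.** Core sets are split into all 2ᵏ − 1 regions plus a
  `non_core` catch-all for ids present in the supplied universe but in
  no core set; the regions partition the union exactly.
* **Control-taxon removal.** OTUs found in both the control (kitome)
  core and the sample core are removed. Matching defaults to OTU ids
  within a marker; at genus level *every* OTU affiliated to a shared
  genus is removed — the conservative rule appropriate when a reagent
  genus (e.g. *Sphingomonas*) has been detected in the controls. OTU
  ids are never compared across markers, whose clustering runs are
  independent.

## Occupancy–abundance classification

For each OTU over a chosen sample set we compute occurrence (fraction of
samples with a nonzero count) and frequency of high abundance (fraction
of samples where relative abundance exceeds 0.1%). "Present" defaults to
any nonzero count; an `above-threshold` mode is exposed that collapses
presence onto the high-abundance rule, for data sets where singleton
counts are not trusted. Classification applies strict thresholds:
occurrence ≤ 70% → other; otherwise high-abundance frequency > 90% →
core symbiont, else FAM. The rule is monotone in the high-abundance
frequency by construction. Two markers are reconciled by mapping each
called OTU to its lowest confidently assigned rank at genus or family
(confidence ≥ 0.9 by default, the usual bootstrap-confidence convention)
and intersecting the label sets; OTUs resolvable at neither rank are
reported as unresolved rather than silently dropped. Exact-boundary
profiles (occurrence exactly 0.70, high-abundance frequency exactly
0.90) are intentionally avoided in the synthetic defaults, since with
thresholds read as strict inequalities such profiles are knife-edge
cases with no biological meaning.

## Community statistics

* **Shannon index** uses the natural logarithm; the base is a parameter.
* **Rarefaction** is the exact hypergeometric expectation
  E[Sₙ] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n)), evaluated through log-gamma to
  avoid overflow; it equals observed richness at full depth and is
  non-decreasing in depth.
* **Bray–Curtis** is computed on per-sample proportions, square-root
  transformed by default. The transform is applied to proportions rather
  than raw counts because sequencing depths differ between samples; the
  untransformed option is exposed.  Samples are not rarefied to equal
  depth beforehand — proportions already remove the depth scale, and
  subsampling would discard reads and add noise.
* **PCoA** Gower-centers −½D∘D and eigendecomposes. Negative
  eigenvalues (expected for non-Euclidean Bray–Curtis matrices) are
  reported but excluded from the coordinates and from the
  proportion-explained denominator; no Cailliez/Lingoes correction is
  applied. Eigenvalues below 10⁻¹² × the leading eigenvalue are treated
  as zero.
* **PERMANOVA** is one-way only. SS_total = (1/n)Σ_{i<j} d²ᵢⱼ,
  SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²ᵢⱼ, pseudo-F =
  (SS_among/(a−1))/(SS_within/(n−a)), R² = SS_among/SS_total. The
  p-value is (#{F* ≥ F} + 1)/(m + 1) under random relabelling with fixed
  group sizes (default m = 9999), with the permutation null evaluated in
  a single vectorized pass; R² and pseudo-F do not depend on the
  permutations. A factor with one level, or with no residual degrees of
  freedom, is an error. When SS_within = 0 the pseudo-F is reported as
  infinity rather than an exception, so perfectly separated toy inputs
  remain usable.

## Phylogenetics

K2P distances use pairwise deletion of gaps and ambiguous bases by
default (complete deletion is an option); saturation
(1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0) raises a dedicated error naming the
sequence pair. Neighbour joining follows Saitou–Nei with the
Studier–Keppler Q-criterion; ties in Q are broken by the lowest index
pair in the current node ordering, making topologies deterministic.
Negative branch lengths are clamped to zero with the deficit moved to
the sibling branch (the common convention), and the final three nodes
are joined as a trifurcating root with closed-form lengths, so additive
matrices are reproduced exactly. Bootstrap support resamples alignment
columns with replacement; a per-pair site-category table (same /
transition / transversion / incomparable) is precomputed once so each
replicate reduces to counting. Replicates with a saturated or undefined
distance are skipped and counted, with a warning above 5% skipped;
support is the percentage of completed replicates containing the
bipartition, written as internal node labels in Newick output.

## Synthetic community model

The generator is a deliberate stand-in: the studies this pipeline serves
publish no generative model, so we use the simplest construction that
decouples occupancy from abundance, the axis separation on which the
core/FAM classification rests.

For sample j and taxon i: presence Zᵢⱼ ~ Bernoulli(θᵢ); conditional
abundance weight Wᵢⱼ = exp(Normal(μᵢ + δᵢ,b(j), σᵢ)) with batch effect
δᵢ,b ~ Normal(0, τ) drawn once per (taxon, batch); proportions are the
normalized weights of present taxa; counts per marker are
Multinomial(depth, proportions) on the *same* realized proportions, so
the two markers see one underlying community through independent read
draws. Column sums therefore equal the realized depths exactly. Samples
with no present taxon are redrawn (and logged). All randomness derives
from one seed through four named substreams (layout, batch effects,
community, controls), so identical seeds reproduce identical bytes and
control tables share OTU ids and masked taxonomy with their community
tables without regenerating them.

Default study conditions: one host species, 11 multiplication batches
across 6 strains and two laboratories, 6 technical replicates each
(66 samples), fixed depth 20 000 reads (controls 2 000 — kitome
libraries are low-biomass), τ = 0.8. The planted community is one
dominant symbiont (θ = 0.98, μ = 4.5), eight FAM Proteobacteria
(θ = 0.82–0.90, μ = −1.3, σ = 1.0 — roughly 0.3% relative abundance when
present, hence intermittently above the 0.1% threshold), three
contaminants (one *Sphingomonas*-like taxon that also infiltrates the IJ
samples at θ = 0.9, two kitome-only genera with high control occupancy
but rare leakage) and six low-occupancy transients. FAM occupancies sit
in the upper part of the intermediate range because occurrence is
estimated from 66 samples: binomial noise around a strict 70% cut-off
would otherwise make exact set recovery a coin flip rather than a test
of the method. Marker taxonomy masking uses the genus/species
assignment rates observed for the two markers (57%/12% for V3V4,
56%/32% for rpoB). Recovery experiments use a variant with
genus-assignment probability 1.0, because under random genus masking the
"planted FAM genus set" is not a well-defined target — a masked genus
legitimately falls back to its family label.

What passing the recovery tests shows: on data generated by *this*
model, the pipeline removes planted contaminants, calls exactly one core
symbiont and recovers the planted FAM set in ≥ 90% of seeded runs. What
it does not show: robustness to compositional effects the model omits —
PCR/primer bias, chimeras, cross-talk between samples, overdispersed
(non-multinomial) counts, copy-number variation, or OTU-clustering
artefacts. Results on real data inherit those caveats.

## Problem sizes

The test suite and acceptance script favour many small replicates over
few large ones: recovery rates use 100 pipeline runs at 66 samples ×
18 taxa × 2 markers; the PERMANOVA type-I error uses 2000 null data sets
of 12 samples with 199 permutations each; exhaustive oracles (rarefaction
subsets, 3+3 PERMANOVA relabellings) run at sizes where complete
enumeration is feasible; bootstrap checks use 5-taxon trees with
2 000-site alignments and 1 000 replicates. These sizes give stable
pass/fail behaviour for the stated thresholds while keeping a full run
in the order of seconds to a minute.

## Known limitations

* One-way PERMANOVA only; no PERMDISP companion test, so location and
  dispersion effects are confounded as in any PERMANOVA-only analysis.
* The decontamination logic is set-based (core-set intersection), not a
  statistical contaminant model; a contaminant whose in-sample frequency
  falls below the core cut-off escapes removal (and occasionally does in
  the synthetic runs).
* The BIOM reader targets the sparse JSON dialect only, not HDF5 BIOM.
* NJ tie-breaking and deletion conventions differ between published
  implementations; trees on saturated or highly gapped alignments may
  legitimately differ from other software at weakly supported nodes.
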