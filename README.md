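# famprof

Profiling the bacterial communities carried by entomopathogenic-nematode
infective juveniles (IJs) from multi-marker amplicon OTU tables.

Laboratory-reared *Steinernema* nematodes were long assumed to carry only
their obligate symbiont (*Xenorhabdus nematophila* for *S. carpocapsae*).
Metabarcoding of IJ samples tells a richer story: besides the symbiont, a
set of Proteobacteria shows up in most samples — a **frequently associated
microbiota (FAM)** — while reagent contaminants ("kitome") and rare
transients muddy the picture. `famprof` is a small analysis toolkit for
separating these signals. It is aimed at microbial-ecology researchers
working with low-biomass amplicon data sets profiled with more than one
marker (e.g. 16S V3V4 and *rpoB*).

## What it computes

**Filtering and decontamination.** OTUs with a total read count below
0.005% of all reads are discarded. For a replicate group, the *core set*
is every OTU whose relative abundance exceeds 0.01% in strictly more than
80% of replicates; core sets of IJ samples and negative controls are
intersected (Venn partition), and any taxon shared with the controls —
matched at OTU level within a marker, at genus level across tables — is
removed as a kitome contaminant.

**Occupancy–abundance classification.** For each OTU over a sample set,

- occurrence = fraction of samples with a nonzero count,
- frequency of high abundance = fraction of samples where the OTU exceeds
  0.1% relative abundance.

OTUs occurring in > 70% of samples split into the **core symbiont**
(high-abundance frequency > 90%: abundant essentially whenever present)
and the **FAM** (frequent but only intermittently abundant); all other
OTUs are "other". Calls from two markers are reconciled at taxon level
(genus, falling back to family); the consensus is the label set supported
by both markers.

**Community statistics**, implemented from first principles: observed
richness and Shannon index H = −Σ pᵢ ln pᵢ; exact analytic rarefaction
E[Sₙ] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n)); Bray–Curtis dissimilarity on
square-root-transformed proportions; principal coordinates analysis
(Gower double-centering + eigendecomposition); one-way PERMANOVA with
pseudo-F, R² = SS_among/SS_total and a seeded permutation p-value.

**Isolate phylogenetics.** Kimura two-parameter distances
d = −½ ln((1 − 2P − Q)·√(1 − 2Q)), Saitou–Nei neighbour joining, and
column-bootstrap support values (percent of replicates containing each
bipartition).

**Synthetic communities.** A generative model (Bernoulli occupancy ×
log-normal abundance weights × multinomial reads, with per-(taxon, batch)
effects and marker-specific taxonomy masking) plants a known symbiont,
FAM, contaminants and transients, so every stage of the pipeline can be
tested against ground truth without downloading anything.

## Worked example

Generate a synthetic study (66 IJ samples: 11 batches × 6 technical
replicates, plus negative controls; paired V3V4/rpoB markers) and run the
pipeline on the V3V4 table:

```sh
famprof simulate --seed 1 --out-dir demo
famprof filter demo/community_V3V4.tsv --out demo/filtered_V3V4.tsv
famprof decontam demo/filtered_V3V4.tsv demo/controls_V3V4.tsv \
    --level genus --out demo/clean_V3V4.tsv --report demo/removed.tsv
famprof core-fam demo/clean_V3V4.tsv --out demo/profiles_V3V4.tsv
famprof permanova demo/community_rpoB.tsv demo/samples.tsv \
    --factor batch --permutations 9999 --seed 1
```

which prints:

```
wrote 2 marker tables (66 samples, 6 controls) to demo
kept 18/18 OTUs -> demo/filtered_V3V4.tsv
removed 1 OTUs (Sphingomonas)
calls: {'FAM': 8, 'other': 8, 'core_symbiont': 1}
PERMANOVA: Df = 10, R2 = 0.28, pseudo-F = 2.091, p = 0.0006 (9999 permutations)
```

Reading the output: exactly one OTU was shared between the IJ and
control core sets and removed as a kitome contaminant (the planted
*Sphingomonas*); of the remaining OTUs, one is called the core symbiont
(the planted *Xenorhabdus*), eight are FAM (the planted facultative
Proteobacteria), and the low-occupancy transients are "other". The
PERMANOVA shows that multiplication batch explains 28% of the
compositional variance in this simulation (p ≈ 10⁻³ under 9999
permutations). The same operations are available as library functions
(`famprof.run_pipeline`, `famprof.permanova`, ...) for scripted use.

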