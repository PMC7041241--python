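import numpy as np
import pytest

from famprof import (
    MarkerSpec,
    SampleGroup,
    SyntheticSpec,
    SyntheticSpecError,
    TaxonSpec,
    bray_curtis,
    k2p_distance,
    permanova,
    simulate_alignment,
    simulate_community,
    simulate_controls,
)
from famprof.simulate import default_spec, recovery_spec


def tiny_spec(taxa, seed=0, n_replicates=3, depth=100, tau=0.0, markers=None):
    return SyntheticSpec(
        groups=[SampleGroup("host", "strainA", "batch1", "lab", n_replicates)],
        taxa=taxa,
        markers=markers or {"V3V4": MarkerSpec(1.0, 1.0)},
        depth=depth,
        batch_effect_sd=tau,
        seed=seed,
    )


def symbiont(**kw):
    defaults = dict(name="Xenorhabdus nematophila", role="core_symbiont",
                    occupancy=1.0, mean_log_weight=4.0, sd_log_weight=0.5,
                    genus="Xenorhabdus", family="Morganellaceae")
    defaults.update(kw)
    return TaxonSpec(**defaults)


class TestSpecValidation:
    def test_requires_exactly_one_symbiont_per_host(self):
        with pytest.raises(SyntheticSpecError, match="core symbiont"):
            tiny_spec([TaxonSpec("t", "transient", 0.5, 0.0)])
        with pytest.raises(SyntheticSpecError, match="core symbiont"):
            tiny_spec([symbiont(), symbiont(name="Another symbiont")])

    def test_parameter_domains(self):
        with pytest.raises(SyntheticSpecError):
            TaxonSpec("x", "fam", occupancy=1.5, mean_log_weight=0)
        with pytest.raises(SyntheticSpecError):
            TaxonSpec("x", "fam", occupancy=0.5, mean_log_weight=0,
                      sd_log_weight=-1)
        with pytest.raises(SyntheticSpecError):
            MarkerSpec(1.2, 0.5)
        with pytest.raises(SyntheticSpecError):
            tiny_spec([symbiont()], tau=-0.1)

    def test_yaml_round_trip(self, tmp_path):
        spec = default_spec(seed=7)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        again = SyntheticSpec.from_yaml(path)
        assert again == spec


class TestSimulateCommunity:
    def test_single_taxon_full_occupancy_gives_constant_columns(self):
        tables, metas, truth = simulate_community(
            tiny_spec([symbiont(occupancy=1.0)], depth=100, n_replicates=3))
        t = tables["V3V4"]
        assert t.n_otus == 1 and t.n_samples == 3
        assert (t.counts == 100).all()
        assert truth.roles["Xenorhabdus nematophila"] == "core_symbiont"

    def test_column_sums_equal_depth_exactly(self):
        spec = default_spec(seed=3, n_replicates=2)
        tables, _, _ = simulate_community(spec)
        for t in tables.values():
            assert (t.counts.sum(axis=0) == spec.depth).all()

    def test_same_seed_reproduces_every_byte(self, tmp_path):
        from famprof import write_otu_table
        for run in range(2):
            tables, metas, truth = simulate_community(default_spec(seed=11))
            write_otu_table(tables["rpoB"], tmp_path / f"t{run}.tsv")
            truth.write_tsv(tmp_path / f"truth{run}.tsv")
        assert (tmp_path / "t0.tsv").read_bytes() == \
            (tmp_path / "t1.tsv").read_bytes()
        assert (tmp_path / "truth0.tsv").read_bytes() == \
            (tmp_path / "truth1.tsv").read_bytes()

    def test_markers_share_samples_but_not_otu_ids(self):
        tables, _, truth = simulate_community(default_spec(seed=5))
        v, r = tables["V3V4"], tables["rpoB"]
        assert v.sample_ids == r.sample_ids
        assert not (set(v.otu_ids) & set(r.otu_ids))
        # every OTU maps to exactly one taxon
        for (marker, otu), name in truth.otu_to_taxon.items():
            assert otu in tables[marker].otu_ids
            assert name in truth.roles

    def test_dominant_symbiont_exceeds_transients_in_mean_proportion(self):
        taxa = [symbiont(occupancy=1.0, mean_log_weight=4.0)] + [
            TaxonSpec(f"transient {i}", "transient", 0.2, 0.0, 1.0,
                      genus=f"Genus{i}", family="F")
            for i in range(10)
        ]
        spec = tiny_spec(taxa, seed=2, n_replicates=200, depth=1000)
        tables, _, _ = simulate_community(spec)
        props = tables["V3V4"].counts / 1000
        means = props.mean(axis=1)
        assert all(means[0] > means[i] for i in range(1, 11))

    def test_batch_effect_increases_permanova_r2(self):
        taxa = [symbiont(occupancy=1.0, mean_log_weight=2.0, sd_log_weight=0.3)] + [
            TaxonSpec(f"fam {i}", "fam", 1.0, 0.0, 0.3,
                      genus=f"Genus{i}", family="F")
            for i in range(8)
        ]

        def r2(tau, seed):
            spec = SyntheticSpec(
                groups=[
                    SampleGroup("host", "s", f"batch{b}", "lab", 5)
                    for b in range(4)
                ],
                taxa=[TaxonSpec(**vars(t)) for t in taxa],
                markers={"V3V4": MarkerSpec(1.0, 1.0)},
                depth=2000, batch_effect_sd=tau, seed=seed,
            )
            tables, metas, _ = simulate_community(spec)
            dm = bray_curtis(tables["V3V4"])
            grouping = {s: metas[s].batch for s in tables["V3V4"].sample_ids}
            return permanova(dm, grouping, n_permutations=99, seed=0).r_squared

        wins = sum(r2(2.0, seed) > r2(0.0, seed) for seed in range(20))
        assert wins >= 18

    def test_host_restricted_symbionts(self):
        taxa = [
            symbiont(host_species="hostA"),
            symbiont(name="Photorhabdus luminescens", genus="Photorhabdus",
                     host_species="hostB"),
        ]
        spec = SyntheticSpec(
            groups=[SampleGroup("hostA", "sA", "bA", "lab", 4),
                    SampleGroup("hostB", "sB", "bB", "lab", 4)],
            taxa=taxa, markers={"V3V4": MarkerSpec(1.0, 1.0)},
            depth=500, seed=1,
        )
        tables, metas, truth = simulate_community(spec)
        t = tables["V3V4"]
        a_cols = [j for j, s in enumerate(t.sample_ids)
                  if metas[s].host_species == "hostA"]
        b_cols = [j for j, s in enumerate(t.sample_ids)
                  if metas[s].host_species == "hostB"]
        xeno = t.otu_ids.index(
            next(o for (m, o), n in truth.otu_to_taxon.items()
                 if n == "Xenorhabdus nematophila"))
        assert (t.counts[xeno, a_cols] > 0).all()
        assert (t.counts[xeno, b_cols] == 0).all()


class TestSimulateControls:
    def test_controls_contain_only_contaminants(self):
        spec = default_spec(seed=9)
        tables, _ = simulate_controls(spec, n_controls=4)
        for t in tables.values():
            assert t.n_otus == 3 and t.n_samples == 4
            genera = {t.taxonomy[o].label_at("genus") for o in t.otu_ids}
            # taxonomy may be masked, but ids map to contaminant taxa only
        _, _, truth = simulate_community(spec)
        for m, t in tables.items():
            for o in t.otu_ids:
                assert truth.roles[truth.otu_to_taxon[(m, o)]] == "contaminant"

    def test_certain_contaminant_present_in_all_controls(self):
        taxa = [symbiont(),
                TaxonSpec("Sphingomonas sp.", "contaminant", 0.5, 0.0,
                          genus="Sphingomonas", family="Sphingomonadaceae",
                          control_occupancy=1.0)]
        tables, _ = simulate_controls(tiny_spec(taxa, seed=4), n_controls=6)
        t = tables["V3V4"]
        assert (t.counts > 0).all()

    def test_no_contaminants_rejected(self):
        with pytest.raises(SyntheticSpecError, match="contaminant"):
            simulate_controls(tiny_spec([symbiont()]), 3)


class TestSimulateAlignment:
    def test_zero_length_branches_give_identical_sequences(self):
        aln = simulate_alignment("((A:0,B:0):0,C:0);", 200, seed=1)
        assert aln.seqs[0] == aln.seqs[1] == aln.seqs[2]

    def test_fixed_seed_fixes_bytes(self, tmp_path):
        for run in range(2):
            aln = simulate_alignment("(A:0.1,B:0.2);", 500, seed=42)
            aln.write_fasta(tmp_path / f"a{run}.fasta")
        assert (tmp_path / "a0.fasta").read_bytes() == \
            (tmp_path / "a1.fasta").read_bytes()

    def test_k2p_distance_consistent_at_long_lengths(self):
        aln = simulate_alignment("(A:0.05,B:0.05);", 100000,
                                 transition_rate=0.5, transversion_rate=0.25,
                                 seed=8)
        d = k2p_distance(aln.seqs[0], aln.seqs[1])
        assert d == pytest.approx(0.1, abs=0.01)

    def test_negative_branch_rejected(self):
        with pytest.raises(SyntheticSpecError, match="negative branch"):
            simulate_alignment("(A:-0.1,B:0.1);", 100, seed=0)
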