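"""Coalescent simulator: genealogies, sequence evolution, gene conversion."""

import numpy as np
import pytest

from gbgcscan.errors import InputError
from gbgcscan.simulate import (
    SimulationConfig,
    apply_gene_conversion,
    evolve_sequences,
    sample_codon_root,
    simulate_clonal_tree,
    simulate_dataset,
    write_dataset,
)


class TestClonalTree:
    def test_two_lineages_single_coalescence(self):
        tree = simulate_clonal_tree(2, seed=1)
        assert tree.n_leaves == 2
        assert tree.n_nodes == 3
        # both pendant branches span the whole tree depth
        assert tree.total_branch_length == pytest.approx(2 * tree.time.max())

    def test_deterministic_newick(self):
        assert simulate_clonal_tree(8, seed=11).newick == simulate_clonal_tree(8, seed=11).newick
        assert simulate_clonal_tree(8, seed=11).newick != simulate_clonal_tree(8, seed=12).newick

    def test_expected_total_length_matches_coalescent(self):
        # E[total length] = 2 * sum_{k=1}^{n-1} 1/k for Ne = 1 haploid lineages
        n, reps = 6, 400
        expected = 2 * sum(1 / k for k in range(1, n))
        lengths = [simulate_clonal_tree(n, seed=s + 1).total_branch_length for s in range(reps)]
        se = np.std(lengths, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(lengths) - expected) < 3 * se

    def test_too_few_genomes_rejected(self):
        with pytest.raises(InputError):
            simulate_clonal_tree(1, seed=1)


class TestEvolveSequences:
    def test_no_mutation_keeps_root_everywhere(self):
        tree = simulate_clonal_tree(6, seed=3)
        root = "ACG" * 100
        a = evolve_sequences(tree, 300, theta=0.0, lambda_mut=1.0, B=0.0,
                             seed=4, root_seq=root)
        assert all(s == root for s in a.seqs)

    def test_symmetric_process_is_gc_balanced(self):
        tree = simulate_clonal_tree(6, seed=5)
        a = evolve_sequences(tree, 20_000, theta=0.2, lambda_mut=1.0, B=0.0, seed=6)
        gc = np.mean([sum(c in "GC" for c in s) / 20_000 for s in a.seqs])
        assert gc == pytest.approx(0.5, abs=0.02)

    def test_at_biased_mutation_lowers_gc(self):
        tree = simulate_clonal_tree(6, seed=7)
        a = evolve_sequences(tree, 20_000, theta=0.2, lambda_mut=2.0, B=0.0, seed=8)
        gc = np.mean([sum(c in "GC" for c in s) / 20_000 for s in a.seqs])
        assert gc == pytest.approx(1 / 3, abs=0.02)

    def test_codon_root_biases_composition(self, rng):
        seq = sample_codon_root(200, rng, pi3=0.9)
        gc3 = sum(c in "GC" for c in seq[2::3]) / 200
        assert gc3 > 0.6


class TestGeneConversion:
    def _aln(self):
        tree = simulate_clonal_tree(6, seed=21)
        return evolve_sequences(tree, 900, theta=0.05, lambda_mut=2.0, B=0.0, seed=22)

    def test_zero_events_is_identity(self):
        a = self._aln()
        b, events = apply_gene_conversion(a, 0, 200, 0.5, seed=1)
        assert b.seqs == a.seqs
        assert events == []

    def test_taxa_and_length_conserved(self):
        a = self._aln()
        b, _ = apply_gene_conversion(a, 10, 200, 0.8, seed=2)
        assert b.taxa == a.taxa
        assert b.length == a.length

    def test_forced_gc_transmission(self, make_alignment):
        a = make_alignment(["G" * 60, "A" * 60], taxa=("d", "r"))
        b, events = apply_gene_conversion(a, 1, 60, 1.0, seed=3)
        # every site is GC/AT-heterozygous: with p_gc = 1 the recipient ends
        # up all-GC whichever lineage donates; the donor is untouched
        recipient = a.taxa.index(events[0].recipient)
        assert set(b.seqs[recipient]) == {"G"}
        assert b.seqs[1 - recipient] == a.seqs[1 - recipient]
        assert events[0].n_het == 60
        assert events[0].n_to_gc == 60

    def test_changes_confined_to_logged_tracts(self):
        a = self._aln()
        b, events = apply_gene_conversion(a, 3, 150, 0.5, seed=4)
        changed = {
            i
            for s_old, s_new in zip(a.seqs, b.seqs)
            for i, (x, y) in enumerate(zip(s_old, s_new))
            if x != y
        }
        covered = set()
        for e in events:
            covered |= set(range(e.start, e.end))
        assert changed <= covered

    def test_oversized_tract_rejected(self):
        with pytest.raises(InputError):
            apply_gene_conversion(self._aln(), 1, 901, 0.5, seed=5)

    def test_unbiased_transmission_preserves_mean_gc(self, rng):
        # over many events between random lineages, p_gc = 0.5 should not
        # change the expected GC of the alignment
        a = self._aln()
        gc0 = np.mean([sum(c in "GC" for c in s) for s in a.seqs])
        deltas = []
        for s in range(40):
            b, _ = apply_gene_conversion(a, 5, 200, 0.5, seed=s)
            deltas.append(np.mean([sum(c in "GC" for c in sq) for sq in b.seqs]) - gc0)
        assert abs(np.mean(deltas)) < 3 * np.std(deltas, ddof=1) / np.sqrt(40) + 0.5


class TestSimulateDataset:
    @pytest.fixture(scope="class")
    def small_sim(self):
        return simulate_dataset(SimulationConfig(n_families=12, n_genomes=6, seed=9))

    def test_ground_truth_consistent(self, small_sim):
        t = small_sim.truth
        assert len(t) == 12
        assert set(t.rate_class) <= {"low", "high"}
        assert (t.loc[t.rate_class == "high", "conv_rate"] == 4.0).all()
        assert t.is_rp.sum() == round(0.1 * 12)
        assert len(small_sim.group.families) == 12
        for fam in small_sim.group.families:
            assert fam.length == 900
            assert fam.taxa == small_sim.group.genomes

    def test_byte_identical_reruns(self, tmp_path, small_sim):
        cfg = SimulationConfig(n_families=12, n_genomes=6, seed=9)
        d1 = write_dataset(simulate_dataset(cfg), tmp_path / "a")
        d2 = write_dataset(simulate_dataset(cfg), tmp_path / "b")
        for p1 in sorted(d1.rglob("*")):
            if p1.is_file():
                p2 = d2 / p1.relative_to(d1)
                assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_different_seeds_differ(self, small_sim):
        other = simulate_dataset(SimulationConfig(n_families=12, n_genomes=6, seed=10))
        assert other.group.families[0].seqs != small_sim.group.families[0].seqs

    def test_biased_high_rate_genes_are_gc3_richer(self):
        sim = simulate_dataset(SimulationConfig(n_families=60, p_gc=0.8, seed=13))
        from gbgcscan.composition import family_mean_gc

        gc3 = {f.family_id: family_mean_gc(f).gc3 for f in sim.group.families}
        t = sim.truth
        hi = t.loc[t.rate_class == "high", "family_id"].map(gc3).mean()
        lo = t.loc[t.rate_class == "low", "family_id"].map(gc3).mean()
        assert hi > lo + 0.05

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_families=5, seed=3, p_gc=0.7)
        cfg.to_yaml(tmp_path / "c.yml")
        assert SimulationConfig.from_yaml(tmp_path / "c.yml") == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(InputError):
            SimulationConfig(n_genomes=4)
        with pytest.raises(InputError):
            SimulationConfig(gene_length=901)
        with pytest.raises(InputError):
            SimulationConfig(p_gc=1.2)
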