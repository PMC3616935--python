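"""The synthetic-data generator: determinism, stationarity, structure."""

import numpy as np
import pytest
from scipy import stats

from codonet.codon_model import build_rate_matrix, transition_probs, uniform_pi
from codonet.io import read_codon_alignment, write_codon_alignment
from codonet.simulate import (
    SimulationSpec,
    mammal9_fixture,
    random_connected_network,
    simulate_alignment,
    simulate_study,
)
from codonet.tree import parse_newick

STUDY_TAXA = {
    "human", "chimpanzee", "gorilla", "orangutan", "macaque",
    "marmoset", "mouse", "rat", "dog",
}


class TestMammal9Fixture:
    def test_nine_study_taxa(self):
        tree = mammal9_fixture()
        assert set(tree.leaf_labels()) == STUDY_TAXA
        assert len(tree.leaf_labels()) == 9

    def test_focal_ancestral_branches_addressable(self):
        tree = mammal9_fixture()
        for label in ("hominids", "rodents"):
            tagged = tree.with_foreground(label)
            assert tagged.foreground.sum() == 1

    def test_binary_with_root_trifurcation(self):
        tree = mammal9_fixture()
        root = tree.root
        assert len(tree.children[root]) == 3  # unrooted convention
        for v in range(tree.n_nodes):
            if v != root and not tree.is_leaf(v):
                assert len(tree.children[v]) == 2


class TestSimulateAlignment:
    def test_determinism(self):
        spec = SimulationSpec(seed=4, n_codons=50)
        a = simulate_alignment(spec)
        b = simulate_alignment(spec)
        assert a.taxa == b.taxa
        assert np.array_equal(a.codons, b.codons)

    def test_zero_branch_lengths_copy_root(self):
        tree = mammal9_fixture()
        tree.branch_lengths[:] = 0.0
        spec = SimulationSpec(seed=1, n_codons=40, tree=tree)
        aln = simulate_alignment(spec)
        assert np.all(aln.codons == aln.codons[0])

    def test_equilibrium_codon_frequencies(self, code):
        # the process is stationary: leaf codon frequencies ~ multinomial(pi)
        spec = SimulationSpec(seed=2, n_codons=10_000)
        aln = simulate_alignment(spec)
        pi = uniform_pi(code)
        counts = np.bincount(aln.codons[3], minlength=61)
        se = np.sqrt(pi * (1 - pi) * aln.n_sites)
        outside = np.abs(counts - pi * aln.n_sites) > 3 * se
        assert outside.sum() <= 2  # ~0.3 expected at 3 SE over 61 bins

    def test_branch_substitution_count(self, code):
        # observed pair differences match n * (1 - sum_i pi_i P_ii(t))
        t = 0.15
        tree = parse_newick(f"(A:{t/2},B:{t/2});")
        spec = SimulationSpec(
            seed=8, n_codons=5000, tree=tree, model_params={"omega": 1.0}
        )
        aln = simulate_alignment(spec)
        pi = uniform_pi(code)
        Q = build_rate_matrix(spec.kappa, 1.0, pi, code)
        P = transition_probs(Q, t)
        p_diff = 1 - float(pi @ np.diag(P))
        observed = int((aln.codons[0] != aln.codons[1]).sum())
        se = np.sqrt(5000 * p_diff * (1 - p_diff))
        assert abs(observed - 5000 * p_diff) < 3 * se

    def test_roundtrip_through_fasta(self, tmp_path, code):
        spec = SimulationSpec(seed=6, n_codons=30)
        aln = simulate_alignment(spec)
        path = tmp_path / "sim.fasta"
        write_codon_alignment(aln, path, code)
        again = read_codon_alignment(path, code)
        assert again.taxa == aln.taxa
        assert np.array_equal(again.codons, aln.codons)


class TestRandomNetwork:
    def test_connected_with_exact_edge_count(self):
        rng = np.random.default_rng(0)
        import networkx as nx

        G = random_connected_network(30, 81, rng)
        assert G.number_of_nodes() == 30
        assert G.number_of_edges() == 81
        assert nx.is_connected(G)

    def test_infeasible_requests_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            random_connected_network(10, 8, rng)  # below spanning tree
        with pytest.raises(ValueError):
            random_connected_network(5, 11, rng)  # above simple capacity


class TestSimulateStudy:
    @pytest.fixture(scope="class")
    def small_study(self):
        spec = SimulationSpec(seed=10, n_genes=14, n_network_nodes=8,
                              n_network_edges=12, n_codons=40)
        return spec, simulate_study(spec)

    def test_structure(self, small_study):
        spec, (alignments, network, annotations, truth) = small_study
        assert len(alignments) == 14
        assert network.number_of_edges() == 12
        assert len(truth) == 14
        assert truth["in_network"].sum() == 8
        # non-network genes play the retinoid-cycle/development part
        off = truth[~truth["in_network"]]
        assert set(off["process"]) <= {"retinoid_cycle", "development"}
        assert np.all(truth["true_omega"] < 1)

    def test_determinism(self, small_study):
        spec, (alignments, _, _, truth) = small_study
        alignments2, _, _, truth2 = simulate_study(spec)
        assert truth.equals(truth2)
        g = truth["gene"].iloc[0]
        assert np.array_equal(alignments[g].codons, alignments2[g].codons)

    def test_noiseless_slope_gives_perfect_rank_order(self):
        spec = SimulationSpec(
            seed=9, n_genes=8, n_network_nodes=8, n_network_edges=10,
            n_codons=10, noise_scale=0.0, group_shifts={},
            topology_slope=0.05, omega_bounds=(0.001, 0.999),
        )
        _, network, _, truth = simulate_study(spec)
        import networkx as nx

        clo = nx.closeness_centrality(network, wf_improved=False)
        sub = truth[truth["in_network"]]
        rho = stats.spearmanr(
            [clo[g] for g in sub["gene"]], sub["true_omega"]
        ).statistic
        assert np.isclose(rho, -1.0)

    def test_flat_spec_is_null(self):
        spec = SimulationSpec(
            seed=9, n_genes=8, n_network_nodes=8, n_network_edges=10,
            n_codons=10, noise_scale=0.0, group_shifts={}, topology_slope=0.0,
        )
        _, _, _, truth = simulate_study(spec)
        assert truth["true_omega"].nunique() == 1

    def test_default_network_mirrors_curated_size(self):
        spec = SimulationSpec(seed=0)
        assert spec.n_network_edges == 81
        assert spec.n_genes == 54
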