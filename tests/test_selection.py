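"""LRTs, multiple-testing correction and BEB site identification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonet.fit import FitConfig, fit_model
from codonet.selection import (
    adjust_pvalues,
    attach_adjusted,
    beb_site_posteriors,
    branch_site_test,
    lrt,
    site_model_tests,
)
from codonet.simulate import SimulationSpec, mammal9_fixture, simulate_alignment

FAST = FitConfig(start_omegas=(0.5,))


class TestLRT:
    def test_closed_form_chi2_df2(self):
        # chi2_2 survival has the closed form exp(-x/2): stat 6 -> exp(-3)
        stat, p = lrt(-100.0, -103.0, df=2)
        assert stat == 6.0
        assert np.isclose(p, np.exp(-3.0), rtol=1e-12)

    def test_equal_likelihoods(self):
        stat, p = lrt(-100.0, -100.0, df=1)
        assert stat == 0.0 and p == 1.0

    def test_negative_statistic_clamped(self, caplog):
        stat, p = lrt(-100.000001, -100.0, df=1)
        assert stat == 0.0 and p == 1.0

    def test_mixture_null_halves_p(self):
        stat, p_plain = lrt(-100.0, -102.0, df=1)
        _, p_mix = lrt(-100.0, -102.0, df=1, mixture=True)
        assert np.isclose(p_mix, 0.5 * p_plain)

    def test_df_restricted(self):
        with pytest.raises(ValueError):
            lrt(-1.0, -2.0, df=3)


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        # min over j>=i of p_(j) * m / j: all four collapse to 0.04
        adj = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.123])[0] == 0.123

    def test_all_ones(self):
        assert np.allclose(adjust_pvalues([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12),
        st.randoms(use_true_random=False),
    )
    def test_bh_monotone_and_order_invariant(self, ps, rnd):
        adj = adjust_pvalues(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        # monotone in the raw p-values
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        # invariant to input order
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        adj_perm = adjust_pvalues([ps[i] for i in perm])
        assert np.allclose(adj_perm, adj[perm])

    def test_bonferroni_and_holm_available(self):
        ps = [0.01, 0.04]
        assert np.allclose(adjust_pvalues(ps, "bonferroni"), [0.02, 0.08])
        assert np.allclose(adjust_pvalues(ps, "holm"), [0.02, 0.04])


class TestSiteTests:
    def test_df_and_structure(self, m0_alignment, mammal_tree):
        results = site_model_tests(m0_alignment, mammal_tree, FAST)
        assert [r.test for r in results] == ["M1a_vs_M2a", "M7_vs_M8"]
        assert all(r.df == 2 for r in results)
        assert all(r.lnL_alt >= r.lnL_null - 1e-6 for r in results)
        assert all(0 <= r.p_raw <= 1 for r in results)
        attach_adjusted(results)
        assert all(r.p_adjusted >= r.p_raw - 1e-12 for r in results)

    def test_purifying_data_not_significant(self, m0_alignment, mammal_tree):
        # uniform omega=0.3 data gives the alternatives nothing to find
        results = site_model_tests(m0_alignment, mammal_tree, FAST)
        assert all(r.p_raw > 0.05 for r in results)


class TestBranchSiteTest:
    def test_df_is_one_and_foreground_recorded(self, m0_alignment, mammal_tree):
        r = branch_site_test(m0_alignment, mammal_tree, "rodents", FAST)
        assert r.df == 1
        assert r.branch == "rodents"
        assert r.lnL_alt >= r.lnL_null - 1e-6

    def test_unknown_branch_rejected(self, m0_alignment, mammal_tree):
        with pytest.raises(Exception):
            branch_site_test(m0_alignment, mammal_tree, "no_such_branch", FAST)

    def test_detects_planted_foreground_selection(self):
        # strong effect: 30% of sites at omega2=6 on the rodent ancestor
        spec = SimulationSpec(
            seed=77, n_codons=400, model_name="branch_site_A",
            model_params={"omega0": 0.1, "p0": 0.5, "p1": 0.2, "omega2": 6.0},
            tree=mammal9_fixture().with_foreground("rodents"),
        )
        aln = simulate_alignment(spec)
        r = branch_site_test(aln, mammal9_fixture(), "rodents", FAST)
        assert r.p_raw < 0.05


class TestBEB:
    @pytest.fixture(scope="class")
    def m2a_sim(self):
        spec = SimulationSpec(
            seed=5, n_codons=2000, model_name="M2a",
            model_params={"omega0": 0.1, "p0": 0.7, "p1": 0.15, "omega2": 5.0},
        )
        aln = simulate_alignment(spec)
        tree = mammal9_fixture()
        fit = fit_model(aln, tree, "M2a", FAST)
        return spec, aln, tree, fit

    def test_posteriors_are_probabilities(self, m2a_sim):
        _, aln, tree, fit = m2a_sim
        post = beb_site_posteriors(aln, tree, fit)
        for vec in (post.neb, post.beb):
            assert len(vec) == aln.n_sites
            assert np.all((vec >= 0) & (vec <= 1))

    def test_selected_sites_rank_higher(self, m2a_sim):
        from codonet.simulate import true_site_classes

        spec, aln, tree, fit = m2a_sim
        post = beb_site_posteriors(aln, tree, fit)
        classes = true_site_classes(spec, spec.seed)
        sel = classes == 2
        assert post.beb[sel].mean() > post.beb[~sel].mean()
        assert post.neb[sel].mean() > post.neb[~sel].mean()

    def test_neb_beb_agree_on_strong_data(self, m2a_sim):
        _, aln, tree, fit = m2a_sim
        post = beb_site_posteriors(aln, tree, fit)
        assert np.corrcoef(post.neb, post.beb)[0, 1] > 0.9

    def test_null_model_rejected(self, m0_alignment, mammal_tree):
        fit = fit_model(m0_alignment, mammal_tree, "M1a", FAST)
        with pytest.raises(ValueError):
            beb_site_posteriors(m0_alignment, mammal_tree, fit)
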