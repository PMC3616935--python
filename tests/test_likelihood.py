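"""Pruning-likelihood correctness against closed forms and enumeration."""

import itertools

import numpy as np
import pytest

from codonet.codon_model import (
    build_rate_matrix,
    expm_oracle,
    make_site_model,
    mixture_matrices,
)
from codonet.genetic_code import MISSING
from codonet.io import CodonAlignment
from codonet.likelihood import (
    LikelihoodError,
    TreeLikelihood,
    model_log_likelihood,
    site_log_likelihood,
)
from codonet.tree import parse_newick


def dirichlet_pi(seed):
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.full(61, 5.0))
    return pi / pi.sum()


def brute_force_star_quartet(aln_col, pi, Q, tree):
    """Enumerate both internal states of (A,B,(C,D)) for one site.

    Independent oracle: transition matrices via scipy's expm, likelihood by
    explicit summation over the 61 x 61 internal-node state pairs.
    """
    labels = {tree.labels[i]: i for i in range(tree.n_nodes)}
    t = tree.branch_lengths
    P = {
        name: expm_oracle(Q, t[labels[name]])
        for name in ("A", "B", "C", "D", "cd")
    }

    def tip(Pm, state, row):
        return 1.0 if state == MISSING else Pm[row, state]

    a, b, c, d = aln_col
    total = 0.0
    for r in range(61):
        for x in range(61):
            total += (
                pi[r]
                * tip(P["A"], a, r)
                * tip(P["B"], b, r)
                * P["cd"][r, x]
                * tip(P["C"], c, x)
                * tip(P["D"], d, x)
            )
    return np.log(total)


@pytest.fixture()
def star_quartet():
    return parse_newick("(A:0.1,B:0.15,(C:0.2,D:0.1)cd:0.05);")


class TestPruning:
    def test_two_taxon_closed_form(self, code):
        # for a pair, lnL = log(pi_i * P_ij(t_A + t_B)) by reversibility
        tree = parse_newick("(A:0.12,B:0.08);")
        pi = dirichlet_pi(0)
        Q = build_rate_matrix(2.0, 0.5, pi, code)
        i, j = code.index("ATG"), code.index("ATA")
        aln = CodonAlignment("pair", ["A", "B"], np.array([[i], [j]]))
        model = make_site_model("M0", {"omega": 0.5})
        engine = TreeLikelihood(aln, tree, code)
        lnL = engine.log_likelihood(model, 2.0, pi)
        from codonet.codon_model import transition_probs

        expected = np.log(pi[i] * transition_probs(Q, 0.2)[i, j])
        assert np.isclose(lnL, expected, atol=1e-10)

    def test_quartet_matches_enumeration_oracle(self, code, star_quartet):
        rng = np.random.default_rng(5)
        pi = dirichlet_pi(5)
        cols = rng.integers(0, 61, size=(5, 4)).astype(np.int16)
        cols[2, 1] = MISSING  # one missing cell among the 5 sites
        aln = CodonAlignment("q", ["A", "B", "C", "D"], cols.T)
        model = make_site_model("M0", {"omega": 0.4})
        engine = TreeLikelihood(aln, tree=star_quartet, code=code)
        Qm = build_rate_matrix(1.8, 0.4, pi, code)
        per_site = engine.site_log_likelihoods(model, 1.8, pi)
        for s in range(5):
            expected = brute_force_star_quartet(cols[s], pi, Qm.Q, star_quartet)
            assert np.isclose(per_site[s], expected, atol=1e-8)

    def test_missing_row_equals_absent_taxon(self, code, star_quartet):
        rng = np.random.default_rng(9)
        pi = dirichlet_pi(2)
        cols = rng.integers(0, 61, size=(4, 6)).astype(np.int16)
        model = make_site_model("M0", {"omega": 0.3})
        with_missing = CodonAlignment(
            "g", ["A", "B", "C", "D"],
            np.vstack([cols[:3], np.full((1, 6), MISSING, dtype=np.int16)]),
        )
        without = CodonAlignment("g", ["A", "B", "C"], cols[:3])
        l1 = TreeLikelihood(with_missing, star_quartet, code).log_likelihood(
            model, 2.0, pi
        )
        l2 = TreeLikelihood(without, star_quartet, code).log_likelihood(
            model, 2.0, pi
        )
        assert np.isclose(l1, l2, atol=1e-10)

    def test_rerooting_invariance(self, code):
        # one unrooted tree, three rooted presentations
        newicks = [
            "(A:0.1,B:0.15,(C:0.2,D:0.1):0.05);",
            "(C:0.2,D:0.1,(A:0.1,B:0.15):0.05);",
            "((C:0.2,D:0.1):0.025,(A:0.1,B:0.15):0.025);",
        ]
        rng = np.random.default_rng(1)
        pi = dirichlet_pi(1)
        cols = rng.integers(0, 61, size=(4, 8)).astype(np.int16)
        aln = CodonAlignment("g", ["A", "B", "C", "D"], cols)
        model = make_site_model("M0", {"omega": 0.5})
        lnLs = [
            TreeLikelihood(aln, parse_newick(nw), code).log_likelihood(
                model, 2.0, pi
            )
            for nw in newicks
        ]
        assert np.allclose(lnLs, lnLs[0], atol=1e-9)

    def test_unknown_taxon_rejected(self, code, star_quartet):
        aln = CodonAlignment("g", ["A", "Z"], np.zeros((2, 3), dtype=np.int16))
        with pytest.raises(LikelihoodError, match="Z"):
            TreeLikelihood(aln, star_quartet, code)


class TestMixtures:
    def test_m0_equals_per_site_sum(self, code, star_quartet):
        rng = np.random.default_rng(3)
        pi = dirichlet_pi(3)
        cols = rng.integers(0, 61, size=(4, 6)).astype(np.int16)
        aln = CodonAlignment("g", ["A", "B", "C", "D"], cols)
        model = make_site_model("M0", {"omega": 0.7})
        total = model_log_likelihood(aln, star_quartet, model, 2.0, pi, code)
        Q = build_rate_matrix(2.0, 0.7, pi, code)
        per_branch = {v: Q for v in star_quartet.branch_indices()}
        sites = sum(
            site_log_likelihood(aln, star_quartet, per_branch, s, code)
            for s in range(6)
        )
        assert np.isclose(total, sites, atol=1e-8)

    def test_branch_site_null_collapses_when_foreground_vanishes(
        self, code, star_quartet
    ):
        # with omega2 pinned at 1 AND a zero-length foreground branch, the
        # foreground distinction disappears: classes (0, 2a) and (1, 2b)
        # merge and the four-class model equals M1a with summed weights
        tagged = star_quartet.with_foreground("cd")
        cd = [i for i, l in enumerate(tagged.labels) if l == "cd"][0]
        tagged.branch_lengths[cd] = 0.0
        rng = np.random.default_rng(8)
        pi = dirichlet_pi(8)
        cols = rng.integers(0, 61, size=(4, 10)).astype(np.int16)
        aln = CodonAlignment("g", ["A", "B", "C", "D"], cols)
        p0, p1, w0 = 0.55, 0.25, 0.12
        bsa = make_site_model(
            "branch_site_A_null", {"omega0": w0, "p0": p0, "p1": p1}
        )
        rest = 1 - p0 - p1
        m1a = make_site_model(
            "M1a", {"omega0": w0, "p0": p0 + rest * p0 / (p0 + p1)}
        )
        l_bsa = model_log_likelihood(aln, tagged, bsa, 2.0, pi, code)
        l_m1a = model_log_likelihood(aln, tagged, m1a, 2.0, pi, code)
        assert np.isclose(l_bsa, l_m1a, atol=1e-9)

    def test_branch_model_requires_tagged_tree(self, code, star_quartet):
        aln = CodonAlignment(
            "g", ["A", "B", "C", "D"], np.zeros((4, 2), dtype=np.int16)
        )
        model = make_site_model(
            "branch_site_A", {"omega0": 0.1, "p0": 0.6, "p1": 0.2, "omega2": 3.0}
        )
        pi = dirichlet_pi(0)
        with pytest.raises(LikelihoodError):
            model_log_likelihood(aln, star_quartet, model, 2.0, pi, code)

    def test_branch_gradient_matches_finite_differences(self, code, star_quartet):
        rng = np.random.default_rng(4)
        pi = dirichlet_pi(4)
        cols = rng.integers(0, 61, size=(4, 12)).astype(np.int16)
        aln = CodonAlignment("g", ["A", "B", "C", "D"], cols)
        model = make_site_model("M1a", {"omega0": 0.2, "p0": 0.8})
        engine = TreeLikelihood(aln, star_quartet, code)
        t0 = star_quartet.branch_lengths.copy()
        lnL, grad = engine.log_likelihood_and_branch_grad(model, 2.0, pi, t0)
        for bi, v in enumerate(star_quartet.branch_indices()):
            h = 1e-6
            tp = t0.copy()
            tp[v] += h
            tm = t0.copy()
            tm[v] -= h
            fd = (
                engine.log_likelihood(model, 2.0, pi, tp)
                - engine.log_likelihood(model, 2.0, pi, tm)
            ) / (2 * h)
            assert np.isclose(grad[bi], fd, rtol=1e-5, atol=1e-7)
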