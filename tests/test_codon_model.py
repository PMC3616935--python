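import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import beta as beta_dist

from codonet.codon_model import (
    build_rate_matrix,
    discretize_beta,
    expm_oracle,
    make_site_model,
    mixture_matrices,
    transition_probs,
    uniform_pi,
)


def dirichlet_pi(seed, n=61):
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.full(n, 5.0))
    return pi / pi.sum()


class TestRateMatrix:
    def test_rows_sum_to_zero_and_normalised(self, code, upi):
        Q = build_rate_matrix(2.0, 0.5, upi, code)
        assert np.allclose(Q.Q.sum(axis=1), 0, atol=1e-12)
        assert np.isclose(-(upi * np.diag(Q.Q)).sum(), 1.0)

    def test_uniform_neutral_symmetry(self, code, upi):
        # kappa=omega=1: all allowed exchanges share one rate before scaling
        Q = build_rate_matrix(1.0, 1.0, upi, code)
        off = Q.Q[~np.eye(61, dtype=bool)]
        rates = off[off > 0]
        assert np.allclose(rates, rates[0])

    def test_multi_nucleotide_changes_forbidden(self, code, upi):
        Q = build_rate_matrix(2.0, 0.5, upi, code)
        blocked = code.single_nt_changes() == 0
        np.fill_diagonal(blocked, False)
        assert np.all(Q.Q[blocked] == 0)

    def test_kappa_omega_rate_ratio(self, code, upi):
        # AAA->AAG is a synonymous transition (rate kappa*pi_j); AAA->AAT is a
        # nonsynonymous transversion (rate omega*pi_j): ratio = kappa/omega = 4
        Q = build_rate_matrix(2.0, 0.5, upi, code)
        i = code.index("AAA")
        assert np.isclose(
            Q.Q[i, code.index("AAG")] / Q.Q[i, code.index("AAT")], 4.0
        )

    @settings(max_examples=20, deadline=None)
    @given(
        kappa=st.floats(0.1, 10),
        omega=st.floats(0.01, 5),
        seed=st.integers(0, 10_000),
    )
    def test_reversibility_property(self, code, kappa, omega, seed):
        pi = dirichlet_pi(seed)
        Q = build_rate_matrix(kappa, omega, pi, code)
        flux = pi[:, None] * Q.Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_invalid_inputs(self, code, upi):
        with pytest.raises(ValueError):
            build_rate_matrix(-1.0, 0.5, upi, code)
        with pytest.raises(ValueError):
            build_rate_matrix(2.0, 0.5, upi * 2, code)


class TestTransitionProbs:
    def test_zero_time_is_identity(self, code, upi):
        Q = build_rate_matrix(2.0, 0.3, upi, code)
        assert np.allclose(transition_probs(Q, 0.0), np.eye(61), atol=1e-12)

    def test_long_time_reaches_stationarity(self, code):
        pi = dirichlet_pi(3)
        Q = build_rate_matrix(2.0, 0.3, pi, code)
        P = transition_probs(Q, 1e4)
        assert np.allclose(P, np.tile(pi, (61, 1)), atol=1e-8)

    def test_matches_scaling_and_squaring_oracle(self, code):
        pi = dirichlet_pi(7)
        Q = build_rate_matrix(2.5, 0.4, pi, code)
        P = transition_probs(Q, 0.2)
        assert np.abs(P - expm_oracle(Q.Q, 0.2)).max() < 1e-10
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_time_rejected(self, code, upi):
        Q = build_rate_matrix(2.0, 0.3, upi, code)
        with pytest.raises(ValueError):
            transition_probs(Q, -0.1)


class TestDiscretizeBeta:
    def test_uniform_beta_gives_decile_midpoints(self):
        om, w = discretize_beta(1.0, 1.0, 10)
        assert np.allclose(om, np.arange(0.05, 1.0, 0.1))
        assert np.allclose(w, 0.1)

    def test_single_category_is_the_median(self):
        om, _ = discretize_beta(2.0, 5.0, 1)
        assert np.isclose(om[0], beta_dist.ppf(0.5, 2.0, 5.0))

    def test_symmetric_beta_quartiles(self):
        # independent quantile oracle for Beta(2,2), K=4 bin medians
        om, w = discretize_beta(2.0, 2.0, 4)
        expected = beta_dist.ppf([0.125, 0.375, 0.625, 0.875], 2.0, 2.0)
        assert np.allclose(om, expected)
        assert np.all(np.diff(om) > 0)
        assert np.allclose(om + om[::-1], 1.0)  # symmetry about 0.5

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            discretize_beta(1.0, 1.0, 0)
        with pytest.raises(ValueError):
            discretize_beta(-1.0, 1.0, 4)


class TestSiteClassModels:
    @pytest.mark.parametrize(
        "name,params,n_classes",
        [
            ("M0", {"omega": 0.3}, 1),
            ("M1a", {"omega0": 0.2, "p0": 0.8}, 2),
            ("M2a", {"omega0": 0.2, "p0": 0.7, "p1": 0.2, "omega2": 3.0}, 3),
            ("M7", {"p_beta": 1.0, "q_beta": 2.0}, 10),
            ("M8", {"p_beta": 1.0, "q_beta": 2.0, "p0": 0.9, "omega_s": 2.5}, 11),
        ],
    )
    def test_weights_normalised(self, name, params, n_classes):
        m = make_site_model(name, params)
        assert m.n_classes == n_classes
        assert np.isclose(m.class_weights.sum(), 1.0)
        assert not m.is_branch_model

    def test_branch_site_class_structure(self):
        m = make_site_model(
            "branch_site_A",
            {"omega0": 0.1, "p0": 0.6, "p1": 0.2, "omega2": 4.0},
        )
        assert m.is_branch_model
        assert np.allclose(m.class_omegas_background, [0.1, 1.0, 0.1, 1.0])
        assert np.allclose(m.class_omegas_foreground, [0.1, 1.0, 4.0, 4.0])
        # 2a/2b split the remainder proportionally to p0:p1
        rest = 1 - 0.6 - 0.2
        assert np.allclose(
            m.class_weights, [0.6, 0.2, rest * 0.75, rest * 0.25]
        )

    def test_branch_site_null_pins_omega2(self):
        m = make_site_model(
            "branch_site_A_null", {"omega0": 0.1, "p0": 0.6, "p1": 0.2}
        )
        assert np.allclose(m.class_omegas_foreground, [0.1, 1.0, 1.0, 1.0])

    def test_m7_uniform_case_is_decile_grid(self):
        m = make_site_model("M7", {"p_beta": 1.0, "q_beta": 1.0}, K=10)
        assert np.allclose(m.class_omegas_background, np.arange(0.05, 1.0, 0.1))
        assert np.allclose(m.class_weights, 0.1)

    def test_mixture_scale_weights_class_rates(self, code, upi):
        # a mixture with a fast class must give the slow class Q a flow < 1
        m = make_site_model("M2a", {"omega0": 0.1, "p0": 0.5, "p1": 0.3, "omega2": 5.0})
        bg, _ = mixture_matrices(m, 2.0, upi, code)
        flows = [-(upi * np.diag(Q.Q)).sum() for Q in bg]
        mean_flow = float(np.dot(m.class_weights, flows))
        assert np.isclose(mean_flow, 1.0)
        assert flows[0] < 1.0 < flows[2]
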