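"""GY94-style codon substitution models and site-class mixtures.

The instantaneous rate between sense codons i and j is zero unless they
differ at exactly one nucleotide position, and otherwise proportional to

=====================  ==========
change                 rate
=====================  ==========
synonymous transversion      pi_j
synonymous transition        kappa * pi_j
nonsynonymous transversion   omega * pi_j
nonsynonymous transition     omega * kappa * pi_j
=====================  ==========

with ``kappa`` the transition/transversion rate ratio, ``omega`` = dN/dS the
selective-pressure parameter and ``pi`` the equilibrium sense-codon
frequencies.  A single-matrix model is normalised so one time unit equals
one expected substitution per codon; site-class mixtures share a common
scale weighted by the class proportions (so branch lengths remain expected
substitutions per codon averaged over classes).

Site-class models follow the codeml family: M0 (one ratio), M1a
(nearly-neutral), M2a (positive selection), M7 (beta), M8 (beta&omega), and
branch-site model A with its ``omega2 = 1`` null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import beta as beta_dist

from .genetic_code import MISSING, GeneticCode, universal_code

OMEGA_MAX = 50.0  # box bound during optimisation; hitting it is logged
_PI_FLOOR = 1e-10

SITE_MODEL_NAMES = (
    "M0", "M1a", "M2a", "M7", "M8", "branch_site_A", "branch_site_A_null",
)


# ---------------------------------------------------------------------------
# rate matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonRateMatrix:
    """A normalised, time-reversible GY94 rate matrix.

    ``scale`` is the expected substitutions per codon per unit time of the
    *unnormalised* matrix; ``Q`` is the matrix after division by it (or by a
    shared mixture scale), so ``-sum_i pi_i Q_ii`` equals 1 for a standalone
    matrix.
    """

    kappa: float
    omega: float
    pi: np.ndarray
    Q: np.ndarray
    scale: float

    def eig(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition exploiting reversibility.

        Returns ``(lam, U, Uinv)`` with ``Q = U diag(lam) Uinv`` and real
        eigenvalues, via symmetrisation ``S = D^{1/2} Q D^{-1/2}``.
        """
        d = np.sqrt(self.pi)
        S = (self.Q * d[:, None]) / d[None, :]
        S = 0.5 * (S + S.T)  # symmetrise away rounding noise
        lam, V = np.linalg.eigh(S)
        U = V / d[:, None]
        Uinv = V.T * d[None, :]
        return lam, U, Uinv


def _structure_tables(code: GeneticCode) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(single-nt exchange mask, transition mask, nonsynonymous mask)."""
    cls = code.single_nt_changes()
    single = cls > 0
    transition = (cls == 2) | (cls == 4)
    nonsyn = (cls == 3) | (cls == 4)
    return single, transition, nonsyn


def unnormalized_rates(
    kappa: float, omega: float, pi: np.ndarray, code: GeneticCode
) -> np.ndarray:
    """Off-diagonal GY94 rates before scaling (diagonal left at 0)."""
    single, transition, nonsyn = _structure_tables(code)
    R = np.where(single, pi[None, :], 0.0)
    R = np.where(single & transition, R * kappa, R)
    R = np.where(single & nonsyn, R * omega, R)
    return R


def flow_rate(R: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time of unnormalised R."""
    return float(pi @ R.sum(axis=1))


def build_rate_matrix(
    kappa: float,
    omega: float,
    pi: np.ndarray,
    code: GeneticCode | None = None,
    scale: float | None = None,
) -> CodonRateMatrix:
    """Build a normalised GY94 rate matrix.

    Parameters
    ----------
    scale:
        Externally supplied normalisation (used for site-class mixtures that
        share one scale); by default the matrix's own flow rate, giving
        ``-sum_i pi_i Q_ii = 1``.
    """
    code = code or universal_code()
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be non-negative")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (code.n_states,):
        raise ValueError(f"pi must have length {code.n_states}")
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must be a probability vector")
    R = unnormalized_rates(kappa, omega, pi, code)
    if scale is None:
        scale = flow_rate(R, pi)
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero flow)")
    Q = R / scale
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return CodonRateMatrix(kappa=kappa, omega=omega, pi=pi, Q=Q, scale=scale)


def transition_probs(Q: CodonRateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt), computed through the reversible eigendecomposition."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    lam, U, Uinv = Q.eig()
    P = (U * np.exp(lam * t)[None, :]) @ Uinv
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# equilibrium codon frequencies
# ---------------------------------------------------------------------------

def uniform_pi(code: GeneticCode) -> np.ndarray:
    return np.full(code.n_states, 1.0 / code.n_states)


def f3x4_pi(alignment, code: GeneticCode) -> np.ndarray:
    """Position-specific nucleotide-frequency (F3x4) codon frequencies."""
    from .genetic_code import NUCLEOTIDES

    counts = np.zeros((3, 4))
    nt_index = {n: k for k, n in enumerate(NUCLEOTIDES)}
    for row in alignment.codons:
        for state in row:
            if state == MISSING:
                continue
            codon = code.sense_codons[state]
            for pos, nt in enumerate(codon):
                counts[pos, nt_index[nt]] += 1
    if counts.sum() == 0:
        return uniform_pi(code)
    freqs = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]] * freqs[2, nt_index[c[2]]]
            for c in code.sense_codons
        ]
    )
    pi = np.maximum(pi, _PI_FLOOR)
    return pi / pi.sum()


def f61_pi(alignment, code: GeneticCode) -> np.ndarray:
    """Empirical codon frequencies with a half-count prior."""
    counts = np.full(code.n_states, 0.5)
    for row in alignment.codons:
        for state in row:
            if state != MISSING:
                counts[state] += 1
    return counts / counts.sum()


def pi_from_mode(mode: str, alignment, code: GeneticCode) -> np.ndarray:
    if mode == "F3x4":
        return f3x4_pi(alignment, code)
    if mode == "F61":
        return f61_pi(alignment, code)
    if mode == "uniform":
        return uniform_pi(code)
    raise ValueError(f"unknown pi mode: {mode!r}")


# ---------------------------------------------------------------------------
# beta discretization (M7/M8)
# ---------------------------------------------------------------------------

def discretize_beta(p: float, q: float, K: int) -> tuple[np.ndarray, np.ndarray]:
    """K equal-weight categories of Beta(p, q); category value = bin median.

    Returns ``(omegas, weights)`` with omegas strictly inside (0, 1).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be positive")
    quantiles = (np.arange(K) + 0.5) / K
    omegas = beta_dist.ppf(quantiles, p, q)
    omegas = np.clip(omegas, 1e-8, 1 - 1e-8)
    return omegas, np.full(K, 1.0 / K)


# ---------------------------------------------------------------------------
# site-class models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteClassModel:
    """A fully specified site-class mixture.

    ``class_omegas_background`` / ``class_omegas_foreground`` give per-class
    omega on background and foreground branches (identical for non-branch
    models); ``class_weights`` are the mixture proportions.
    """

    name: str
    class_omegas_background: np.ndarray
    class_omegas_foreground: np.ndarray
    class_weights: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.class_weights, dtype=float)
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("class weights must be a probability vector")

    @property
    def n_classes(self) -> int:
        return len(self.class_weights)

    @property
    def is_branch_model(self) -> bool:
        return not np.allclose(
            self.class_omegas_background, self.class_omegas_foreground
        )


def make_site_model(name: str, params: dict, K: int = 10) -> SiteClassModel:
    """Instantiate a site-class model from its free parameters.

    Parameters are the natural ones: ``omega`` (M0); ``omega0, p0`` (M1a);
    ``omega0, p0, p1, omega2`` (M2a); ``p_beta, q_beta`` (M7); plus
    ``p0, omega_s`` (M8); ``omega0, p0, p1, omega2`` (branch-site A, where
    2a/2b proportions follow codeml's proportional split).
    """
    if name == "M0":
        w = np.array([1.0])
        om = np.array([params["omega"]])
        return SiteClassModel(name, om, om, w, dict(params))
    if name == "M1a":
        om = np.array([params["omega0"], 1.0])
        w = np.array([params["p0"], 1 - params["p0"]])
        return SiteClassModel(name, om, om, w, dict(params))
    if name == "M2a":
        om = np.array([params["omega0"], 1.0, params["omega2"]])
        p0, p1 = params["p0"], params["p1"]
        w = np.array([p0, p1, 1 - p0 - p1])
        return SiteClassModel(name, om, om, w, dict(params))
    if name == "M7":
        om, w = discretize_beta(params["p_beta"], params["q_beta"], K)
        return SiteClassModel(name, om, om, w, dict(params))
    if name == "M8":
        om_b, w_b = discretize_beta(params["p_beta"], params["q_beta"], K)
        p0 = params["p0"]
        om = np.append(om_b, params["omega_s"])
        w = np.append(w_b * p0, 1 - p0)
        return SiteClassModel(name, om, om, w, dict(params))
    if name in ("branch_site_A", "branch_site_A_null"):
        omega0 = params["omega0"]
        omega2 = 1.0 if name == "branch_site_A_null" else params["omega2"]
        p0, p1 = params["p0"], params["p1"]
        if p0 + p1 <= 0:
            raise ValueError("branch-site A requires p0 + p1 > 0")
        rest = 1 - p0 - p1
        w = np.array(
            [p0, p1, rest * p0 / (p0 + p1), rest * p1 / (p0 + p1)]
        )
        bg = np.array([omega0, 1.0, omega0, 1.0])
        fg = np.array([omega0, 1.0, omega2, omega2])
        return SiteClassModel(name, bg, fg, w, dict(params, omega2=omega2))
    raise ValueError(f"unknown site model: {name!r}")


def mixture_scale(
    model: SiteClassModel,
    kappa: float,
    pi: np.ndarray,
    code: GeneticCode | None = None,
) -> float:
    """Shared normalisation (expected raw flow per codon) of a mixture."""
    code = code or universal_code()
    base = unnormalized_rates(kappa, 1.0, pi, code)
    _, _, nonsyn = _structure_tables(code)
    syn_flow = flow_rate(np.where(nonsyn, 0.0, base), pi)
    nonsyn_flow = flow_rate(np.where(nonsyn, base, 0.0), pi)
    return float(
        np.sum(
            model.class_weights
            * (syn_flow + model.class_omegas_background * nonsyn_flow)
        )
    )


def mixture_matrices(
    model: SiteClassModel,
    kappa: float,
    pi: np.ndarray,
    code: GeneticCode | None = None,
) -> tuple[list[CodonRateMatrix], list[CodonRateMatrix]]:
    """Per-class (background, foreground) rate matrices on a common scale.

    The shared scale is the proportion-weighted flow of the *background*
    class matrices, so one unit of branch length is one expected
    substitution per codon averaged over site classes.
    """
    code = code or universal_code()
    scale = mixture_scale(model, kappa, pi, code)
    bg = [
        build_rate_matrix(kappa, float(om), pi, code, scale=scale)
        for om in model.class_omegas_background
    ]
    if model.is_branch_model:
        fg = [
            build_rate_matrix(kappa, float(om), pi, code, scale=scale)
            for om in model.class_omegas_foreground
        ]
    else:
        fg = bg
    return bg, fg


# ---------------------------------------------------------------------------
# expm oracle used in tests (independent of the eig path)
# ---------------------------------------------------------------------------

def expm_oracle(Q: np.ndarray, t: float) -> np.ndarray:
    """Scaling-and-squaring matrix exponential (scipy), for cross-checks."""
    return linalg.expm(Q * t)
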