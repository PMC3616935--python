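"""Likelihood-ratio tests of positive selection and BEB site posteriors.

Site tests compare M2a against M1a and M8 against M7 (both df = 2); the
branch-site test compares branch-site model A against its ``omega2 = 1``
null (df = 1) on a designated foreground branch.  Raw p-values are
corrected per family — one family across genes for the site tests, one
across gene x branch combinations for the branch-site tests — with
Benjamini-Hochberg FDR by default.

Sites driving a positive test are localised with the Bayes Empirical Bayes
(BEB) scheme: the posterior probability that a codon evolves at omega > 1
is averaged over a uniform prior grid on the mixture proportions and the
positive-selection omega, with the remaining parameters (kappa, branch
lengths, purifying-class omega) fixed at their MLEs.  The plug-in NEB
posterior is computed alongside for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .codon_model import make_site_model, mixture_scale
from .fit import FitConfig, ModelFit, fit_model
from .genetic_code import GeneticCode, universal_code
from .io import CodonAlignment
from .likelihood import TreeLikelihood
from .tree import PhyloTree

logger = logging.getLogger(__name__)


@dataclass
class SelectionTestResult:
    gene_id: str
    test: str  # M1a_vs_M2a | M7_vs_M8 | branch_site
    branch: str | None
    lnL_alt: float
    lnL_null: float
    statistic: float
    df: int
    p_raw: float
    p_adjusted: float | None = None
    fit_alt: ModelFit | None = None
    fit_null: ModelFit | None = None


@dataclass
class SitePosterior:
    """Per-codon posterior probabilities of omega > 1 (NEB and BEB)."""

    gene_id: str
    neb: np.ndarray
    beb: np.ndarray
    neb_class: np.ndarray  # most probable class per site, plug-in
    method: str = "BEB"


# ---------------------------------------------------------------------------
# LRT machinery
# ---------------------------------------------------------------------------

def lrt(
    lnL_alt: float, lnL_null: float, df: int, mixture: bool = False
) -> tuple[float, float]:
    """Likelihood-ratio statistic and its chi-square p-value.

    Negative statistics (optimiser noise at the boundary) clamp to 0 with a
    warning.  ``mixture=True`` uses the 50:50 point-mass/chi2 mixture null
    sometimes recommended for boundary tests instead of the plain chi2.
    """
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2 for these tests")
    stat = 2.0 * (lnL_alt - lnL_null)
    if stat < 0:
        if stat < -1e-3:
            logger.warning("LRT statistic %.4g < 0; clamped to 0", stat)
        stat = 0.0
    if mixture:
        p = 0.5 * chi2.sf(stat, df) if stat > 0 else 1.0
    else:
        p = float(chi2.sf(stat, df))
    return float(stat), float(p)


def _null_anchored_start(alt_name: str, null: ModelFit) -> dict:
    """Starting values that reproduce the null inside the alternative.

    The positive-selection class opens with negligible weight and omega
    barely above 1, so the alternative's first evaluation sits at the
    null's optimum and the optimiser can only improve on it.
    """
    est = null.estimates
    if alt_name == "M2a":
        return {
            "omega0": est["omega0"], "p0": est["p0"],
            "p1_rel": 1 - 1e-9, "omega2": 1.0 + 1e-5,
        }
    if alt_name == "M8":
        return {
            "p_beta": est["p_beta"], "q_beta": est["q_beta"],
            "p0": 1 - 1e-9, "omega_s": 1.0 + 1e-5,
        }
    if alt_name == "branch_site_A":
        p0, p1 = est["p0"], est["p1"]
        return {
            "omega0": est["omega0"], "p01": p0 + p1,
            "p0_rel": p0 / (p0 + p1), "omega2": 1.0 + 1e-5,
        }
    return {}


def _refit_if_inverted(
    alt: ModelFit, null: ModelFit, alignment, tree, config, code
) -> ModelFit:
    """Guard the nesting: refit the alternative from the null's optimum."""
    if alt.lnL >= null.lnL - 1e-9:
        return alt
    logger.info(
        "%s: alternative lnL %.6f below null %.6f; refitting from null optimum",
        alt.gene_id, alt.lnL, null.lnL,
    )
    warm_tree = tree.with_branch_lengths(null.branch_lengths)
    cfg2 = FitConfig(**{**config.__dict__, "start_omegas": (1.0,),
                        "kappa_start": null.kappa})
    refit = fit_model(
        alignment, warm_tree, alt.model.name, cfg2, code,
        init_overrides=_null_anchored_start(alt.model.name, null),
    )
    return refit if refit.lnL > alt.lnL else alt


_SITE_TEST_PAIRS = {
    "M1a_vs_M2a": ("M1a", "M2a"),
    "M7_vs_M8": ("M7", "M8"),
}


def site_model_tests(
    alignment: CodonAlignment,
    tree: PhyloTree,
    config: FitConfig | None = None,
    code: GeneticCode | None = None,
    tests: tuple[str, ...] = ("M1a_vs_M2a", "M7_vs_M8"),
) -> list[SelectionTestResult]:
    """The whole-tree site tests (M1a vs M2a and/or M7 vs M8), df = 2 each."""
    config = config or FitConfig()
    code = code or universal_code()
    out = []
    for null_name, alt_name, label in (
        _SITE_TEST_PAIRS[t] + (t,) for t in tests
    ):
        f_null = fit_model(alignment, tree, null_name, config, code)
        f_alt = fit_model(alignment, tree, alt_name, config, code)
        f_alt = _refit_if_inverted(f_alt, f_null, alignment, tree, config, code)
        stat, p = lrt(f_alt.lnL, f_null.lnL, df=2)
        out.append(
            SelectionTestResult(
                gene_id=alignment.gene_id, test=label, branch=None,
                lnL_alt=f_alt.lnL, lnL_null=f_null.lnL, statistic=stat, df=2,
                p_raw=p, fit_alt=f_alt, fit_null=f_null,
            )
        )
    return out


def branch_site_test(
    alignment: CodonAlignment,
    tree: PhyloTree,
    foreground_branch: str,
    config: FitConfig | None = None,
    code: GeneticCode | None = None,
    mixture_null: bool = False,
) -> SelectionTestResult:
    """Branch-site model A against its omega2 = 1 null on one branch (df=1)."""
    config = config or FitConfig()
    code = code or universal_code()
    tagged = tree.with_foreground(foreground_branch)
    if tagged.foreground.all() or tagged.foreground[tagged.root]:
        raise ValueError("foreground cannot be the entire tree")
    f_null = fit_model(alignment, tagged, "branch_site_A_null", config, code)
    f_alt = fit_model(alignment, tagged, "branch_site_A", config, code)
    f_alt = _refit_if_inverted(f_alt, f_null, alignment, tagged, config, code)
    stat, p = lrt(f_alt.lnL, f_null.lnL, df=1, mixture=mixture_null)
    return SelectionTestResult(
        gene_id=alignment.gene_id, test="branch_site", branch=foreground_branch,
        lnL_alt=f_alt.lnL, lnL_null=f_null.lnL, statistic=stat, df=1,
        p_raw=p, fit_alt=f_alt, fit_null=f_null,
    )


def adjust_pvalues(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment over one correction family.

    Default Benjamini-Hochberg step-up (monotone by construction); ``holm``
    and ``bonferroni`` are also accepted.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method=method)[1]


def attach_adjusted(
    results: list[SelectionTestResult], method: str = "fdr_bh"
) -> list[SelectionTestResult]:
    """Fill ``p_adjusted`` in place, treating the given results as one family."""
    adj = adjust_pvalues([r.p_raw for r in results], method=method)
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results


# ---------------------------------------------------------------------------
# site posteriors (NEB / BEB)
# ---------------------------------------------------------------------------

_GRID = 10  # points per free prior dimension


def _grid_mid(lo: float, hi: float, n: int = _GRID) -> np.ndarray:
    edges = np.linspace(lo, hi, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def beb_site_posteriors(
    alignment: CodonAlignment,
    tree: PhyloTree,
    fit: ModelFit,
    code: GeneticCode | None = None,
    grid_size: int = _GRID,
) -> SitePosterior:
    """NEB and BEB posterior P(omega > 1) per codon site.

    Supported alternative models: M2a, M8 and branch-site A.  The BEB prior
    is uniform over a ``grid_size``-point grid per free dimension: the
    mixture proportions and the positive-class omega (M2a, branch-site A)
    or the beta-weight proportion and omega_s (M8, with the beta shapes at
    their MLEs).  Everything else is fixed at the MLE.
    """
    code = code or universal_code()
    name = fit.model.name
    if name not in ("M2a", "M8", "branch_site_A"):
        raise ValueError(f"BEB is defined for alternative models, not {name}")
    if name == "branch_site_A" and not tree.foreground.any():
        raise ValueError("branch-site BEB needs the foreground-tagged tree")
    engine = TreeLikelihood(alignment, tree, code)
    kappa, pi = fit.kappa, fit.pi
    # Branch lengths are held fixed on the raw-rate time scale implied by
    # the MLE normalisation, so per-class site likelihoods are independent
    # of the grid's mixture proportions and can be shared across combos.
    s_mle = mixture_scale(fit.model, kappa, pi, code)
    tau = fit.branch_lengths / s_mle

    cacheL: dict = {}

    def class_L(model) -> np.ndarray:
        key = tuple(np.round(model.class_omegas_background, 12)) + tuple(
            np.round(model.class_omegas_foreground, 12)
        )
        if key not in cacheL:
            L, _ = engine.class_pattern_likelihoods_raw(
                model.class_omegas_background,
                model.class_omegas_foreground,
                kappa, pi, tau,
            )
            cacheL[key] = L
        return cacheL[key]  # (n_classes, n_patterns)

    # --- NEB: plug-in posterior under the MLE model
    L_mle = class_L(fit.model)
    w = fit.model.class_weights
    post = (w[:, None] * L_mle) / np.maximum(w @ L_mle, 1e-300)[None, :]
    pos_classes = _positive_classes(fit.model)
    neb = post[pos_classes].sum(axis=0)[engine.pattern_of_site]
    neb_class = np.argmax(post, axis=0)[engine.pattern_of_site]

    # --- BEB: average class posteriors over the prior grid
    grids = _beb_grid_models(fit, grid_size)
    counts = engine.counts
    log_post = np.empty(len(grids))
    pos_frac = np.empty((len(grids), engine.n_patterns))
    for gi, (model_g, prior_w) in enumerate(grids):
        Lg = class_L(model_g)
        wg = model_g.class_weights
        mix = np.maximum(wg @ Lg, 1e-300)
        log_post[gi] = float(counts @ np.log(mix)) + np.log(prior_w)
        pos = _positive_classes(model_g)
        pos_frac[gi] = (wg[pos] @ Lg[pos]) / mix
    log_post -= log_post.max()
    gw = np.exp(log_post)
    gw /= gw.sum()
    beb = (gw @ pos_frac)[engine.pattern_of_site]
    return SitePosterior(
        gene_id=alignment.gene_id, neb=neb, beb=beb, neb_class=neb_class
    )


def _positive_classes(model) -> list[int]:
    """Indices of classes whose (foreground) omega exceeds 1."""
    return [
        c
        for c in range(model.n_classes)
        if model.class_omegas_foreground[c] > 1.0 + 1e-9
    ]


def _beb_grid_models(fit: ModelFit, n: int) -> list[tuple]:
    """(model, prior weight) pairs making up the BEB prior grid."""
    name = fit.model.name
    est = fit.estimates
    K = (
        len(fit.model.class_weights) - 1
        if name == "M8"
        else None
    )
    p_grid = _grid_mid(0.0, 1.0, n)
    w2_grid = _grid_mid(1.0, 11.0, n)
    out = []
    if name == "M2a":
        combos = [
            (p0, p1)
            for p0 in p_grid
            for p1 in p_grid
            if p0 + p1 <= 1.0 - 1e-9
        ]
        for p0, p1 in combos:
            for w2 in w2_grid:
                m = make_site_model(
                    "M2a",
                    {"omega0": est["omega0"], "p0": p0, "p1": p1, "omega2": w2},
                )
                out.append((m, 1.0 / (len(combos) * n)))
    elif name == "branch_site_A":
        for x in p_grid:  # p0 + p1
            for y in p_grid:  # p0 / (p0 + p1)
                for w2 in w2_grid:
                    m = make_site_model(
                        "branch_site_A",
                        {
                            "omega0": est["omega0"],
                            "p0": x * y,
                            "p1": x * (1 - y),
                            "omega2": w2,
                        },
                    )
                    out.append((m, 1.0 / (n * n * n)))
    elif name == "M8":
        for p0 in p_grid:
            for ws in w2_grid:
                m = make_site_model(
                    "M8",
                    {
                        "p_beta": est["p_beta"],
                        "q_beta": est["q_beta"],
                        "p0": p0,
                        "omega_s": ws,
                    },
                    K=K,
                )
                out.append((m, 1.0 / (n * n)))
    return out
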