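"""Maximum-likelihood fitting of codon site-class models.

Optimisation runs over unconstrained transforms of the free parameters
(log for positive rates, logit for proportions and omegas bounded in (0,1),
``1 + exp(u)`` for omegas constrained >= 1) plus log branch lengths, with
L-BFGS-B.  Branch-length gradients are analytic (outer/inner pruning
partials); the handful of substitution parameters use central differences.
Each fit is staged: a cheap pass that rescales the starting tree jointly
with the substitution parameters, then (by default) full per-branch
optimisation warm-started from it.

Restarts follow the multi-start practice for codon models: by default the
omega-type parameters are re-seeded from ``start_omegas`` (0.1, 1.0, 2.0)
while later restarts reuse the first optimum's branch lengths and kappa;
the best converged log-likelihood is kept and every start is recorded.
"""

from __future__ import annotations

import logging
import math
import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .codon_model import (
    OMEGA_MAX,
    SiteClassModel,
    make_site_model,
    pi_from_mode,
    unnormalized_rates,
    flow_rate,
    _structure_tables,
)
from .genetic_code import MISSING, GeneticCode, universal_code
from .io import CodonAlignment
from .likelihood import TreeLikelihood
from .tree import PhyloTree

logger = logging.getLogger(__name__)

_MIN_BL = 1e-6
_MAX_BL = 20.0


class FitError(RuntimeError):
    pass


@dataclass
class FitConfig:
    """Knobs of the likelihood optimisation."""

    pi_mode: str = "F3x4"
    n_beta_categories: int = 10
    start_omegas: tuple[float, ...] = (0.1, 1.0, 2.0)
    replicates: int = 1  # repeats of the whole start set, for consistency checks
    kappa_start: float = 2.0
    tol: float = 1e-6  # convergence in lnL units
    maxiter: int = 400
    omega_max: float = OMEGA_MAX
    branch_mode: str = "full"  # "full" or "scale"


@dataclass
class ModelFit:
    """A maximised site-class model on a tree."""

    gene_id: str
    model: SiteClassModel
    lnL: float
    kappa: float
    pi: np.ndarray
    branch_lengths: np.ndarray  # indexed by tree node; root entry unused
    estimates: dict
    restarts: list[tuple[float, float]]
    converged: bool
    identifiable: bool = True

    @property
    def tree_length(self) -> float:
        # the root entry is stored as 0, so summing everything is safe
        return float(np.nansum(self.branch_lengths))

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "model": self.model.name,
            "lnL": self.lnL,
            "kappa": self.kappa,
            "pi": self.pi.tolist(),
            "branch_lengths": self.branch_lengths.tolist(),
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "restarts": [list(r) for r in self.restarts],
            "converged": self.converged,
            "identifiable": self.identifiable,
        }

    @classmethod
    def from_dict(cls, d: dict, K: int = 10) -> "ModelFit":
        model = make_site_model(d["model"], d["estimates"], K=K)
        return cls(
            gene_id=d["gene_id"],
            model=model,
            lnL=d["lnL"],
            kappa=d["kappa"],
            pi=np.array(d["pi"]),
            branch_lengths=np.array(d["branch_lengths"]),
            estimates=dict(d["estimates"]),
            restarts=[tuple(r) for r in d["restarts"]],
            converged=d["converged"],
            identifiable=d.get("identifiable", True),
        )


@dataclass
class RateEstimates:
    """Tree-wide omega, dN and dS derived from an M0 fit."""

    gene_id: str
    omega: float
    dN: float
    dS: float
    tree_length: float


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

def _sigmoid(u: float) -> float:
    if u >= 0:
        z = math.exp(-u)
        return 1.0 / (1.0 + z)
    z = math.exp(u)
    return z / (1.0 + z)


def _logit(x: float) -> float:
    x = min(max(x, 1e-9), 1 - 1e-9)
    return math.log(x / (1 - x))


@dataclass(frozen=True)
class _Param:
    name: str
    transform: str  # log | logit | shift1
    init: float
    upper: float | None = None  # natural-scale upper bound (log transform)

    def to_u(self, x: float) -> float:
        if self.transform == "log":
            return math.log(max(x, 1e-9))
        if self.transform == "logit":
            return _logit(x)
        if self.transform == "shift1":
            return math.log(max(x - 1.0, 1e-6))
        if self.transform == "omexp":  # x = 1 - e^u: boundary x -> 1 reachable
            return math.log(max(1.0 - x, 1e-13))
        raise ValueError(self.transform)

    def from_u(self, u: float) -> float:
        if self.transform == "log":
            x = math.exp(u)
            return min(x, self.upper) if self.upper else x
        if self.transform == "logit":
            return _sigmoid(u)
        if self.transform == "shift1":
            return 1.0 + math.exp(u)
        if self.transform == "omexp":
            return 1.0 - math.exp(min(u, -1e-12))  # clamp: x stays in (0, 1)
        raise ValueError(self.transform)

    def bounds(self) -> tuple[float, float]:
        if self.transform == "log":
            hi = math.log(self.upper) if self.upper else 10.0
            return (-14.0, hi)
        if self.transform == "logit":
            return (-12.0, 12.0)
        if self.transform == "shift1":
            return (-12.0, math.log(OMEGA_MAX))
        if self.transform == "omexp":
            return (-30.0, -1e-9)
        raise ValueError(self.transform)


def _model_params(name: str, start_omega: float, config: FitConfig) -> list[_Param]:
    """Free substitution/mixture parameters of each model (kappa separate)."""
    w0 = min(max(start_omega, 0.02), 0.9)  # purifying-class seed
    w2 = max(start_omega, 1.5)  # positive-class seed
    m = min(max(start_omega, 0.05), 0.95)
    if name == "M0":
        return [_Param("omega", "log", min(start_omega, config.omega_max),
                       upper=config.omega_max)]
    if name == "M1a":
        return [_Param("omega0", "logit", w0), _Param("p0", "logit", 0.7)]
    if name == "M2a":
        return [
            _Param("omega0", "logit", w0),
            _Param("p0", "logit", 0.6),
            _Param("p1_rel", "omexp", 0.5),
            _Param("omega2", "shift1", w2),
        ]
    if name == "M7":
        return [_Param("p_beta", "log", 2 * m, upper=99.0),
                _Param("q_beta", "log", 2 * (1 - m), upper=99.0)]
    if name == "M8":
        return [
            _Param("p_beta", "log", 2 * m, upper=99.0),
            _Param("q_beta", "log", 2 * (1 - m), upper=99.0),
            _Param("p0", "omexp", 0.9),
            _Param("omega_s", "shift1", w2),
        ]
    if name == "branch_site_A":
        return [
            _Param("omega0", "logit", w0),
            _Param("p01", "logit", 0.85),
            _Param("p0_rel", "logit", 0.7),
            _Param("omega2", "shift1", w2),
        ]
    if name == "branch_site_A_null":
        return [
            _Param("omega0", "logit", w0),
            _Param("p01", "logit", 0.85),
            _Param("p0_rel", "logit", 0.7),
        ]
    raise ValueError(f"unknown model {name!r}")


def _natural_to_model_kwargs(name: str, values: dict) -> dict:
    """Map the optimisation parameterisation to make_site_model params."""
    v = dict(values)
    if name == "M2a":
        p0 = v.pop("p0")
        p1 = (1 - p0) * v.pop("p1_rel")
        v.update(p0=p0, p1=p1)
    if name in ("branch_site_A", "branch_site_A_null"):
        p01 = v.pop("p01")
        rel = v.pop("p0_rel")
        v.update(p0=p01 * rel, p1=p01 * (1 - rel))
    return v


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

class _Objective:
    """Negative lnL with mixed analytic/numeric gradient.

    Works on the raw-rate time scale: per-class likelihoods are computed
    under unnormalised GY94 matrices at tau = t / s, where s is the shared
    mixture normalisation.  Branch-length and mixture-weight gradients (and
    the chain-rule term through s) are analytic; each distinct omega/shape
    parameter needs a forward difference over only the classes it touches,
    and kappa over all classes.
    """

    _FD = 1e-5

    def __init__(
        self,
        engine: TreeLikelihood,
        model_name: str,
        params: list[_Param],
        pi: np.ndarray,
        config: FitConfig,
        base_lengths: np.ndarray,
        branch_mode: str,
    ) -> None:
        self.engine = engine
        self.model_name = model_name
        self.params = params  # model params then kappa, in u-space order
        self.pi = pi
        self.config = config
        self.base_lengths = base_lengths  # per-node lengths of the input tree
        self.branch_mode = branch_mode
        self.branches = engine.tree.branch_indices()
        self.n_model = len(params)  # includes kappa as the last entry
        self.n_calls = 0
        # per-site scaling keeps gradients O(1) so the optimiser's initial
        # steepest-descent step is sane
        self.fscale = float(max(engine.counts.sum(), 1.0))
        base = unnormalized_rates(1.0, 1.0, pi, engine.code)
        _, transition, nonsyn = _structure_tables(engine.code)
        # flow = B + kappa*Bk + omega*(A + kappa*Ak)
        self._B = flow_rate(np.where(~nonsyn & ~transition, base, 0.0), pi)
        self._Bk = flow_rate(np.where(~nonsyn & transition, base, 0.0), pi)
        self._A = flow_rate(np.where(nonsyn & ~transition, base, 0.0), pi)
        self._Ak = flow_rate(np.where(nonsyn & transition, base, 0.0), pi)

    # vector layout: [model params + kappa][branch part]
    def split(self, x: np.ndarray) -> tuple[dict, float, np.ndarray]:
        values = {
            p.name: p.from_u(x[i]) for i, p in enumerate(self.params[:-1])
        }
        kappa = self.params[-1].from_u(x[self.n_model - 1])
        t = np.zeros(len(self.base_lengths))
        if self.branch_mode == "scale":
            s = math.exp(x[self.n_model])
            t[self.branches] = self.base_lengths[self.branches] * s
        else:
            t[self.branches] = np.exp(x[self.n_model :])
        return values, kappa, t

    def model_of(self, values: dict) -> SiteClassModel:
        kwargs = _natural_to_model_kwargs(self.model_name, values)
        return make_site_model(
            self.model_name, kwargs, K=self.config.n_beta_categories
        )

    def _scale(self, model: SiteClassModel, kappa: float) -> float:
        syn = self._B + kappa * self._Bk
        non = self._A + kappa * self._Ak
        return float(
            np.sum(model.class_weights * (syn + model.class_omegas_background * non))
        )

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        self.n_calls += 1
        values, kappa, t = self.split(x)
        model = self.model_of(values)
        s = self._scale(model, kappa)
        tau = np.zeros_like(t)
        tau[self.branches] = t[self.branches] / s
        eng = self.engine
        w = model.class_weights
        L, G = eng.class_pattern_likelihoods_raw(
            model.class_omegas_background, model.class_omegas_foreground,
            kappa, self.pi, tau, want_grad=True,
        )
        mix = np.maximum(w @ L, 1e-300)
        counts = eng.counts
        lnL = float(counts @ np.log(mix))
        inv = counts / mix
        # analytic pieces
        r_class = L @ inv                     # dlnL/dw_c
        g_tau = np.einsum("c,cbp,p->b", w, G, inv)  # dlnL/dtau_b
        T1 = float(np.dot(g_tau, tau[self.branches]))  # for the s chain rule

        g = np.zeros_like(x)
        if self.branch_mode == "scale":
            g[self.n_model] = T1
        else:
            g[self.n_model:] = g_tau * tau[self.branches]

        h = self._FD
        for i, prm in enumerate(self.params):
            xp = x.copy()
            xp[i] += h
            vp, kp, _ = self.split(xp)
            model_p = self.model_of(vp)
            dw = (model_p.class_weights - w) / h
            d_bg = (model_p.class_omegas_background - model.class_omegas_background) / h
            d_fg = (model_p.class_omegas_foreground - model.class_omegas_foreground) / h
            sp = self._scale(model_p, kp)
            ds = (sp - s) / h
            gi = float(np.dot(dw, r_class)) - (ds / s) * T1
            changed = [
                c for c in range(model.n_classes)
                if abs(d_bg[c]) > 1e-12 or abs(d_fg[c]) > 1e-12
            ]
            if prm.name == "kappa" and kp != kappa:
                changed = list(range(model.n_classes))
            if changed:
                Lp, _ = eng.class_pattern_likelihoods_raw(
                    model_p.class_omegas_background,
                    model_p.class_omegas_foreground,
                    kp, self.pi, tau, classes=changed,
                )
                dL = np.zeros(eng.n_patterns)
                for c in changed:
                    dL += w[c] * (Lp[c] - L[c]) / h
                gi += float(np.dot(dL, inv))
            g[i] = gi
        return -lnL / self.fscale, -g / self.fscale


def _is_informationless(alignment: CodonAlignment) -> bool:
    """True when no site shows two different non-missing states."""
    for col in alignment.codons.T:
        states = set(int(s) for s in col if s != MISSING)
        if len(states) > 1:
            return False
    return True


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit_model(
    alignment: CodonAlignment,
    tree: PhyloTree,
    model_name: str,
    config: FitConfig | None = None,
    code: GeneticCode | None = None,
    pi: np.ndarray | None = None,
    init_overrides: dict | None = None,
) -> ModelFit:
    """Fit a site-class model by maximum likelihood.

    Maximises lnL over kappa, the model's omega/proportion/shape parameters
    and the branch lengths, from each configured starting omega; the best
    start is kept and all are recorded in ``ModelFit.restarts``.
    ``init_overrides`` pins chosen starting values in the fit
    parameterisation (used to anchor an alternative model at its null's
    optimum).
    """
    config = config or FitConfig()
    code = code or universal_code()
    if pi is None:
        pi = pi_from_mode(config.pi_mode, alignment, code)
    engine = TreeLikelihood(alignment, tree, code)

    if _is_informationless(alignment):
        logger.warning(
            "%s: alignment has no substitutions; boundary fit returned",
            alignment.gene_id,
        )
        t = np.full(len(tree.branch_lengths), _MIN_BL)
        params = {p.name: p.init for p in _model_params(model_name, 1.0, config)}
        kwargs = _natural_to_model_kwargs(model_name, params)
        model = make_site_model(model_name, kwargs, K=config.n_beta_categories)
        lnL = engine.log_likelihood(model, config.kappa_start, pi, t)
        est = dict(kwargs)
        for k in est:
            if k.startswith("omega"):
                est[k] = float("nan")
        return ModelFit(
            gene_id=alignment.gene_id,
            model=model,
            lnL=lnL,
            kappa=config.kappa_start,
            pi=pi,
            branch_lengths=t,
            estimates=est,
            restarts=[],
            converged=True,
            identifiable=False,
        )

    best: dict | None = None
    restarts: list[tuple[float, float]] = []
    warm: dict | None = None
    start_list = list(config.start_omegas) * max(1, config.replicates)
    for start_omega in start_list:
        result = _fit_once(
            engine, model_name, start_omega, pi, config, tree, warm,
            init_overrides,
        )
        restarts.append((start_omega, result["lnL"]))
        if best is None or result["lnL"] > best["lnL"]:
            best = result
        if warm is None:
            warm = {
                "kappa": best["kappa"],
                "branch_lengths": best["branch_lengths"],
            }
    assert best is not None
    if not best["converged"]:
        logger.warning(
            "%s/%s: optimiser did not report convergence (lnL=%.6f)",
            alignment.gene_id, model_name, best["lnL"],
        )
    est = dict(best["values_model"])
    if any(
        v >= config.omega_max * 0.999
        for k, v in est.items()
        if k.startswith("omega")
    ):
        logger.warning("%s/%s: omega hit upper bound", alignment.gene_id, model_name)
    return ModelFit(
        gene_id=alignment.gene_id,
        model=best["model"],
        lnL=best["lnL"],
        kappa=best["kappa"],
        pi=pi,
        branch_lengths=best["branch_lengths"],
        estimates=est,
        restarts=restarts,
        converged=bool(best["converged"]),
        identifiable=True,
    )


def _fit_once(
    engine: TreeLikelihood,
    model_name: str,
    start_omega: float,
    pi: np.ndarray,
    config: FitConfig,
    tree: PhyloTree,
    warm: dict | None,
    init_overrides: dict | None = None,
) -> dict:
    params = _model_params(model_name, start_omega, config)
    if init_overrides:
        params = [
            dataclasses.replace(p, init=init_overrides[p.name])
            if p.name in init_overrides
            else p
            for p in params
        ]
    kappa_init = warm["kappa"] if warm else config.kappa_start
    params = params + [_Param("kappa", "log", kappa_init, upper=200.0)]
    base = (
        warm["branch_lengths"].copy()
        if warm is not None
        else np.clip(tree.branch_lengths, 10 * _MIN_BL, _MAX_BL)
    )
    branches = tree.branch_indices()

    # ftol is relative in L-BFGS-B; aim for the configured absolute lnL change
    scale_guess = max(1.0, engine.counts.sum())
    opts = {
        "maxiter": config.maxiter,
        "ftol": config.tol / (10.0 * scale_guess),
        "gtol": 2e-4,
    }

    # stage A: joint tree-scale
    obj = _Objective(engine, model_name, params, pi, config, base, "scale")
    x0 = np.array([p.to_u(p.init) for p in params] + [0.0])
    bounds = [p.bounds() for p in params] + [(-10.0, 6.0)]
    resA = optimize.minimize(
        obj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options=dict(opts, maxiter=min(config.maxiter, 100)
                     if config.branch_mode == "full" else config.maxiter),
    )
    valuesA, kappaA, tA = obj.split(resA.x)
    lnL = -resA.fun * obj.fscale
    converged = bool(resA.success)
    values, kappa, t = valuesA, kappaA, tA

    if config.branch_mode == "full":
        objB = _Objective(engine, model_name, params, pi, config, base, "full")
        tstart = np.clip(tA[branches], 2 * _MIN_BL, _MAX_BL * 0.99)
        xB0 = np.concatenate([resA.x[: len(params)], np.log(tstart)])
        boundsB = [p.bounds() for p in params] + [
            (math.log(_MIN_BL), math.log(_MAX_BL))
        ] * len(branches)
        resB = optimize.minimize(
            objB, xB0, jac=True, method="L-BFGS-B", bounds=boundsB,
            options=opts,
        )
        lnL_B = -resB.fun * objB.fscale
        if lnL_B >= lnL - 1e-9:
            values, kappa, t = objB.split(resB.x)
            lnL = lnL_B
            converged = bool(resB.success)

    kwargs = _natural_to_model_kwargs(model_name, values)
    model = make_site_model(model_name, kwargs, K=config.n_beta_categories)
    return {
        "lnL": float(lnL),
        "kappa": float(kappa),
        "branch_lengths": t,
        "values_model": {k: float(v) for k, v in kwargs.items()},
        "model": model,
        "converged": converged,
    }


def choose_tree(
    alignment: CodonAlignment,
    candidate_trees: list[PhyloTree],
    config: FitConfig | None = None,
    code: GeneticCode | None = None,
) -> tuple[PhyloTree, list[float]]:
    """Pick the candidate tree whose M0 fit attains the higher lnL.

    Ties (within the optimiser tolerance) go to the earlier candidate, with
    a logged note.
    """
    if not candidate_trees:
        raise ValueError("no candidate trees supplied")
    config = config or FitConfig()
    lnLs = [
        fit_model(alignment, t, "M0", config, code).lnL for t in candidate_trees
    ]
    best = int(np.argmax(lnLs))
    top = max(lnLs)
    ties = [i for i, l in enumerate(lnLs) if abs(l - top) <= config.tol]
    if len(ties) > 1:
        logger.info(
            "%s: %d candidate trees tie at lnL=%.6f; keeping the first",
            alignment.gene_id, len(ties), top,
        )
        best = ties[0]
    return candidate_trees[best], lnLs


def estimate_rates(
    m0_fit: ModelFit, code: GeneticCode | None = None
) -> RateEstimates:
    """Tree-wide dN and dS from an M0 fit.

    Site proportions are evaluated at omega = 1 (mutational opportunity),
    substitution fractions at the fitted omega; dN and dS are per-site
    totals over the tree (three nucleotide sites per codon), so
    dN/dS = omega by construction.
    """
    code = code or universal_code()
    if m0_fit.model.name != "M0":
        raise ValueError("estimate_rates requires an M0 fit")
    omega = m0_fit.estimates.get("omega", float("nan"))
    T = float(np.sum(m0_fit.branch_lengths[m0_fit.branch_lengths > 0]))
    if not m0_fit.identifiable or not np.isfinite(omega):
        logger.warning("%s: omega not identifiable; rates reported as 0", m0_fit.gene_id)
        return RateEstimates(m0_fit.gene_id, float("nan"), 0.0, 0.0, T)
    pi = m0_fit.pi
    base = unnormalized_rates(m0_fit.kappa, 1.0, pi, code)
    _, _, nonsyn = _structure_tables(code)
    A = flow_rate(np.where(nonsyn, base, 0.0), pi)  # nonsynonymous flow at omega=1
    B = flow_rate(np.where(nonsyn, 0.0, base), pi)  # synonymous flow
    fN = omega * A / (omega * A + B)  # realised nonsyn substitution fraction
    pN = A / (A + B)  # nonsyn site proportion
    dN = T * fN / (3 * pN)
    dS = T * (1 - fN) / (3 * (1 - pN))
    if dS == 0:
        logger.warning("%s: dS = 0; omega taken from the fit", m0_fit.gene_id)
    return RateEstimates(m0_fit.gene_id, float(omega), float(dN), float(dS), T)
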