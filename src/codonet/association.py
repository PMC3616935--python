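"""Rank statistics linking evolutionary rates to topology and classification.

The battery mirrors the study design: Spearman's rho of each rate (omega,
dN, dS) against each topological variable (closeness, betweenness, degree)
and protein length; Kruskal-Wallis of each rate across each classification
(cell type, process, function); and Spearman's rho of each node's rate
against the mean rate of its network neighbors.  Missing values are
dropped listwise per statistic — genes outside the network simply never
enter the topology correlations — and p-values are reported uncorrected.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import neighbor_mean

logger = logging.getLogger(__name__)

RATE_VARIABLES = ("omega", "dN", "dS")
TOPOLOGY_VARIABLES = ("closeness", "betweenness", "degree", "protein_length")
CLASSIFICATIONS = ("cell_type", "process", "function")

_EXACT_N = 10  # below this, Spearman p by permutation


@dataclass
class SpearmanResult:
    x_variable: str
    y_variable: str
    rho: float
    p: float
    n: int


@dataclass
class KruskalResult:
    classification: str
    rate_variable: str
    H: float
    df: int
    p: float
    group_medians: dict
    group_quartiles: dict = field(default_factory=dict)


@dataclass
class AssociationReport:
    spearman_results: list[SpearmanResult]
    kruskal_results: list[KruskalResult]
    neighbor_results: list[SpearmanResult]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "spearman": [vars(r) for r in self.spearman_results],
            "kruskal_wallis": [vars(r) for r in self.kruskal_results],
            "neighbor_spearman": [vars(r) for r in self.neighbor_results],
        }


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def spearman(
    x,
    y,
    method: str = "auto",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Spearman rank correlation with a two-sided p-value.

    ``method='auto'`` uses the t approximation for n >= 10 and an exact /
    sampled permutation null below that (all n! orderings are enumerated up
    to n = 8, otherwise ``n_permutations`` draws).  Pairs with a missing
    member are dropped; a constant vector yields rho = NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: Spearman rho undefined")
        return float("nan"), float("nan"), n
    rho = float(stats.spearmanr(x, y).statistic)
    if method == "approx" or (method == "auto" and n >= _EXACT_N):
        p = float(stats.spearmanr(x, y).pvalue)
        return rho, p, n
    # permutation null on the rank correlation
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(_pearson(rx, ry))
    if n <= 8:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    null = _pearson_rows(rx[perms], ry)
    p = float(np.mean(np.abs(null) >= obs - 1e-12))
    return rho, p, n


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / math.sqrt((a @ a) * (b @ b)))


def _pearson_rows(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=1, keepdims=True)
    b = b - b.mean()
    denom = np.sqrt((A * A).sum(axis=1) * (b @ b))
    return (A @ b) / denom


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square df = k - 1 p-value.

    Groups emptied by missing-value removal are dropped (df adjusted, with
    a warning); all-tied data report H = 0, p = 1 with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    samples = []
    for g in pd.unique(groups):
        sample = values[groups == g]
        if len(sample) == 0:
            logger.warning("group %r empty after missing-value removal", g)
            continue
        samples.append(sample)
    if len(samples) < 2:
        raise ValueError("need at least 2 nonempty groups")
    df = len(samples) - 1
    if np.ptp(values) == 0:
        logger.warning("all values tied: Kruskal-Wallis H degenerate, reported 0")
        return 0.0, df, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), df, float(p)


# ---------------------------------------------------------------------------
# the full battery
# ---------------------------------------------------------------------------

def run_associations(
    per_gene: pd.DataFrame,
    network,
    spearman_method: str = "auto",
) -> AssociationReport:
    """Run the whole association battery on the joined per-gene table.

    ``per_gene`` must hold one row per gene with the rate columns (omega,
    dN, dS), topology columns (closeness, betweenness, degree; NaN for
    genes outside the network), protein_length and the three
    classification columns.  ``network`` supplies neighbor structure for
    the neighbor-mean correlations.
    """
    required = set(RATE_VARIABLES) | {"gene", "protein_length"} | set(CLASSIFICATIONS)
    missing = required - set(per_gene.columns)
    if missing:
        raise ValueError(f"per-gene table missing columns: {sorted(missing)}")
    if len(per_gene) == 0:
        raise ValueError("empty per-gene table")

    sp_results = []
    for rate in RATE_VARIABLES:
        for topo in TOPOLOGY_VARIABLES:
            if topo not in per_gene.columns:
                continue
            try:
                rho, p, n = spearman(
                    per_gene[topo], per_gene[rate], method=spearman_method
                )
            except ValueError:
                logger.warning("skipping %s vs %s: too few pairs", topo, rate)
                continue
            sp_results.append(SpearmanResult(topo, rate, rho, p, n))

    kw_results = []
    for cls in CLASSIFICATIONS:
        for rate in RATE_VARIABLES:
            vals = per_gene[rate].to_numpy(dtype=float)
            grp = per_gene[cls].to_numpy()
            keep = np.isfinite(vals)
            present = pd.unique(grp[keep])
            if len(present) < 2:
                logger.warning("skipping %s vs %s: <2 groups", cls, rate)
                continue
            H, df, p = kruskal_wallis(vals, grp)
            med = {}
            quart = {}
            for g in present:
                sample = vals[keep & (grp == g)]
                med[str(g)] = float(np.median(sample))
                quart[str(g)] = [
                    float(np.percentile(sample, 25)),
                    float(np.percentile(sample, 75)),
                ]
            kw_results.append(KruskalResult(cls, rate, H, df, p, med, quart))

    nb_results = []
    in_net = per_gene[per_gene["gene"].isin(network.nodes)] if network else per_gene.iloc[:0]
    for rate in RATE_VARIABLES:
        if len(in_net) == 0:
            break
        values = dict(zip(in_net["gene"], in_net[rate].astype(float)))
        nmean = neighbor_mean(network, values)
        x = np.array([values.get(g, np.nan) for g in in_net["gene"]])
        y = np.array([nmean.get(g, np.nan) for g in in_net["gene"]])
        try:
            rho, p, n = spearman(x, y, method=spearman_method)
        except ValueError:
            continue
        nb_results.append(SpearmanResult(f"neighbor_mean_{rate}", rate, rho, p, n))

    return AssociationReport(
        spearman_results=sp_results,
        kruskal_results=kw_results,
        neighbor_results=nb_results,
        metadata={
            "n_genes": int(len(per_gene)),
            "n_network_genes": int(len(in_net)) if network else 0,
            "multiplicity_correction": "none (raw p-values)",
        },
    )
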