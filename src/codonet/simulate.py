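"""Forward simulation of the study's inputs.

Three layers: codon alignments evolved under the fitted model families on a
fixed tree; a connected random pathway network with the curated graph's size
(81 interactions); and a gene table whose true selective pressures carry a
planted topology slope and functional-class shifts, mirroring the structure
the analysis is designed to detect.  Every gene of a study draws its own
random substream from the single global seed, so per-gene results are
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .codon_model import (
    make_site_model,
    mixture_matrices,
    uniform_pi,
)
from .genetic_code import GeneticCode, universal_code
from .io import FUNCTIONS, CodonAlignment
from .tree import PhyloTree, parse_newick

#: The nine-taxon mammal phylogeny used throughout, with branch lengths in
#: expected substitutions per codon chosen to reflect the group's divergence
#: (primate branches short, rodent/dog branches long; total ~1.9).  Internal
#: nodes carry stable labels so foreground branches are addressable by name,
#: in particular ``hominids`` (great-ape ancestor) and ``rodents``.
MAMMAL9_NEWICK = (
    "((((((human:0.02,chimpanzee:0.02)hominini:0.015,gorilla:0.025)"
    "homininae:0.02,orangutan:0.05)hominids:0.05,macaque:0.09)"
    "catarrhini:0.06,marmoset:0.12)primates:0.25,"
    "(mouse:0.18,rat:0.16)rodents:0.45,dog:0.35);"
)


def mammal9_fixture() -> PhyloTree:
    """The packaged nine-mammal species tree."""
    return parse_newick(MAMMAL9_NEWICK)


@dataclass
class SimulationSpec:
    """Conditions of a simulated study.

    Defaults emulate the real study's shape: a 9-taxon mammal tree, ~54
    genes of ~300 codons, a connected 30-node/81-edge signaling network
    (the genes beyond the network playing the part of the retinoid-cycle
    and development genes outside it), purifying selection everywhere
    (true omega clamped below 1), a negative closeness-omega slope and
    function-class shifts.
    """

    seed: int = 0
    tree: PhyloTree | None = None
    model_name: str = "M0"
    model_params: dict = field(default_factory=lambda: {"omega": 0.3})
    kappa: float = 2.0
    pi: np.ndarray | None = None  # default: uniform over sense codons
    n_codons: int = 300
    # study-level structure
    n_genes: int = 54
    n_network_nodes: int = 30
    n_network_edges: int = 81
    omega_base: float = 0.30
    topology_slope: float = 0.12  # omega drop per SD of closeness
    group_shifts: dict = field(
        default_factory=lambda: {
            "enzyme": 0.10,
            "ion_channel_exchanger": 0.12,
            "chaperone": -0.10,
            "g_protein": -0.12,
        }
    )
    noise_scale: float = 0.05
    omega_bounds: tuple[float, float] = (0.005, 0.95)
    length_jitter: float = 0.25  # per-gene codon count ~ U(1-j, 1+j) * n_codons

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be >= 0")

    def resolved_tree(self) -> PhyloTree:
        return self.tree if self.tree is not None else mammal9_fixture()


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def _sample_rows(P: np.ndarray, states: np.ndarray, rng: np.random.Generator
                 ) -> np.ndarray:
    """Draw one categorical sample per row of P[states]."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(states))
    return (cum[states] < u[:, None]).sum(axis=1).astype(np.int16)


def simulate_alignment(
    spec: SimulationSpec,
    gene_id: str = "gene",
    rng: np.random.Generator | None = None,
    code: GeneticCode | None = None,
) -> CodonAlignment:
    """Evolve a codon alignment down the tree under a site-class model.

    Per site: a class is drawn by its mixture weight, the root codon from
    ``pi``, and each branch applies that class's transition matrix
    (foreground branches use the foreground omega).  Deterministic given the
    spec's seed (or an explicit generator).
    """
    code = code or universal_code()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    tree = spec.resolved_tree()
    pi = spec.pi if spec.pi is not None else uniform_pi(code)
    model = make_site_model(spec.model_name, spec.model_params)
    bg, fg = mixture_matrices(model, spec.kappa, pi, code)
    n = spec.n_codons
    classes = rng.choice(model.n_classes, size=n, p=model.class_weights)
    states = {tree.root: rng.choice(code.n_states, size=n, p=pi).astype(np.int16)}
    order = list(reversed(tree.postorder()))  # preorder: parents first
    eig_bg = [Q.eig() for Q in bg]
    eig_fg = eig_bg if fg is bg else [Q.eig() for Q in fg]
    for v in order:
        if v == tree.root:
            continue
        is_fg = bool(tree.foreground[v])
        child = np.empty(n, dtype=np.int16)
        for c in range(model.n_classes):
            mask = classes == c
            if not mask.any():
                continue
            lam, U, Uinv = eig_fg[c] if is_fg else eig_bg[c]
            P = (U * np.exp(lam * tree.branch_lengths[v])[None, :]) @ Uinv
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            child[mask] = _sample_rows(P, states[v_parent(tree, v)][mask], rng)
        states[v] = child
    taxa = []
    rows = []
    for v in tree.leaf_indices():
        taxa.append(tree.labels[v])
        rows.append(states[v])
    aln = CodonAlignment(gene_id, taxa, np.array(rows, dtype=np.int16))
    return aln


def v_parent(tree: PhyloTree, v: int) -> int:
    return int(tree.parent[v])


def true_site_classes(spec: SimulationSpec, gene_seed: int) -> np.ndarray:
    """Replay the per-site class draw of :func:`simulate_alignment`."""
    rng = np.random.default_rng(gene_seed)
    model = make_site_model(spec.model_name, spec.model_params)
    return rng.choice(model.n_classes, size=spec.n_codons, p=model.class_weights)


# ---------------------------------------------------------------------------
# network simulation
# ---------------------------------------------------------------------------

def random_connected_network(
    n_nodes: int, n_edges: int, rng: np.random.Generator,
    prefix: str = "G",
) -> nx.Graph:
    """Connected simple graph: random spanning tree plus extra edges."""
    if n_edges < n_nodes - 1:
        raise ValueError("need at least n_nodes - 1 edges for connectivity")
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("edge count exceeds simple-graph capacity")
    names = [f"{prefix}{i:03d}" for i in range(n_nodes)]
    G = nx.Graph()
    G.add_nodes_from(names)
    shuffled = list(names)
    rng.shuffle(shuffled)
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        G.add_edge(shuffled[i], shuffled[j])
    while G.number_of_edges() < n_edges:
        a, b = rng.choice(n_nodes, size=2, replace=False)
        G.add_edge(names[int(a)], names[int(b)])
    return G


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

def simulate_study(
    spec: SimulationSpec, code: GeneticCode | None = None
) -> tuple[dict[str, CodonAlignment], nx.Graph, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic study.

    Returns ``(alignments, network, annotations, truth)`` where ``truth``
    holds each gene's true omega, its components (closeness effect, group
    shift, noise) and the substream seed used for its alignment.
    """
    code = code or universal_code()
    if spec.n_genes < spec.n_network_nodes:
        raise ValueError("n_genes must cover the network nodes")
    root_ss = np.random.SeedSequence(spec.seed)
    net_ss, assign_ss, genes_ss = root_ss.spawn(3)
    rng_net = np.random.default_rng(net_ss)
    rng_assign = np.random.default_rng(assign_ss)

    G = random_connected_network(
        spec.n_network_nodes, spec.n_network_edges, rng_net
    )
    network_genes = sorted(G.nodes)
    n_extra = spec.n_genes - spec.n_network_nodes
    extra_genes = [f"X{i:03d}" for i in range(n_extra)]
    genes = network_genes + extra_genes

    closeness = nx.closeness_centrality(G, wf_improved=False)
    cvals = np.array([closeness[g] for g in network_genes])
    cz = (cvals - cvals.mean()) / (cvals.std() or 1.0)

    functions = list(FUNCTIONS)
    rows = []
    gene_seeds = [int(s.generate_state(1)[0] >> 1) for s in genes_ss.spawn(len(genes))]
    for k, g in enumerate(genes):
        in_net = g in G
        function = functions[int(rng_assign.integers(0, len(functions)))]
        if in_net:
            process = "phototransduction"
            cell_type = ("rod", "cone", "shared")[int(rng_assign.integers(0, 3))]
            topo = -spec.topology_slope * cz[network_genes.index(g)]
        else:
            process = ("retinoid_cycle", "development")[int(rng_assign.integers(0, 2))]
            cell_type = "shared"
            topo = 0.0
        shift = spec.group_shifts.get(function, 0.0)
        noise = float(rng_assign.normal(0.0, spec.noise_scale))
        omega = float(
            np.clip(spec.omega_base + topo + shift + noise, *spec.omega_bounds)
        )
        j = spec.length_jitter
        n_codons = max(
            10, int(round(spec.n_codons * rng_assign.uniform(1 - j, 1 + j)))
        )
        rows.append(
            dict(
                gene=g, in_network=in_net, cell_type=cell_type, process=process,
                function=function, protein_length=n_codons,
                true_omega=omega, topology_effect=topo, group_shift=shift,
                noise=noise, seed=gene_seeds[k],
            )
        )
    truth = pd.DataFrame(rows)

    alignments: dict[str, CodonAlignment] = {}
    for _, row in truth.iterrows():
        gene_spec = replace(
            spec, model_name="M0", model_params={"omega": row["true_omega"]},
            seed=int(row["seed"]), n_codons=int(row["protein_length"]),
        )
        alignments[row["gene"]] = simulate_alignment(
            gene_spec, gene_id=row["gene"], code=code
        )

    annotations = truth[
        ["gene", "cell_type", "process", "function", "protein_length"]
    ].copy()
    return alignments, G, annotations, truth
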