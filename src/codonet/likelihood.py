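"""Felsenstein pruning on codon alignments, with branch-length gradients.

The engine compresses the alignment to unique site patterns, computes
per-class per-pattern likelihoods by postorder accumulation of partial
likelihood vectors, and (optionally) the exact gradient of each class's
pattern likelihood with respect to every branch length via a preorder pass
of "outer" partials.  MISSING tip states contribute all-ones partial
vectors, the standard missing-data treatment.

The model is time-reversible, so the computed likelihood does not depend on
root placement (pulley principle); a test asserts this on re-rooted trees.
"""

from __future__ import annotations

import numpy as np

from .codon_model import CodonRateMatrix, SiteClassModel, mixture_matrices
from .genetic_code import MISSING, GeneticCode, universal_code
from .io import CodonAlignment
from .tree import PhyloTree


class LikelihoodError(ValueError):
    pass


def _pattern_compress(codons: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique columns of the codon matrix with counts and inverse map."""
    cols = codons.T  # (n_sites, n_taxa)
    patterns, inverse, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts.astype(float), inverse


class TreeLikelihood:
    """Pruning likelihood for one alignment on one tree.

    Parameters are supplied per evaluation (rate matrices and branch
    lengths), so a single engine serves a whole optimisation.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhyloTree,
        code: GeneticCode | None = None,
    ) -> None:
        self.code = code or universal_code()
        self.tree = tree
        leaf_labels = tree.leaf_labels()
        missing = [t for t in alignment.taxa if t not in leaf_labels]
        if missing:
            raise LikelihoodError(f"taxa not in tree: {missing}")
        # Leaves of the tree absent from the alignment carry all-missing data.
        row_of = {t: i for i, t in enumerate(alignment.taxa)}
        self.patterns, self.counts, self.pattern_of_site = _pattern_compress(
            alignment.codons
        )
        self.n_patterns = self.patterns.shape[1]
        self.n_sites = alignment.n_sites
        n_states = self.code.n_states
        # per-leaf pattern states, MISSING mapped to the augmented index
        self.leaf_states: dict[int, np.ndarray] = {}
        for v in tree.leaf_indices():
            label = tree.labels[v]
            if label in row_of:
                states = self.patterns[row_of[label]].astype(int)
            else:
                states = np.full(self.n_patterns, MISSING)
            self.leaf_states[v] = np.where(states == MISSING, n_states, states)
        self._postorder = tree.postorder()
        self._preorder = list(reversed(self._postorder))
        self._branches = tree.branch_indices()

    # -- single-class pass -------------------------------------------------
    def _class_pass(
        self,
        P: dict[int, np.ndarray],
        Qmat: dict[int, np.ndarray],
        pi: np.ndarray,
        want_grad: bool,
    ) -> tuple[np.ndarray, dict[int, np.ndarray] | None]:
        tree = self.tree
        npat = self.n_patterns
        n_states = len(pi)
        root = tree.root
        ones_col = np.ones((n_states, 1))
        Paug = {v: np.hstack([P[v], ones_col]) for v in self._branches}

        M: dict[int, np.ndarray] = {}  # message from node v to its parent
        D: dict[int, np.ndarray] = {}  # partial at internal node v
        for v in self._postorder:
            if tree.is_leaf(v):
                M[v] = Paug[v][:, self.leaf_states[v]].T
            else:
                prod = M[tree.children[v][0]].copy()
                for c in tree.children[v][1:]:
                    prod *= M[c]
                D[v] = prod
                if v != root:
                    M[v] = prod @ P[v].T
        L = D[root] @ pi
        if not want_grad:
            return L, None

        # preorder outer partials O[v]: likelihood of everything outside v's
        # subtree, indexed by the state of v's parent (root prior included)
        O: dict[int, np.ndarray] = {}
        grads: dict[int, np.ndarray] = {}
        zeros_col = np.zeros((n_states, 1))
        for v in self._preorder:
            if v == root:
                continue
            par = tree.parent[v]
            sibs = [s for s in tree.children[par] if s != v]
            sib_prod = M[sibs[0]].copy()
            for s in sibs[1:]:
                sib_prod *= M[s]
            if par == root:
                O[v] = pi[None, :] * sib_prod
            else:
                O[v] = (O[par] @ P[par]) * sib_prod
            A = Qmat[v] @ P[v]
            if tree.is_leaf(v):
                T = O[v] @ np.hstack([A, zeros_col])
                grads[v] = T[np.arange(npat), self.leaf_states[v]]
            else:
                grads[v] = ((O[v] @ A) * D[v]).sum(axis=1)
        return L, grads

    # -- mixtures ------------------------------------------------------------
    def class_pattern_likelihoods(
        self,
        model: SiteClassModel,
        kappa: float,
        pi: np.ndarray,
        branch_lengths: np.ndarray | None = None,
        want_grad: bool = False,
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Per-class per-pattern likelihoods (and branch gradients).

        Returns ``(L, G)`` with ``L`` of shape (n_classes, n_patterns) and
        ``G`` of shape (n_classes, n_branches, n_patterns) or None.
        """
        tree = self.tree
        if model.is_branch_model and not tree.foreground.any():
            raise LikelihoodError(
                "branch-site model requires a foreground branch on the tree"
            )
        if model.is_branch_model and tree.foreground.all():
            raise LikelihoodError("foreground cannot be the entire tree")
        t = (
            tree.branch_lengths
            if branch_lengths is None
            else np.asarray(branch_lengths, dtype=float)
        )
        if np.any(t[self._branches] < 0):
            raise LikelihoodError("negative branch length")
        bg, fg = mixture_matrices(model, kappa, pi, self.code)
        L = np.empty((model.n_classes, self.n_patterns))
        G = (
            np.zeros((model.n_classes, len(self._branches), self.n_patterns))
            if want_grad
            else None
        )
        for c in range(model.n_classes):
            eig_bg = bg[c].eig()
            eig_fg = fg[c].eig() if fg[c] is not bg[c] else eig_bg
            P: dict[int, np.ndarray] = {}
            Qd: dict[int, np.ndarray] = {}
            for v in self._branches:
                Q = fg[c] if tree.foreground[v] else bg[c]
                lam, U, Uinv = eig_fg if tree.foreground[v] else eig_bg
                Pv = (U * np.exp(lam * t[v])[None, :]) @ Uinv
                np.clip(Pv, 0.0, None, out=Pv)
                P[v] = Pv
                Qd[v] = Q.Q
            Lc, gc = self._class_pass(P, Qd, pi, want_grad)
            L[c] = Lc
            if want_grad:
                for bi, v in enumerate(self._branches):
                    G[c, bi] = gc[v]
        return L, G

    def class_pattern_likelihoods_raw(
        self,
        omegas_bg: np.ndarray,
        omegas_fg: np.ndarray,
        kappa: float,
        pi: np.ndarray,
        tau: np.ndarray,
        want_grad: bool = False,
        classes: list[int] | None = None,
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Per-class likelihoods under *unnormalised* GY94 matrices.

        ``tau`` are branch lengths on the raw-rate time scale (the caller
        owns the normalisation); eigendecompositions are shared between
        classes with equal omega.  ``classes`` restricts the computation to
        a subset (rows of the result are zero elsewhere), which the fitter
        uses for single-class finite differences.
        """
        from .codon_model import build_rate_matrix

        tree = self.tree
        n_classes = len(omegas_bg)
        sel = list(range(n_classes)) if classes is None else classes
        L = np.zeros((n_classes, self.n_patterns))
        G = (
            np.zeros((n_classes, len(self._branches), self.n_patterns))
            if want_grad
            else None
        )
        cache: dict[float, tuple] = {}

        def eig_of(om: float):
            if om not in cache:
                Q = build_rate_matrix(kappa, om, pi, self.code, scale=1.0)
                cache[om] = (Q, Q.eig())
            return cache[om]

        for c in sel:
            Qb, eb = eig_of(float(omegas_bg[c]))
            Qf, ef = eig_of(float(omegas_fg[c]))
            P: dict[int, np.ndarray] = {}
            Qd: dict[int, np.ndarray] = {}
            for v in self._branches:
                Q, (lam, U, Uinv) = (Qf, ef) if tree.foreground[v] else (Qb, eb)
                Pv = (U * np.exp(lam * tau[v])[None, :]) @ Uinv
                np.clip(Pv, 0.0, None, out=Pv)
                P[v] = Pv
                Qd[v] = Q.Q
            Lc, gc = self._class_pass(P, Qd, pi, want_grad)
            L[c] = Lc
            if want_grad:
                for bi, v in enumerate(self._branches):
                    G[c, bi] = gc[v]
        return L, G

    def log_likelihood(
        self,
        model: SiteClassModel,
        kappa: float,
        pi: np.ndarray,
        branch_lengths: np.ndarray | None = None,
    ) -> float:
        L, _ = self.class_pattern_likelihoods(model, kappa, pi, branch_lengths)
        mix = model.class_weights @ L
        return float(self.counts @ np.log(np.maximum(mix, 1e-300)))

    def log_likelihood_and_branch_grad(
        self,
        model: SiteClassModel,
        kappa: float,
        pi: np.ndarray,
        branch_lengths: np.ndarray | None = None,
    ) -> tuple[float, np.ndarray]:
        """lnL and its gradient over branches (ordered as branch_indices)."""
        L, G = self.class_pattern_likelihoods(
            model, kappa, pi, branch_lengths, want_grad=True
        )
        w = model.class_weights
        mix = np.maximum(w @ L, 1e-300)
        lnL = float(self.counts @ np.log(mix))
        # dlnL/dt_b = sum_p c_p (sum_c w_c dL_cpb) / mix_p
        gmix = np.einsum("c,cbp->bp", w, G)
        grad = (gmix * (self.counts / mix)[None, :]).sum(axis=1)
        return lnL, grad

    def site_log_likelihoods(
        self,
        model: SiteClassModel,
        kappa: float,
        pi: np.ndarray,
        branch_lengths: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-site (not per-pattern) mixture log-likelihoods."""
        L, _ = self.class_pattern_likelihoods(model, kappa, pi, branch_lengths)
        mix = np.maximum(model.class_weights @ L, 1e-300)
        return np.log(mix)[self.pattern_of_site]


# ---------------------------------------------------------------------------
# spec-level convenience operations
# ---------------------------------------------------------------------------

def site_log_likelihood(
    alignment: CodonAlignment,
    tree: PhyloTree,
    per_branch_Q: dict[int, CodonRateMatrix],
    site: int,
    code: GeneticCode | None = None,
) -> float:
    """Log-likelihood of a single codon site under per-branch rate matrices.

    ``per_branch_Q`` maps node index (branch above that node) to its matrix;
    the stationary distribution of the root's first branch matrix is used as
    the root prior.
    """
    code = code or universal_code()
    engine = TreeLikelihood(
        CodonAlignment(alignment.gene_id, alignment.taxa,
                       alignment.codons[:, [site]]),
        tree, code,
    )
    branches = tree.branch_indices()
    pi = per_branch_Q[branches[0]].pi
    P = {}
    Qd = {}
    for v in branches:
        Q = per_branch_Q[v]
        P[v] = np.asarray(
            (lambda lam, U, Uinv: (U * np.exp(lam * tree.branch_lengths[v])) @ Uinv)(
                *Q.eig()
            )
        )
        np.clip(P[v], 0.0, None, out=P[v])
        Qd[v] = Q.Q
    L, _ = engine._class_pass(P, Qd, pi, want_grad=False)
    return float(np.log(np.maximum(L[0], 1e-300)))


def model_log_likelihood(
    alignment: CodonAlignment,
    tree: PhyloTree,
    model: SiteClassModel,
    kappa: float,
    pi: np.ndarray,
    code: GeneticCode | None = None,
) -> float:
    """Mixture log-likelihood of the whole alignment under a site model."""
    engine = TreeLikelihood(alignment, tree, code)
    return engine.log_likelihood(model, kappa, pi)
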