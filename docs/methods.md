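# Methods

## The model

All rate estimation is built on the Goldman–Yang codon substitution model.
States are the 61 sense codons of the universal genetic code; the
instantaneous rate from codon *i* to codon *j* is zero unless the codons
differ at exactly one nucleotide, and otherwise

    q_ij = pi_j                      synonymous transversion
    q_ij = kappa * pi_j              synonymous transition
    q_ij = omega * pi_j              nonsynonymous transversion
    q_ij = omega * kappa * pi_j      nonsynonymous transition

with equilibrium codon frequencies `pi`, transition/transversion rate ratio
`kappa`, and `omega = dN/dS` measuring selective pressure (`omega < 1`
purifying, `= 1` neutral, `> 1` positive selection).  The matrix is
time-reversible; transition probabilities come from the symmetrized
eigendecomposition, and a scaling-and-squaring matrix exponential serves as
an independent numerical oracle in the tests (agreement to 1e-10).

Site-class mixtures follow the codeml family:

* **M0** — one `omega` for all sites and branches.
* **M1a / M2a** — nearly-neutral (`omega0 < 1`, `omega1 = 1`) versus
  positive selection (an added class with `omega2 >= 1`); LRT with df = 2.
* **M7 / M8** — beta-distributed `omega` in (0,1), discretized into K = 10
  equal-weight categories at bin medians (the codeml default; K is
  configurable), versus beta plus a class at `omega_s >= 1`; df = 2.
* **Branch-site model A** — four site classes (0, 1, 2a, 2b); classes 2a/2b
  allow `omega2 >= 1` on a single designated foreground branch only, with
  the remainder proportions split as `p0 : p1`.  The null pins
  `omega2 = 1`; df = 1.  The chi-square reference (not the 50:50 mixture)
  is the default, matching common practice; the mixture null is available
  as an option.

Mixture normalisation uses a single shared scale — the proportion-weighted
expected flow of the background class matrices — so one unit of branch
length is one expected substitution per codon averaged over site classes,
and faster classes genuinely evolve faster.  The simulator uses the same
convention, so recovery tests are internally consistent.

Tree-wide `dN` and `dS` are derived from the M0 fit: site proportions are
evaluated at `omega = 1` (mutational opportunity), substitution fractions
at the fitted `omega`, and both rates are per-site totals over the tree
(three nucleotide sites per codon), which makes `dN/dS = omega` an exact
internal identity.  Whether such totals or per-branch averages are
reported is a presentation choice; totals are used here.

## Likelihood and optimisation

The likelihood engine compresses alignments to unique site patterns and
runs Felsenstein pruning with per-class transition matrices; gap or
ambiguous codons contribute all-ones partial vectors (standard
missing-data treatment), and deleting a taxon's data is
likelihood-equivalent to marking it missing (tested).  The engine also
returns the exact gradient of the likelihood with respect to every branch
length from one extra pre-order pass of outer partial vectors.

Fits maximise lnL over `kappa`, the mixture's free parameters and all
branch lengths with L-BFGS-B on unconstrained transforms: log for positive
rates, logit for proportions and omegas in (0,1), `1 + exp(u)` for omegas
constrained at or above 1, and a log-complement transform for proportions
whose boundary value 1 must be attainable (so that M8 can collapse exactly
onto M7, and M2a onto M1a — otherwise nested LRTs can go slightly
negative).  The objective is scaled per site so the optimiser's initial
steepest-descent step is well-conditioned.  Branch-length gradients are
analytic; the remaining few parameters use forward differences that
recompute only the site classes each parameter touches, with the chain
rule through the shared mixture scale handled analytically.

Each fit is staged: a cheap pass that co-optimises a single tree-scale
factor with the substitution parameters, then full per-branch optimisation
warm-started from it.  Convergence is declared at lnL changes below 1e-6.
Multi-start fitting re-seeds the omega-type parameters from
`start_omegas = (0.1, 1.0, 2.0)` by default; restarts after the first
reuse the incumbent branch lengths and kappa.  For the single-omega M0
surface — which is well-behaved in practice (the three standard starts
agree to better than 1e-4 in the tests) — the large simulation batteries
use a single start at 1.0 to keep runtimes proportionate.  `omega` is
bounded at 50 during optimisation (logged if hit).  An alignment with no
two differing codons at any site yields a boundary fit: near-zero branch
lengths, lnL equal to the zero-length-tree value and `omega` reported as
non-identifiable rather than as an error.

Nested test pairs carry a safety net: if the alternative's optimum falls
below the null's, the alternative is refitted from a start that reproduces
the null exactly inside the alternative's parameter space (vanishing
positive-class weight, `omega2` just above 1), after which the LRT
statistic is clamped at zero if still marginally negative.

When both a species tree and a gene tree are supplied, the tree whose M0
fit attains the higher maximum likelihood is kept (ties go to the first
candidate, logged).

## BEB site identification

Posterior probabilities that a codon evolves at `omega > 1` are computed
two ways.  NEB plugs the MLEs into Bayes' rule.  BEB averages the class
posteriors over a uniform prior grid — 10 points per free dimension over
the mixture proportions and the positive-class omega (grid midpoints of
(0,1) for proportions and of (1,11) for `omega2`/`omega_s`), with
`kappa`, branch lengths and the purifying-class parameters fixed at their
MLEs.  Branch lengths are held fixed on the raw-rate time scale implied by
the MLE normalisation, so per-class site likelihoods are independent of
the grid's proportions and are shared across grid points.  For M8 the
beta shapes stay at their MLEs and the grid covers the beta-weight
proportion and `omega_s`; this desk-scale reduction keeps the integration
over the dimensions that dominate posterior uncertainty.  On long
(2000-codon) simulated alignments NEB and BEB posteriors agree closely;
on short ones BEB shrinks toward the prior, which is its purpose.

## Networks and statistics

The pathway graph is undirected and unweighted (interaction presence, not
strength).  Closeness uses the within-component convention
`(n_c - 1) / sum of distances`; betweenness is unnormalised over unordered
pairs with endpoints excluded (a normalised column is emitted alongside);
disconnected inputs are computed per component with a prominent warning.
These are library computations (networkx) behind the module surface, and
the tests pin them to an exhaustive all-pairs path-enumeration oracle on
every small graph tried.

Spearman correlations use averaged ranks; p-values come from the
t approximation for n >= 10 and from exact (n <= 8, all n! orderings) or
sampled (n = 9) permutation otherwise.  Kruskal–Wallis is the
tie-corrected rank statistic against chi-square with k - 1 df; groups
emptied by missing values are dropped with a warning, fully tied data
report H = 0.  The association battery runs Spearman of {omega, dN, dS}
against {closeness, betweenness, degree, protein length}, Kruskal–Wallis
of the three rates across the three classifications, and Spearman of each
node's rate against its neighbors' mean rate.  Missing values are deleted
listwise per statistic — genes outside the network never enter topology
correlations — and no multiplicity correction is applied across this
battery (noted in the report metadata).  Selection-test p-values, by
contrast, are corrected per family: each site test across genes, the
branch-site test across all gene x branch combinations; the default
procedure is Benjamini–Hochberg FDR, with Holm and Bonferroni selectable.
By default branch-site tests run on internal branches only, configurable.

## The synthetic-data generator

The generator emulates the study design rather than any particular gene:

* a fixed 9-taxon mammal phylogeny (human, chimpanzee, gorilla, orangutan,
  macaque, marmoset, mouse, rat, dog) with branch lengths in expected
  substitutions per codon totalling ~1.9, primate branches short and
  rodent/dog branches long; the great-ape and rodent ancestral branches
  carry stable labels so they can be tagged as branch-site foregrounds;
* codon alignments evolved forward site by site under any of the model
  families (root codon from `pi`, per-branch categorical transitions,
  foreground omegas on tagged branches), deterministic given the seed;
* a connected random pathway network built as a random spanning tree plus
  extra edges, defaulting to 30 nodes and 81 edges to mirror the curated
  interaction list's size — connectedness is guaranteed because the
  closeness convention assumes it;
* a gene table of 54 genes by default: the 30 network genes are
  "phototransduction", the rest split between "retinoid cycle" and
  "development" and stay outside the network, mirroring the fact that the
  curated graph covers only the signaling cascade.  Each gene's true omega
  is `clamp(0.30 - 0.12 * z(closeness) + shift(function) + N(0, 0.05),
  0.005, 0.95)` — the clamp keeps every gene under purifying selection,
  the observed regime.  Function-class shifts default to +0.10/+0.12 for
  retinoid-cycle enzymes and ion channels/exchangers and -0.10/-0.12 for
  chaperones and G proteins, the direction of the relaxation/constraint
  contrast the analysis is designed to detect.  Per-gene codon counts
  jitter by +/-25% around 300 so protein length varies realistically.

A single global seed fans out to per-gene substreams
(`numpy.random.SeedSequence`), so any one gene's data can be regenerated
in isolation.

What the generator does **not** emulate: alignment error or indels (inputs
are modeled as post-cleaning), codon usage bias (the root distribution is
uniform over sense codons by default), rate variation along branches, gene
gain/loss, or correlated evolution between interacting genes beyond the
planted closeness slope.  Passing tests therefore demonstrate estimator
correctness and calibration under the model's own assumptions, not
robustness to real-data pathologies such as the misannotated-exon episode
that motivates alignment screening.

## Problem sizes used by the test suite

Simulation batteries are sized for a single CPU: 200 replicates for M0
omega recovery (500 codons); 60 replicates for site-test calibration and
24 null + 12 alternative replicates for the branch-site test (300
codons); 5 replicates of 2000 codons for BEB discrimination; 100 random
graphs for the centrality oracle; 3 seeds of the full 54-gene planted
study.  The acceptance script reruns smaller versions of the same
computations from scratch.

## Known limitations

* No among-branch free-ratio models, gamma rate variation, or selection on
  synonymous sites; codon frequencies are F3x4/F61/uniform only.
* Likelihood underflow protection relies on float64 headroom, adequate for
  tens of taxa but not for very large trees.
* The BEB grid fixes nuisance parameters at their MLEs (see above), a
  deliberate desk-scale reduction of the published design.
* Branch-site p-values use the plain chi-square reference by default; the
  mixture reference typically halves small p-values.
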