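# Methods

## Problem and model

Tumors accumulate somatic mutations in a handful of core biological
pathways, and the order in which those pathways are hit is informative about
how the cancer develops. Cross-sectional cohorts only show each tumor's
final mutation catalog, but tumor phylogeny reconstruction (PhyloWGS,
Canopy, ...) recovers, per patient, a posterior set of subclone trees in
which ancestry encodes within-patient temporal order. `pathorder` combines
three inputs across a cohort — per-patient candidate trees with posteriors,
per-mutation functional impact scores r_k ∈ [0,1] (the probability that
mutation k is a driver-like functional event), and pathway gene sets — into
a cohort-level estimate of pathway mutation order.

The estimand is the pivotal probability matrix P, whose (k, i) entry is the
probability that the k-th *functional* mutational event of a tumor occurs in
pathway category i. For patient j with mutations 1..c_j, latent functional
statuses S_kj ~ Bernoulli(r_k), and candidate tree T_j, the likelihood
marginalizes over trees, functional splits, and all mutation orders
consistent with the tree:

    L_j = Σ_t P(T_j = t) Σ_S Π_k r_k^{S_k} (1−r_k)^{1−S_k}
            × [ Σ over t-consistent orders of the functional subset
                Π_k p_{k, i_k} ]
            × [ Σ over t-consistent orders of the non-functional subset
                Π_l q_{i_l} ].

"Consistent with t" means: a mutation sequence in which no earlier mutation
sits on a subclone strictly downstream of a later one. Mutations on the same
subclone are mutually incomparable — this is the tie rule forced by the
consistency definition, stated here explicitly. Non-functional (passenger)
mutations are assumed order-free with a common category distribution q,
estimated in closed form from expected passenger counts
E_lj = Σ_{k in category l} (1−r_k) as q_i = (Σ_j E_ij)/(Σ_j Σ_l E_lj). If
every r_k is exactly 1 this is undefined and q falls back to uniform with a
warning. Note that the non-functional factor sums over *all* consistent
passenger orders, so the multiplicity of linear extensions enters the
likelihood, not a single representative order.

Analysis is pairwise: for each pathway pair (A, B), genes are re-organized
into mutually exclusive categories A\B, B\A, A∩B (empty categories
dropped), and mutations outside A∪B are dropped entirely. A patient left
with no pair mutations contributes a unit likelihood factor. The pairwise
design keeps the parameter count small and the tree reductions cheap; it
also means the sequence alphabet contains no "other" category, which is the
design choice we made where the modeling of non-pair mutations was genuinely
open.

Given the fitted P, the probability that A is altered before B is a
first-passage quantity over category sequences of length c = max_j c_j
(total pair-restricted counts, not functional-only): the first event in any
pair-relevant category decides — A\B means A before B, B\A the reverse, and
A∩B a tie. The tie probability therefore decomposes into a shared-category
component and a censoring component (no pair event within c steps); both
are reported (`tie_shared`, `tie_censored`). With row tying (below) the
result is insensitive to c once c exceeds the tying step. The computation is
an O(c) recursion on the undecided mass, checked against explicit sequence
enumeration for small c.

## Estimation

Because the certainty about pathway identity should be greatest for the
first functional event and decay afterwards, the MLE is regularized by an
entropy ordering constraint: H(row k1) < H(row k2) for k1 < k2, where H is
Shannon entropy. Strict inequalities do not define a closed feasible set,
so they are implemented as H(k+1) − H(k) ≥ δ with margin δ = 1e−6. Rows
beyond the tying step k0 share row k0 (default k0 = 4, beyond which
estimated rows stabilize); this caps the parameter count regardless of
mutation burden.

Rows are parameterized by softmax logits (one logit per row pinned to 0),
which keeps iterates in the open simplex where the entropy is smooth, and
the constrained problem is solved with SLSQP. Five starts by default: two
deterministic entropy-ordered tilts of the uniform matrix plus seeded
Gaussian perturbations; the best feasible solution (violation ≤ 1e−7) is
returned with per-start diagnostics, and an error carrying those
diagnostics is raised if no start is feasible. With a single category the
matrix is trivially all-ones and no optimization runs.

For speed, each patient is pre-summarized once per pair: for every reduced
tree poset and every functional split, the sum over consistent functional
orders is grouped by monomial signature — the categories of the first
k0−1 positions plus category counts of the tied tail — so the cohort
log-likelihood becomes a vectorized sum of monomials in P. Optimizer
iterations then cost microseconds per evaluation regardless of tree
complexity.

### Computational reductions

Three reductions keep the computation tractable, mirrored from the method's
design:

1. **Pairwise analysis** (above).
2. **Tree reduction, merging and truncation.** Candidate trees are projected
   onto the pair's mutations; structurally identical reductions (same sorted
   element list and transitively closed relation — our formalization of
   "same structure") are merged with posteriors added exactly; the merged
   list is sorted by descending posterior (ties broken by a canonical
   structure key) and cut at the shortest prefix reaching cumulative
   posterior 0.95, then renormalized to sum to 1. Renormalization is our
   choice where the design was open: without it, patient likelihood factors
   would sit on inconsistent scales.
3. **Row tying** at k0 = 4 (above).

Sums over linear extensions are computed by dynamic programming over
down-closed subsets of the poset (position = subset size), exact to
floating point; with unit weights this equals the number of linear
extensions, which on rooted forests has the closed form n!/Π(subtree
sizes) used as an independent test oracle. The DP is exponential only in
the antichain width of the reduced poset, which is small after pair
restriction. The latent split sum is enumerated exactly for c_j ≤ 12
(default `c_max`) and replaced by a seeded Monte Carlo average over
S ~ Π Bernoulli(r_k) (default 1000 draws, per-patient substream derived
from the config seed and a CRC of the patient id) beyond that; the MC
estimate is unbiased for the likelihood, hence slightly biased for its log,
which matters only for extreme mutation burdens and is documented here.

## Preprocessing rules

- **Hyper-mutator exclusion**: patients with total mutation count strictly
  above the empirical (1−f) quantile are dropped (default f = 0.16), ties at
  the cutoff retained. Hyper-mutated tumors (MSI/POLE-like) follow a
  different mutational process. The quantile uses linear interpolation; the
  rule is deterministic but not idempotent under re-application, since the
  quantile recomputes on the filtered cohort.
- **Posterior tolerance**: per-patient tree posteriors must sum to 1 within
  1e−6 (renormalized silently inside tolerance; an error beyond it, treated
  as data corruption rather than rounding).

## Graph summary

Per pair, only the more probable direction is kept, and only if it reaches
the edge threshold (default 0.4); both directed values plus the tie mass
are retained in the serialized long-form CSV for transparency. Pairwise
estimates need not be transitive, so cycles are possible: each is broken by
removing its lowest-weight edge, with a logged warning — a rule of ours,
since intransitivity has no canonical resolution. The result then undergoes
transitive reduction (an edge parallel to a longer directed path is
removed) and longest-incoming-path layering, a cosmetic choice emulating
layered graph drawing. DOT export is deterministic byte-for-byte; edge pen
width is proportional to the direction probability (scale 6).

## Synthetic cohorts

The generator plants a known pathway order: per patient, a random subclone
tree (default 4 subclones, branching probability 0.5), a Poisson(5) number
of pathway-relevant mutations of which Binomial(c, 0.5) are functional;
functional pathway identities are drawn sequentially from true pivotal rows
and placed on nodes so the sampled order is a linear extension of the tree
(a new functional mutation may not land on a proper ancestor of an earlier
one); passengers land on uniform nodes, in a uniform pathway or (with
probability 0.2) outside the catalog. Default true rows plant the listed
pathway order: row 1 is geometric with ratio 0.25 over the order — (0.8,
0.2) for two pathways — and later rows mix linearly toward uniform, so row
entropies increase strictly and every row favors earlier pathways.

Candidate-tree uncertainty is emulated by emitting the true tree plus
subtree-prune-regraft perturbations (default 3 trees total) with Dirichlet
posteriors whose concentration favors the true tree (weight 6 vs 1, divided
by a temperature parameter); the true tree has the highest posterior on
average but not always.

Functional scores are drawn class-conditionally as Beta(1.3, 0.3) for
functional and Beta(0.3, 1.3) for passenger mutations. These defaults are
deliberately the coherent pair induced by marginal r ~ Beta(0.3, 0.3) with
S | r ~ Bernoulli(r), so that P(S = 1 | r) = r — exactly the reading the
likelihood gives the scores — while still being strongly separated
(functional scores concentrate near 1, passenger scores near 0). Choosing
incoherent class conditionals would plant a calibration bias in the study
conditions themselves.

What the generator does *not* emulate: read-level data and variant allele
frequencies; correlated tree errors from a real reconstruction tool;
miscalibrated functional scores; gene-level mutation hotspots; pathway
overlap (simulated gene pools are disjoint — overlapping categories are
exercised by handcrafted fixtures instead). Passing tests therefore show
the estimator is correct and well-behaved under its own assumptions, not
that those assumptions hold in any particular real cohort.

## Problem sizes and numerical choices

The validation suite uses cohorts of 80–300 patients with Poisson(5)
pair-relevant mutations, which we consider representative desk-scale
conditions for a pairwise analysis; the exhaustive oracles run on instances
with c_j ≤ 6 and ≤ 3 candidate trees where complete enumeration of 2^c
splits and all permutations is feasible. Parameter recovery is evaluated at
n = 200 patients over 20 seeds (fitted first-row probability within ±0.1 of
the planted 0.8, planted direction recovered); the end-to-end check plants
a three-pathway chain at n = 300 and requires the pruned graph to equal it
exactly.

Tolerances: likelihood DP vs brute force, relative 1e−10; order-probability
recursion vs enumeration, absolute 1e−12; probability simplex checks, 1e−8;
posterior mass conservation under merging, exact (compensated summation);
extension counts vs closed form, exact.

Known limitations: the exact split sum is exponential in c_j (hence the
c_max/Monte-Carlo switch); the extension DP is exponential in antichain
width (irrelevant after pair restriction, prohibitive for joint N-pathway
analysis, which is out of scope along with standard errors for P); on an
exactly symmetric cohort the strict entropy ordering excludes the uniform
matrix, so the constrained optimum sits a hair below the unconstrained one;
and the PhyloWGS adapter consumes a merged JSON dialect (per-tree `llh`,
`structure`, `mut_assignments`, with softmax-normalized log-likelihoods and
the mutation-free normal root node "0" dropped when it has exactly one
child) rather than the tool's zip-packaged raw output.
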