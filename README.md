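# pathorder

Estimate the temporal order in which biological pathways acquire functional
somatic mutations during tumor development, from a cohort of
phylogeny-annotated tumor samples.

## The problem

Cohort mutation catalogs alone order pathway alterations poorly: a pathway
that is frequently mutated may still be mutated *late*, as its mutations can
be largely subclonal. `pathorder` is for cancer-genomics analysts who have,
per patient:

- candidate subclone trees with posterior probabilities (from tumor
  phylogeny tools such as PhyloWGS — tree ancestry encodes within-patient
  temporal order),
- per-mutation functional impact scores r_k ∈ [0,1] (probability the
  mutation is a functional/driver event rather than a passenger),
- pathway gene sets (GMT).

## The model

The core estimand is the pivotal probability matrix **P**, with p_{k,i} the
probability that the k-th functional mutational event falls in pathway
category i. For each pathway pair, genes are re-organized into mutually
exclusive categories (A\B, B\A, A∩B), and per patient j the likelihood
marginalizes over candidate trees t, latent functional statuses
S_k ~ Bernoulli(r_k), and all mutation orders consistent with the tree:

    L_j = Σ_t P(t) Σ_S Π_k r_k^{S_k}(1−r_k)^{1−S_k}
            · [Σ_{consistent functional orders} Π_k p_{k,i_k}]
            · [Σ_{consistent passenger orders} Π_l q_{i_l}]

with q the order-free background category distribution of passengers,
estimated from expected passenger counts. **P** is fitted by maximum
likelihood under an entropy ordering constraint (row entropies strictly
increase with the event index k — certainty is highest for the first
event), with rows tied after step k0 = 4. From the fitted **P**, the
probability P(A<B) that pathway A is altered before B is the probability
that the first pair-relevant functional event lies in A\B; all pairwise
results are summarized as a pruned, layered partial-order graph.

Computational reductions: pairwise analysis; reduction of candidate trees
to pair mutations with merging of structurally identical reductions and
truncation at cumulative posterior 0.95; dynamic programming over
down-closed subsets for sums over tree-consistent orders. See
`docs/methods.md` for details and assumptions.

## Worked example

Simulate a two-pathway cohort whose planted first-event distribution is
(0.8, 0.2) over (A, B), then estimate the pair order:

```python
import pathorder as po

cohort, truth = po.simulate_cohort(po.SimulationConfig(n_patients=200, seed=1))
analysis = po.analyze_pair(cohort, truth.catalog, "A", "B", po.FitConfig(seed=1))
print("P(A<B) =", round(analysis.result.p_a_before_b, 3))
print("P(B<A) =", round(analysis.result.p_b_before_a, 3))
print("pivotal rows:\n", analysis.pivotal.rows.round(3))
```

prints

```
P(A<B) = 0.822
P(B<A) = 0.178
pivotal rows:
 [[0.822 0.178]
 [0.685 0.315]
 [0.685 0.315]
 [0.494 0.506]]
```

The fitted first row (0.822, 0.178) recovers the planted (0.8, 0.2): the
first functional event falls in pathway A with probability ≈ 0.82, so A is
estimated to be altered before B with that probability. Later rows drift
toward uniform, reflecting decreasing certainty at later mutational steps
(row entropies 0.468 → 0.623 → 0.693), and the fit improves on the
uniform-matrix log-likelihood (−278.8 vs −316.9).

The same pipeline from the shell:

```sh
pathorder simulate --seed 11 --n 300 --pathways W,M,P -o cohort.json
pathorder fit-all --cohort cohort.json --gmt pathways.gmt --seed 11 -o fits/
pathorder plot --matrix fits/pair_matrix.csv -o order.dot
```

For a cohort with the planted order W ≺ M ≺ P this yields the chain
`W -> M -> P` in `order.dot` (the transitive W→P edge, probability 0.93, is
pruned as an indirect connection; edge widths are proportional to the
direction probabilities).

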