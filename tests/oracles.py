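"""Independent brute-force oracles used to check the package's fast paths.

Everything here deliberately avoids the implementation's dynamic programs:
linear extensions come from filtering raw permutations, likelihoods from
exhaustive sums over every latent functional split and every extension pair,
order probabilities from enumerating all category sequences, and extension
counts of forests from the hook-length closed form.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from pathorder import ReducedPoset


def permutation_extensions(poset: ReducedPoset) -> list[tuple[str, ...]]:
    """Linear extensions by filtering all permutations."""
    out = []
    for perm in itertools.permutations(poset.elements):
        pos = {e: i for i, e in enumerate(perm)}
        if all(pos[u] < pos[v] for u, v in poset.precedes):
            out.append(perm)
    return out


def induced_subposet(poset: ReducedPoset, subset) -> ReducedPoset:
    subset = set(subset)
    return ReducedPoset(
        elements=tuple(sorted(subset)),
        precedes=frozenset((u, v) for u, v in poset.precedes if u in subset and v in subset),
        posterior=1.0,
    )


def brute_patient_log_likelihood(patient, posets, P, q_map, categories) -> float:
    """Exhaustive likelihood: every split S, every extension of both subsets."""
    by_id = patient.mutation_by_id()
    total = 0.0
    for poset in posets:
        elems = poset.elements
        c = len(elems)
        for mask in range(1 << c):
            w = 1.0
            for i, e in enumerate(elems):
                r = by_id[e].functional_score
                w *= r if mask >> i & 1 else 1.0 - r
            func = [e for i, e in enumerate(elems) if mask >> i & 1]
            nonf = [e for i, e in enumerate(elems) if not mask >> i & 1]
            idx = {lab: i for i, lab in enumerate(P.alphabet)}
            fsum = 0.0
            for ext in permutation_extensions(induced_subposet(poset, func)):
                prod = 1.0
                for k, e in enumerate(ext, start=1):
                    prod *= P.row(k)[idx[categories[e]]]
                fsum += prod
            nsum = 0.0
            for ext in permutation_extensions(induced_subposet(poset, nonf)):
                prod = 1.0
                for e in ext:
                    prod *= q_map[categories[e]]
                nsum += prod
            total += poset.posterior * w * fsum * nsum
    return math.log(total)


def enumerate_order_probabilities(P, c: int) -> tuple[float, float, float]:
    """Eq.-style order probabilities by enumerating all category sequences."""
    labels = P.alphabet
    pa = pb = tie = 0.0
    for seq in itertools.product(range(len(labels)), repeat=c):
        prob = 1.0
        for k, i in enumerate(seq, start=1):
            prob *= P.row(k)[i]
        outcome = "tie"
        for i in seq:
            lab = labels[i]
            if lab == "A_only":
                outcome = "a"
                break
            if lab == "B_only":
                outcome = "b"
                break
            if lab == "AB_shared":
                outcome = "tie"
                break
        if outcome == "a":
            pa += prob
        elif outcome == "b":
            pb += prob
        else:
            tie += prob
    return pa, pb, tie


def random_forest_poset(rng: np.random.Generator, n: int) -> tuple[ReducedPoset, int]:
    """Random rooted forest poset on n mutations plus its hook-length count.

    Each mutation sits on its own node under a mutation-free root, so the
    induced order is a forest; the number of linear extensions is
    n! / prod(subtree sizes).
    """
    parent_idx = [-1] * n  # -1: child of the barren root (forest component)
    for i in range(1, n):
        j = int(rng.integers(-1, i))
        parent_idx[i] = j
    elements = tuple(f"m{i}" for i in range(n))
    precedes = set()
    for v in range(n):
        u = parent_idx[v]
        while u != -1:
            precedes.add((elements[u], elements[v]))
            u = parent_idx[u]
    sizes = [1] * n
    for v in range(n - 1, -1, -1):
        if parent_idx[v] != -1:
            sizes[parent_idx[v]] += sizes[v]
    denom = math.prod(sizes)
    count, rem = divmod(math.factorial(n), denom)
    assert rem == 0, "hook-length denominator must divide n!"
    return (
        ReducedPoset(elements=elements, precedes=frozenset(precedes), posterior=1.0),
        count,
    )
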