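"""Likelihood model for the temporal order of pathway mutations.

The quantity of interest is the pivotal probability matrix ``P`` whose
(k, i) entry is the probability that the k-th *functional* mutational event
of a tumor falls in pathway category i. Per patient j, with mutations
k = 1..c_j carrying functional impact scores r_k = P(S_k = 1), the observed
pathway counts have likelihood

    L_j = sum_t P(t) * sum_S prod_k r_k^{S_k} (1 - r_k)^{1 - S_k}
              * [ sum over t-consistent orders of the functional subset of
                  prod_k p_{k, i_k} ]
              * [ sum over t-consistent orders of the non-functional subset of
                  prod_l q_{i_l} ],

where t ranges over the patient's (reduced, truncated) candidate tree posets,
S over latent functional-status splits, and q is the order-free background
category distribution of passenger mutations. Rows of P beyond the tying
step k0 share row k0. P is estimated by maximum likelihood under an entropy
ordering constraint: the k-th row's entropy must increase with k (certainty
about pathway identity is highest for the first functional event).

Implementation note: for fixed q and data, L_j is a polynomial in the
entries of P. Each patient is pre-summarized into sparse monomial
coefficients indexed by (first-(k0-1) category prefix, tail category
counts), so likelihood evaluations inside the optimizer are vectorized
array operations.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .cohort import (
    A_ONLY,
    AB_SHARED,
    B_ONLY,
    CATEGORY_ORDER,
    PairCategories,
    PathwayCatalog,
    PatientSample,
    make_pair_categories,
    restrict_patient_to_pair,
)
from .trees import ReducedPoset, patient_posets

__all__ = [
    "PivotalMatrix",
    "BackgroundDist",
    "FunctionalSplit",
    "PairOrderResult",
    "PairAnalysis",
    "FitConfig",
    "FitError",
    "estimate_q",
    "patient_log_likelihood",
    "cohort_log_likelihood",
    "fit_P",
    "pair_order_probabilities",
    "analyze_pair",
]

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-8


@dataclass(eq=False)
class PivotalMatrix:
    """Row-stochastic matrix p_{k,i} over a category alphabet, tied after k0.

    ``rows`` has shape (k0, N); ``row(k)`` returns row min(k, k0).
    """

    alphabet: tuple[str, ...]
    rows: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != len(self.alphabet):
            raise ValueError("rows must be (k0, len(alphabet))")
        if np.any(self.rows < -1e-12):
            raise ValueError("pivotal probabilities must be non-negative")
        sums = self.rows.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
            raise ValueError(f"pivotal rows must sum to 1 (got {sums})")

    @property
    def k0(self) -> int:
        return self.rows.shape[0]

    def row(self, k: int) -> np.ndarray:
        if k < 1:
            raise ValueError("positions are 1-based")
        return self.rows[min(k, self.k0) - 1]

    def entropies(self) -> np.ndarray:
        p = self.rows
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, -p * np.log(p), 0.0)
        return terms.sum(axis=1)

    @classmethod
    def uniform(cls, alphabet: Sequence[str], k0: int) -> "PivotalMatrix":
        n = len(alphabet)
        return cls(alphabet=tuple(alphabet), rows=np.full((k0, n), 1.0 / n))

    def as_dict(self) -> dict:
        return {"alphabet": list(self.alphabet), "rows": self.rows.tolist()}


@dataclass(eq=False)
class BackgroundDist:
    """Background category distribution q of non-functional mutations.

    ``expected_counts`` keeps the per-patient intermediates E_lj (expected
    non-functional mutation counts per category).
    """

    alphabet: tuple[str, ...]
    q: np.ndarray
    expected_counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q < 0) or abs(self.q.sum() - 1.0) > ROW_SUM_TOL:
            raise ValueError("q must be a probability vector")

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.alphabet, self.q.tolist()))


@dataclass(frozen=True)
class FunctionalSplit:
    """One latent functional-status assignment S over a patient's mutations."""

    mask: int
    weight: float
    n_functional: int


@dataclass(frozen=True)
class PairOrderResult:
    """Directed order probabilities for one pathway pair.

    The tie probability decomposes into the mass of the first pair-relevant
    functional event landing in the shared category A∩B (``tie_shared``) and
    the mass of no pair-relevant event within c steps (``tie_censored``).
    """

    p_a_before_b: float
    p_b_before_a: float
    p_tie: float
    c: int
    tie_shared: float = 0.0
    tie_censored: float = 0.0
    uninformative: bool = False

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings.

    k0: row-tying step of the pivotal matrix (rows beyond k0 reuse row k0).
    truncation: cumulative-posterior threshold for candidate-tree truncation.
    entropy_margin: margin by which consecutive row entropies must increase
        (the strict ordering constraint, relaxed to a closed feasible set).
    c_max: largest mutation count for which the 2^c latent split sum is
        enumerated exactly; larger patients use seeded Monte Carlo.
    mc_draws: number of Monte Carlo splits when c_j > c_max.
    """

    k0: int = 4
    truncation: float = 0.95
    entropy_margin: float = 1e-6
    c_max: int = 12
    mc_draws: int = 1000
    tol: float = 1e-8
    max_iter: int = 300
    restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 < 1:
            raise ValueError("k0 must be >= 1")
        if not (0 < self.truncation <= 1):
            raise ValueError("truncation must be in (0, 1]")
        for name in ("entropy_margin", "c_max", "mc_draws", "tol", "max_iter", "restarts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class FitError(RuntimeError):
    """Raised when the constrained optimizer fails across all restarts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# ---------------------------------------------------------------------------
# Background distribution
# ---------------------------------------------------------------------------


def estimate_q(
    patients: Sequence[PatientSample], alphabet: Sequence[str]
) -> BackgroundDist:
    """Estimate the passenger category distribution q from functional scores.

    E_lj = sum over patient j's mutations in category l of (1 - r_k) is the
    expected non-functional count; q_i = (sum_j E_ij) / (sum_j sum_l E_lj).
    If every score is exactly 1 there are no expected passengers and q falls
    back to uniform with a warning.
    """
    alphabet = tuple(alphabet)
    index = {label: i for i, label in enumerate(alphabet)}
    expected: dict[str, np.ndarray] = {}
    for p in patients:
        e = np.zeros(len(alphabet))
        for m in p.mutations:
            if m.category is None:
                raise ValueError(
                    f"mutation {m.mutation_id!r} of patient {p.patient_id!r} "
                    "has no category; restrict the cohort to a pair first"
                )
            e[index[m.category]] += 1.0 - m.functional_score
        expected[p.patient_id] = e
    total = np.sum(list(expected.values()), axis=0) if expected else np.zeros(len(alphabet))
    denom = total.sum()
    if denom <= 0:
        warnings.warn(
            "all functional scores are 1: background distribution q is "
            "undefined, falling back to uniform",
            stacklevel=2,
        )
        q = np.full(len(alphabet), 1.0 / len(alphabet))
    else:
        q = total / denom
    return BackgroundDist(alphabet=alphabet, q=q, expected_counts=expected)


# ---------------------------------------------------------------------------
# Per-patient monomial summaries
# ---------------------------------------------------------------------------


def iter_splits(scores: Sequence[float]) -> Iterable[FunctionalSplit]:
    """Enumerate all 2^c functional splits with their prior weights."""
    c = len(scores)
    for mask in range(1 << c):
        w = 1.0
        nf = 0
        for k in range(c):
            if mask >> k & 1:
                w *= scores[k]
                nf += 1
            else:
                w *= 1.0 - scores[k]
            if w == 0.0:
                break
        if w > 0.0:
            yield FunctionalSplit(mask=mask, weight=w, n_functional=nf)


def _mc_splits(
    scores: np.ndarray, draws: int, rng: np.random.Generator
) -> Iterable[FunctionalSplit]:
    """Monte Carlo splits S ~ prod Bernoulli(r_k), deduplicated with weights."""
    c = len(scores)
    bits = rng.random((draws, c)) < scores[None, :]
    counter: dict[int, int] = {}
    for row in bits:
        mask = 0
        for i in np.nonzero(row)[0]:
            mask |= 1 << int(i)
        counter[mask] = counter.get(mask, 0) + 1
    for mask in sorted(counter):
        yield FunctionalSplit(
            mask=mask, weight=counter[mask] / draws, n_functional=bin(mask).count("1")
        )


def _subset_constant_dp(members: list[int], pred: list[int], w: np.ndarray, cats: list[int]) -> float:
    """Extension-weighted sum with position-independent weights, on a sub-poset."""
    if not members:
        return 1.0
    full = 0
    for i in members:
        full |= 1 << i
    level = {0: 1.0}
    for _ in range(len(members)):
        nxt: dict[int, float] = {}
        for mask, val in level.items():
            for i in members:
                bit = 1 << i
                if not mask & bit and pred[i] & full & ~mask == 0:
                    wi = w[cats[i]]
                    if wi != 0.0:
                        key = mask | bit
                        nxt[key] = nxt.get(key, 0.0) + val * wi
        level = nxt
        if not level:
            return 0.0
    return level[full]


def _signature_counts(
    members: list[int], pred: list[int], cats: list[int], k0: int, n_cat: int
) -> dict[tuple[tuple[int, ...], tuple[int, ...]], float]:
    """Count linear extensions of a sub-poset grouped by monomial signature.

    The signature of an extension is (categories of the first min(n, k0-1)
    elements, category counts of the remaining positions, which all use the
    tied row k0). Extensions sharing a signature contribute the same monomial
    in P, so only their count matters.
    """
    n = len(members)
    plen = k0 - 1
    full = 0
    total_counts = [0] * n_cat
    for i in members:
        full |= 1 << i
        total_counts[cats[i]] += 1
    if n == 0:
        return {((), tuple(total_counts)): 1.0}
    states: dict[tuple[int, tuple[int, ...]], float] = {(0, ()): 1.0}
    for pos in range(1, n + 1):
        nxt: dict[tuple[int, tuple[int, ...]], float] = {}
        for (mask, prefix), cnt in states.items():
            for i in members:
                bit = 1 << i
                if not mask & bit and pred[i] & full & ~mask == 0:
                    np_prefix = prefix + (cats[i],) if pos <= plen else prefix
                    key = (mask | bit, np_prefix)
                    nxt[key] = nxt.get(key, 0.0) + cnt
        states = nxt
    out: dict[tuple[tuple[int, ...], tuple[int, ...]], float] = {}
    for (mask, prefix), cnt in states.items():
        tail = list(total_counts)
        for cat in prefix:
            tail[cat] -= 1
        key = (prefix, tuple(tail))
        out[key] = out.get(key, 0.0) + cnt
    return out


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(patient_id.encode("utf-8"))])
    )


def _patient_signature_coefs(
    patient: PatientSample,
    posets: Sequence[ReducedPoset],
    q: np.ndarray,
    alphabet: Sequence[str],
    cfg: FitConfig,
) -> dict[tuple[tuple[int, ...], tuple[int, ...]], float]:
    """Summarize one patient's likelihood as monomial coefficients in P."""
    index = {label: i for i, label in enumerate(alphabet)}
    by_id = patient.mutation_by_id()
    coefs: dict[tuple[tuple[int, ...], tuple[int, ...]], float] = {}
    if not posets:
        posets = [
            ReducedPoset(
                elements=tuple(sorted(patient.mutation_ids)),
                precedes=frozenset(),
                posterior=1.0,
            )
        ]
    for poset in posets:
        missing = set(poset.elements) - set(by_id)
        if missing:
            raise ValueError(
                f"poset elements {sorted(missing)} not among patient "
                f"{patient.patient_id!r} mutations"
            )
        elems = poset.elements
        c = len(elems)
        cats = []
        for e in elems:
            m = by_id[e]
            if m.category is None:
                raise ValueError(f"mutation {e!r} has no category")
            cats.append(index[m.category])
        scores = np.array([by_id[e].functional_score for e in elems])
        pred = poset.predecessor_masks()
        if c <= cfg.c_max:
            splits: Iterable[FunctionalSplit] = iter_splits(scores)
        else:
            rng = _patient_rng(cfg.seed, patient.patient_id)
            splits = _mc_splits(scores, cfg.mc_draws, rng)
        for split in splits:
            func = [i for i in range(c) if split.mask >> i & 1]
            nonf = [i for i in range(c) if not split.mask >> i & 1]
            nf_val = _subset_constant_dp(nonf, pred, q, cats)
            if nf_val == 0.0:
                continue
            base = poset.posterior * split.weight * nf_val
            for sig, count in _signature_counts(func, pred, cats, cfg.k0, len(alphabet)).items():
                coefs[sig] = coefs.get(sig, 0.0) + base * count
    return coefs


@dataclass(eq=False)
class _CohortTerms:
    """Stacked monomial coefficients for fast vectorized likelihood."""

    prefix: np.ndarray  # (R, k0-1) int, -1 padded
    tail: np.ndarray  # (R, N) int
    coef: np.ndarray  # (R,)
    pidx: np.ndarray  # (R,) patient index
    n_patients: int  # number of contributing patients

    def loglik(self, rows: np.ndarray) -> float:
        if self.n_patients == 0:
            return 0.0
        w = self.coef.copy()
        for k in range(self.prefix.shape[1]):
            idx = self.prefix[:, k]
            valid = idx >= 0
            w[valid] *= rows[k, idx[valid]]
        if self.tail.size:
            w *= np.prod(rows[-1][None, :] ** self.tail, axis=1)
        vals = np.bincount(self.pidx, weights=w, minlength=self.n_patients)
        with np.errstate(divide="ignore"):
            return float(np.log(vals).sum())


def _build_terms(
    patients: Sequence[PatientSample],
    posets_list: Sequence[Sequence[ReducedPoset]],
    q: np.ndarray,
    alphabet: Sequence[str],
    cfg: FitConfig,
) -> _CohortTerms:
    plen = cfg.k0 - 1
    n_cat = len(alphabet)
    prefix_rows: list[list[int]] = []
    tail_rows: list[tuple[int, ...]] = []
    coefs: list[float] = []
    pidx: list[int] = []
    n_used = 0
    for patient, posets in zip(patients, posets_list):
        sig_coefs = _patient_signature_coefs(patient, posets, q, alphabet, cfg)
        if not sig_coefs:
            # zero-likelihood patient: keep a zero row so log -> -inf honestly
            sig_coefs = {((), (0,) * n_cat): 0.0}
        if patient.c == 0:
            # unit factor, nothing to add
            continue
        for (prefix, tail), coef in sorted(sig_coefs.items()):
            prefix_rows.append(list(prefix) + [-1] * (plen - len(prefix)))
            tail_rows.append(tail)
            coefs.append(coef)
            pidx.append(n_used)
        n_used += 1
    return _CohortTerms(
        prefix=np.array(prefix_rows, dtype=int).reshape(len(coefs), plen),
        tail=np.array(tail_rows, dtype=int).reshape(len(coefs), n_cat),
        coef=np.array(coefs, dtype=float),
        pidx=np.array(pidx, dtype=int),
        n_patients=n_used,
    )


def _default_alphabet(patients: Sequence[PatientSample]) -> tuple[str, ...]:
    seen = {m.category for p in patients for m in p.mutations if m.category}
    ordered = [label for label in CATEGORY_ORDER if label in seen]
    ordered += sorted(seen - set(CATEGORY_ORDER))
    return tuple(ordered)


# ---------------------------------------------------------------------------
# Likelihood API
# ---------------------------------------------------------------------------


def patient_log_likelihood(
    patient: PatientSample,
    posets: Sequence[ReducedPoset],
    P: PivotalMatrix,
    q: BackgroundDist,
    cfg: FitConfig | None = None,
) -> float:
    """Log-likelihood of one pair-restricted patient given P and q.

    ``posets`` are the patient's reduced, merged, truncated tree posets. For
    c_j <= cfg.c_max the 2^{c_j} latent functional splits are enumerated
    exactly; beyond that the split sum is a seeded Monte Carlo average.
    """
    cfg = cfg or FitConfig()
    terms = _build_terms([patient], [posets], q.q, P.alphabet, cfg)
    return terms.loglik(P.rows)


def cohort_log_likelihood(
    cohort: Sequence[PatientSample],
    P: PivotalMatrix,
    q: BackgroundDist,
    cfg: FitConfig | None = None,
) -> float:
    """Sum of patient log-likelihoods; empty patients contribute 0."""
    cfg = cfg or FitConfig()
    posets_list = [patient_posets(p, threshold=cfg.truncation) for p in cohort]
    terms = _build_terms(cohort, posets_list, q.q, P.alphabet, cfg)
    return terms.loglik(P.rows)


# ---------------------------------------------------------------------------
# Entropy-constrained maximum likelihood
# ---------------------------------------------------------------------------


def _softmax_rows(x: np.ndarray, k0: int, n_cat: int) -> np.ndarray:
    logits = np.concatenate([x.reshape(k0, n_cat - 1), np.zeros((k0, 1))], axis=1)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _row_entropies(rows: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rows > 0, -rows * np.log(rows), 0.0)
    return terms.sum(axis=1)


def fit_P(
    cohort: Sequence[PatientSample],
    q: BackgroundDist,
    cfg: FitConfig | None = None,
    alphabet: Sequence[str] | None = None,
    posets_list: Sequence[Sequence[ReducedPoset]] | None = None,
) -> tuple[PivotalMatrix, dict]:
    """Entropy-constrained MLE of the pivotal matrix on a pair-restricted cohort.

    Rows are parameterized by softmax logits (smooth bijection onto the open
    simplex); the strict entropy ordering H(row k) < H(row k+1) is enforced
    as H(k+1) - H(k) >= entropy_margin by SLSQP. Multi-start from tilted /
    perturbed-uniform initials; the best feasible solution is returned along
    with diagnostics (per-start log-likelihoods, entropies, slack, seed).
    """
    cfg = cfg or FitConfig()
    if alphabet is None:
        alphabet = _default_alphabet(cohort)
    alphabet = tuple(alphabet)
    n_cat = len(alphabet)
    if n_cat == 0:
        raise ValueError("cohort has no categorized mutations")
    if posets_list is None:
        posets_list = [patient_posets(p, threshold=cfg.truncation) for p in cohort]
    terms = _build_terms(cohort, posets_list, q.q, alphabet, cfg)
    if terms.n_patients == 0:
        raise ValueError("no non-empty patient in cohort")
    k0 = cfg.k0
    uniform = PivotalMatrix.uniform(alphabet, k0)
    uniform_ll = terms.loglik(uniform.rows)

    if n_cat == 1:
        diagnostics = {
            "trivial": True,
            "loglik": uniform_ll,
            "uniform_loglik": uniform_ll,
            "per_start_loglik": [],
            "entropies": [0.0] * k0,
            "constraint_slack": [],
            "seed": cfg.seed,
            "alphabet": list(alphabet),
            "config": dataclasses.asdict(cfg),
        }
        return uniform, diagnostics

    margin = cfg.entropy_margin

    def rows_of(x: np.ndarray) -> np.ndarray:
        return _softmax_rows(x, k0, n_cat)

    def neg_ll(x: np.ndarray) -> float:
        return -terms.loglik(rows_of(x))

    constraints = []
    for k in range(k0 - 1):
        constraints.append(
            {
                "type": "ineq",
                "fun": (lambda x, k=k: _row_entropies(rows_of(x))[k + 1]
                        - _row_entropies(rows_of(x))[k] - margin),
            }
        )

    # deterministic tilted starts (entropy strictly increasing) + seeded jitter
    rng = np.random.default_rng(cfg.seed)
    base = np.zeros((k0, n_cat - 1))
    for k in range(k0):
        base[k, 0] = 0.6 * (k0 - k) / k0
    starts = [base.ravel(), (2.5 * base).ravel()]
    while len(starts) < cfg.restarts:
        starts.append(base.ravel() + rng.normal(0.0, 0.5, size=base.size))
    starts = starts[: max(cfg.restarts, 1)]

    results = []
    for x0 in starts:
        res = minimize(
            neg_ll,
            x0,
            method="SLSQP",
            constraints=constraints,
            options={"maxiter": cfg.max_iter, "ftol": cfg.tol},
        )
        rows = rows_of(res.x)
        ent = _row_entropies(rows)
        violation = max(
            [ent[k] - ent[k + 1] + margin for k in range(k0 - 1)], default=0.0
        )
        results.append(
            {
                "loglik": -float(res.fun),
                "success": bool(res.success),
                "violation": float(max(violation, 0.0)),
                "rows": rows,
            }
        )

    feas_tol = 1e-7
    feasible = [r for r in results if r["violation"] <= feas_tol and np.isfinite(r["loglik"])]
    diagnostics = {
        "per_start_loglik": [r["loglik"] for r in results],
        "per_start_success": [r["success"] for r in results],
        "per_start_violation": [r["violation"] for r in results],
        "uniform_loglik": uniform_ll,
        "seed": cfg.seed,
        "alphabet": list(alphabet),
        "config": dataclasses.asdict(cfg),
    }
    if not feasible:
        raise FitError(
            "constrained optimizer failed to produce a feasible solution "
            f"in {len(results)} starts",
            diagnostics,
        )
    best = max(feasible, key=lambda r: r["loglik"])
    rows = np.clip(best["rows"], 0.0, 1.0)
    rows /= rows.sum(axis=1, keepdims=True)
    P = PivotalMatrix(alphabet=alphabet, rows=rows)
    ent = _row_entropies(rows)
    diagnostics.update(
        {
            "loglik": best["loglik"],
            "best_start": results.index(best),
            "entropies": ent.tolist(),
            "constraint_slack": [float(ent[k + 1] - ent[k]) for k in range(k0 - 1)],
        }
    )
    return P, diagnostics


# ---------------------------------------------------------------------------
# Pairwise order probabilities
# ---------------------------------------------------------------------------


def pair_order_probabilities(P: PivotalMatrix, c: int) -> PairOrderResult:
    """First-passage probabilities of one pathway preceding the other.

    Over category sequences of length ``c`` with step-k distribution row k of
    P, the first event in any pair-relevant category decides: A-only means A
    before B, B-only means B before A, and a shared A∩B event is a tie. If no
    pair-relevant event occurs within c steps, the pair is tied (censored).
    Computed by recursion on the undecided mass, no enumeration.
    """
    if c < 1:
        raise ValueError("sequence length c must be >= 1")
    idx = {label: i for i, label in enumerate(P.alphabet)}
    relevant = {label: idx[label] for label in (A_ONLY, B_ONLY, AB_SHARED) if label in idx}
    p_a = p_b = tie_shared = 0.0
    undecided = 1.0
    for k in range(1, c + 1):
        row = P.row(k)
        step_a = row[relevant[A_ONLY]] if A_ONLY in relevant else 0.0
        step_b = row[relevant[B_ONLY]] if B_ONLY in relevant else 0.0
        step_s = row[relevant[AB_SHARED]] if AB_SHARED in relevant else 0.0
        p_a += undecided * step_a
        p_b += undecided * step_b
        tie_shared += undecided * step_s
        # fsum is permutation-invariant, keeping A/B label swap an exact symmetry
        undecided *= max(1.0 - math.fsum((step_a, step_b, step_s)), 0.0)
    return PairOrderResult(
        p_a_before_b=float(p_a),
        p_b_before_a=float(p_b),
        p_tie=float(tie_shared + undecided),
        c=c,
        tie_shared=float(tie_shared),
        tie_censored=float(undecided),
    )


# ---------------------------------------------------------------------------
# Pairwise pipeline
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class PairAnalysis:
    """Everything produced by one pairwise analysis."""

    pair: tuple[str, str]
    categories: PairCategories
    result: PairOrderResult
    pivotal: PivotalMatrix
    background: BackgroundDist
    diagnostics: dict
    n_patients_used: int
    c: int


def analyze_pair(
    cohort: Sequence[PatientSample],
    catalog: PathwayCatalog,
    pathway_a: str,
    pathway_b: str,
    cfg: FitConfig | None = None,
) -> PairAnalysis:
    """Full pairwise analysis: restrict, reduce trees, estimate q, fit P, order.

    If no patient carries any pair mutation the result is flagged
    uninformative with tie probability 1.
    """
    cfg = cfg or FitConfig()
    categories = make_pair_categories(catalog, pathway_a, pathway_b)
    restricted = [restrict_patient_to_pair(p, categories) for p in cohort]
    alphabet = categories.labels
    c = max((p.c for p in restricted), default=0)
    if c == 0:
        logger.warning(
            "pair (%s, %s): no patient has any pair mutation; result is uninformative",
            pathway_a,
            pathway_b,
        )
        uniform = PivotalMatrix.uniform(alphabet, cfg.k0)
        background = BackgroundDist(
            alphabet=alphabet, q=np.full(len(alphabet), 1.0 / len(alphabet))
        )
        result = PairOrderResult(
            p_a_before_b=0.0, p_b_before_a=0.0, p_tie=1.0, c=0, tie_censored=1.0,
            uninformative=True,
        )
        return PairAnalysis(
            pair=(pathway_a, pathway_b),
            categories=categories,
            result=result,
            pivotal=uniform,
            background=background,
            diagnostics={"uninformative": True, "config": dataclasses.asdict(cfg)},
            n_patients_used=0,
            c=0,
        )
    posets_list = [patient_posets(p, threshold=cfg.truncation) for p in restricted]
    background = estimate_q(restricted, alphabet)
    pivotal, diagnostics = fit_P(
        restricted, background, cfg, alphabet=alphabet, posets_list=posets_list
    )
    result = pair_order_probabilities(pivotal, c)
    return PairAnalysis(
        pair=(pathway_a, pathway_b),
        categories=categories,
        result=result,
        pivotal=pivotal,
        background=background,
        diagnostics=diagnostics,
        n_patients_used=sum(1 for p in restricted if p.c > 0),
        c=c,
    )
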