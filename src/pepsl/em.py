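"""Noisy-OR EM estimation of cluster-pair genetic-interaction probabilities.

Observed data are protein-pair synthetic-lethal labels L_mn and each
protein's cluster content C(m); hidden data are the per-occurrence
cluster-pair interactions C_ij.  Two proteins interact iff at least one of
their cluster pairs interacts, so

    Pr(L_mn = 1) = 1 - prod_{i in C(m), j in C(n)} (1 - Pr(C_ij = 1)).

EM alternates: the E-step distributes each observed interaction over its
cluster pairs with posterior r_ij = p_ij / Pr(L_mn = 1), accumulating
expected interacting counts M_ij = sum r and non-interacting counts
N_ij = sum (1 - r) over the observed interacting pairs; the fixed K_ij
counts the non-interacting protein pairs containing the cluster pair.  The
M-step re-estimates with symmetric pseudocounts a, b:

    p_ij = (M_ij + a) / (M_ij + N_ij + K_ij + a + b).

Convergence is monitored on the log of the complete-data likelihood
prod_ij p_ij^(M_ij + a) (1 - p_ij)^(N_ij + K_ij + b), evaluated after each
M-step (the raw product underflows; the log is the equivalent stopping rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "InteractionSet",
    "EMState",
    "PredictionResult",
    "canonical_pair",
    "enumerate_cluster_pairs",
    "count_K",
    "init_em",
    "e_step",
    "m_step",
    "run_em",
    "predict_pair",
    "rank_predictions",
    "roc_auc",
]

logger = logging.getLogger(__name__)

Pair = tuple[str, str]
Assignment = Mapping[str, frozenset[str] | set[str]]


def canonical_pair(a: str, b: str) -> Pair:
    """Unordered pair stored in lexicographic order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionSet:
    """Labeled unordered protein pairs: SLGI positives, optional negatives."""

    positives: frozenset[Pair]
    negatives: frozenset[Pair] | None = None

    def __post_init__(self) -> None:
        for pair in self.positives:
            if pair[0] == pair[1]:
                raise ValueError(f"self-pair {pair} in positives")
            if pair != canonical_pair(*pair):
                raise ValueError(f"pair {pair} not canonically ordered")
        if self.negatives is not None:
            for pair in self.negatives:
                if pair[0] == pair[1]:
                    raise ValueError(f"self-pair {pair} in negatives")
                if pair != canonical_pair(*pair):
                    raise ValueError(f"pair {pair} not canonically ordered")
            both = self.positives & self.negatives
            if both:
                raise ValueError(f"pairs labeled both positive and negative: {sorted(both)[:3]}")

    @classmethod
    def from_pairs(
        cls,
        positives: Iterable[tuple[str, str]],
        negatives: Iterable[tuple[str, str]] | None = None,
    ) -> "InteractionSet":
        pos = frozenset(canonical_pair(a, b) for a, b in positives)
        neg = (
            frozenset(canonical_pair(a, b) for a, b in negatives)
            if negatives is not None
            else None
        )
        return cls(pos, neg)


def enumerate_cluster_pairs(m: str, n: str, assignment: Assignment) -> set[Pair]:
    """Unordered cluster pairs {i, j} with i in C(m), j in C(n).

    Self-pairs {i, i} appear when cluster i occurs in both proteins.  A
    protein absent from the assignment contributes the empty set.
    """
    if m == n:
        raise ValueError("cluster pairs are defined for distinct proteins")
    cm = assignment.get(m, frozenset())
    cn = assignment.get(n, frozenset())
    return {canonical_pair(i, j) for i in cm for j in cn}


def count_K(
    assignment: Assignment,
    positives: frozenset[Pair],
    universe: Sequence[str] | None = None,
) -> dict[Pair, int]:
    """Fixed counts K_ij of non-interacting protein pairs per cluster pair.

    K_ij counts the unordered protein pairs of the universe that are *not*
    known SLGIs and contain cluster i in one protein and j in the other.  The
    universe defaults to all proteins carrying at least one cluster.
    """
    prots = sorted(universe) if universe is not None else sorted(assignment)
    K: dict[Pair, int] = {}
    for a in range(len(prots)):
        for b in range(a + 1, len(prots)):
            pp = canonical_pair(prots[a], prots[b])
            if pp in positives:
                continue
            for cp in enumerate_cluster_pairs(pp[0], pp[1], assignment):
                K[cp] = K.get(cp, 0) + 1
    return K


@dataclass
class EMState:
    """Trained (or in-training) cluster-pair probability table.

    ``keys`` fixes a canonical order of cluster pairs; M/N/K/p are aligned
    arrays.  ``loglik`` is the monitored complete-data log-likelihood.
    """

    keys: list[Pair]
    M: np.ndarray
    N: np.ndarray
    K: np.ndarray
    p: np.ndarray
    a: float = 1.0
    b: float = 1.0
    loglik: float = float("-inf")
    loglik_history: list[float] = field(default_factory=list)
    iteration: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.index = {k: i for i, k in enumerate(self.keys)}

    def prob(self, pair: Pair) -> float:
        """Pr(C_ij = 1); cluster pairs never seen in training fall back to the
        pure-pseudocount estimate a / (a + b)."""
        i = self.index.get(pair)
        if i is None:
            return self.a / (self.a + self.b)
        return float(self.p[i])

    def table(self) -> dict[Pair, dict[str, float]]:
        return {
            k: {
                "M": float(self.M[i]),
                "N": float(self.N[i]),
                "K": float(self.K[i]),
                "p": float(self.p[i]),
            }
            for i, k in enumerate(self.keys)
        }


def init_em(
    positives: frozenset[Pair],
    assignment: Assignment,
    K_table: Mapping[Pair, int],
    a: float = 1.0,
    b: float = 1.0,
) -> EMState:
    """Initial state: M_ij = #positives containing {i,j}, N_ij = 0 and
    p_ij = M / (M + N + K)."""
    M_counts: dict[Pair, int] = {}
    scorable = 0
    for (m, n) in sorted(positives):
        cps = enumerate_cluster_pairs(m, n, assignment)
        if cps:
            scorable += 1
        for cp in cps:
            M_counts[cp] = M_counts.get(cp, 0) + 1
    if scorable == 0:
        raise ValueError("no positive pair carries any cluster pair")
    keys = sorted(set(M_counts) | set(K_table))
    M = np.array([float(M_counts.get(k, 0)) for k in keys])
    K = np.array([float(K_table.get(k, 0)) for k in keys])
    N = np.zeros(len(keys))
    denom = M + N + K
    with np.errstate(invalid="ignore"):
        p = np.where(denom > 0, M / np.where(denom > 0, denom, 1.0), 0.0)
    return EMState(keys=keys, M=M, N=N, K=K, p=p, a=a, b=b)


def _build_design(
    positives: frozenset[Pair], assignment: Assignment, index: Mapping[Pair, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Flattened cluster-pair indices of every positive pair.

    Returns ``(flat, starts)`` where ``flat`` concatenates, positive pair by
    positive pair (sorted), the table indices of its cluster pairs, and
    ``starts`` marks each pair's first slot (for segmented reductions).
    Cluster pairs absent from the table behave as p = 0 and are skipped.
    """
    flat: list[int] = []
    starts: list[int] = []
    for (m, n) in sorted(positives):
        idx = sorted(
            index[cp]
            for cp in enumerate_cluster_pairs(m, n, assignment)
            if cp in index
        )
        if idx:
            starts.append(len(flat))
            flat.extend(idx)
    return np.asarray(flat, dtype=np.int64), np.asarray(starts, dtype=np.int64)


def _estep_kernel(
    p: np.ndarray, flat: np.ndarray, starts: np.ndarray, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Expected counts (M_hat, N_hat) over the observed interacting pairs."""
    if len(flat) == 0:
        return np.zeros(size), np.zeros(size)
    one_minus = 1.0 - p[flat]
    prods = np.multiply.reduceat(one_minus, starts)
    pr_l = 1.0 - prods  # Pr(L_mn = 1) per positive pair
    seg = np.zeros(len(flat), dtype=np.int64)
    seg[starts[1:]] = 1
    seg = np.cumsum(seg)
    pr_per_slot = pr_l[seg]
    ok = pr_per_slot > 0.0
    n_dead = int((~(pr_l > 0)).sum())
    if n_dead:
        logger.warning("%d positive pairs have Pr(L=1)=0 and contribute nothing", n_dead)
    r = np.zeros(len(flat))
    r[ok] = p[flat[ok]] / pr_per_slot[ok]
    M_hat = np.bincount(flat, weights=r, minlength=size)
    N_hat = np.bincount(flat[ok], weights=1.0 - r[ok], minlength=size)
    return M_hat, N_hat


def e_step(
    state: EMState, positives: frozenset[Pair], assignment: Assignment
) -> tuple[dict[Pair, float], dict[Pair, float]]:
    """One E-step: expected M_ij and N_ij under the current probabilities."""
    flat, starts = _build_design(positives, assignment, state.index)
    M_hat, N_hat = _estep_kernel(state.p, flat, starts, len(state.keys))
    return (
        {k: float(M_hat[i]) for i, k in enumerate(state.keys)},
        {k: float(N_hat[i]) for i, k in enumerate(state.keys)},
    )


def m_step(
    M_hat: Mapping[Pair, float],
    N_hat: Mapping[Pair, float],
    K_table: Mapping[Pair, int],
    a: float = 1.0,
    b: float = 1.0,
) -> dict[Pair, float]:
    """One M-step: p_ij = (M + a) / (M + N + K + a + b)."""
    out: dict[Pair, float] = {}
    for k in set(M_hat) | set(N_hat) | set(K_table):
        m = float(M_hat.get(k, 0.0))
        n = float(N_hat.get(k, 0.0))
        kk = float(K_table.get(k, 0))
        out[k] = (m + a) / (m + n + kk + a + b)
    return out


def _loglik(M: np.ndarray, N: np.ndarray, K: np.ndarray, p: np.ndarray, a: float, b: float) -> float:
    return float(np.sum((M + a) * np.log(p) + (N + K + b) * np.log1p(-p)))


def run_em(
    positives: frozenset[Pair] | InteractionSet,
    assignment: Assignment,
    K_table: Mapping[Pair, int],
    tol: float = 1e-6,
    max_iter: int = 500,
    a: float = 1.0,
    b: float = 1.0,
) -> EMState:
    """Run EM to convergence of the monitored log-likelihood.

    Stops when the absolute change between successive monitored values drops
    below ``tol`` or after ``max_iter`` iterations.  Deterministic: cluster
    pairs and protein pairs are processed in canonical sorted order.
    """
    if isinstance(positives, InteractionSet):
        positives = positives.positives
    state = init_em(positives, assignment, K_table, a=a, b=b)
    flat, starts = _build_design(positives, assignment, state.index)
    size = len(state.keys)
    prev_ll = None
    for it in range(1, max_iter + 1):
        M_hat, N_hat = _estep_kernel(state.p, flat, starts, size)
        p_new = (M_hat + a) / (M_hat + N_hat + state.K + a + b)
        ll = _loglik(M_hat, N_hat, state.K, p_new, a, b)
        state.M, state.N, state.p = M_hat, N_hat, p_new
        state.loglik = ll
        state.loglik_history.append(ll)
        state.iteration = it
        if prev_ll is not None and abs(ll - prev_ll) < tol:
            state.converged = True
            break
        prev_ll = ll
    return state


def predict_pair(
    m: str, n: str, state: EMState, assignment: Assignment
) -> float | None:
    """Noisy-OR protein-pair interaction probability, or None if unscorable.

    A pair with no cluster pair between its proteins carries no information
    and is reported unscorable rather than assigned probability 0.
    """
    cps = enumerate_cluster_pairs(m, n, assignment)
    if not cps:
        return None
    prod = 1.0
    for cp in cps:
        prod *= 1.0 - state.prob(cp)
    return 1.0 - prod


@dataclass(frozen=True)
class PredictionResult:
    """Scored candidate protein pairs."""

    probabilities: dict[Pair, float]
    flagged: frozenset[Pair]
    unscorable: tuple[Pair, ...]


def rank_predictions(
    state: EMState,
    assignment: Assignment,
    candidate_pairs: Iterable[tuple[str, str]],
    threshold: float,
) -> PredictionResult:
    """Score all scorable candidates and flag those above the threshold."""
    probs: dict[Pair, float] = {}
    unscorable: list[Pair] = []
    for a, b in sorted(canonical_pair(x, y) for x, y in candidate_pairs):
        p = predict_pair(a, b, state, assignment)
        if p is None:
            unscorable.append((a, b))
        else:
            probs[(a, b)] = p
    flagged = frozenset(k for k, v in probs.items() if v > threshold)
    return PredictionResult(probs, flagged, tuple(unscorable))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney (midrank) area under the ROC curve."""
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))
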