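"""Extreme-value statistics for local-alignment scores and reciprocal pairs.

The population of Smith-Waterman scores between one peptide window and all
windows of other proteins follows a Gumbel (extreme value) distribution
F(x) = exp(-exp(-(x - mu)/beta)).  Method-of-moments estimates

    beta = sigma * sqrt(6) / pi,        mu = mean - 0.5772 * beta

convert to Karlin-Altschul parameters lambda = 1/beta and
K = exp(mu/beta) / (m*n), so the expected number of high-scoring segment
pairs above score S is E = K*m*n*exp(-lambda*S) and the p-value of seeing at
least one is P = 1 - exp(-E).

Each window gets its *own* fitted distribution and hence its own score
threshold; a window pair is emitted only when its score is significant under
both windows' thresholds (reciprocal significance).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .align import DEFAULT_GAP, SubstitutionMatrix, encode_catalog, sw_score_matrix
from .windows import PeptideWindow, WindowCatalog

__all__ = [
    "EVDParams",
    "KAParams",
    "SignificantPair",
    "EstimationError",
    "EULER_GAMMA",
    "fit_evd",
    "ka_from_evd",
    "evalue",
    "pvalue",
    "estar_from_pvalue",
    "score_threshold",
    "catalog_score_matrix",
    "find_significant_pairs",
]

logger = logging.getLogger(__name__)

#: Euler-Mascheroni constant as used in the location estimate
EULER_GAMMA = 0.5772

DEFAULT_P_THRESHOLD = 1e-6


class EstimationError(ValueError):
    """Raised when a score population cannot support a distribution fit."""


@dataclass(frozen=True)
class EVDParams:
    """Gumbel location/scale in alignment-score units."""

    mu: float
    beta: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be > 0")


@dataclass(frozen=True)
class KAParams:
    """Karlin-Altschul parameters for sequences of lengths m and n."""

    K: float
    lam: float
    m: int
    n: int

    def __post_init__(self) -> None:
        if not (self.K > 0 and self.lam > 0):
            raise ValueError("K and lambda must be > 0")
        if self.m < 1 or self.n < 1:
            raise ValueError("sequence lengths must be >= 1")


def fit_evd(scores: Iterable[float]) -> EVDParams:
    """Method-of-moments Gumbel fit from a score population.

    Uses the sample mean and the n-1 (sample) standard deviation.  Requires
    at least two scores with nonzero spread.
    """
    x = np.asarray(list(scores), dtype=float)
    if x.size < 2:
        raise EstimationError("need at least 2 scores to fit an EVD")
    sigma = float(x.std(ddof=1))
    if sigma == 0.0:
        raise EstimationError("score population has zero variance")
    beta = sigma * math.sqrt(6.0) / math.pi
    mu = float(x.mean()) - EULER_GAMMA * beta
    return EVDParams(mu=mu, beta=beta)


def ka_from_evd(evd: EVDParams, m: int, n: int) -> KAParams:
    """Convert Gumbel parameters to Karlin-Altschul K and lambda."""
    lam = 1.0 / evd.beta
    K = math.exp(evd.mu / evd.beta) / (m * n)
    return KAParams(K=K, lam=lam, m=m, n=n)


def evalue(S: float, ka: KAParams) -> float:
    """Expected number of HSPs scoring above S: E = K*m*n*exp(-lambda*S)."""
    return ka.K * ka.m * ka.n * math.exp(-ka.lam * S)


def pvalue(E: float) -> float:
    """Probability of at least one HSP above threshold: P = 1 - exp(-E)."""
    if E < 0:
        raise ValueError("E must be >= 0")
    return -math.expm1(-E)


def estar_from_pvalue(p: float) -> float:
    """Exact inversion of P = 1 - exp(-E): E* = -ln(1 - p)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    return -math.log1p(-p)


def score_threshold(p_threshold: float, ka: KAParams) -> float:
    """Smallest score S_min whose p-value does not exceed ``p_threshold``.

    A score S is significant iff S >= S_min.  Note that because
    K = exp(mu/beta)/(m*n), the product m*n cancels and
    S_min = mu - beta*ln(E*).
    """
    estar = estar_from_pvalue(p_threshold)
    return math.log(ka.K * ka.m * ka.n / estar) / ka.lam


@dataclass(frozen=True)
class SignificantPair:
    """A reciprocally significant peptide-window pair.

    ``window_a`` precedes ``window_b`` in the canonical (protein_id, start)
    order; ``pvalue_a``/``pvalue_b`` are the match significances under each
    window's own fitted distribution.
    """

    window_a: PeptideWindow
    window_b: PeptideWindow
    score: int
    pvalue_a: float
    pvalue_b: float

    def __post_init__(self) -> None:
        if self.window_a.protein_id == self.window_b.protein_id:
            raise ValueError("a significant pair must span two proteins")
        if self.window_a.key > self.window_b.key:
            raise ValueError("pair is not canonically ordered")


def catalog_score_matrix(
    catalog: WindowCatalog,
    matrix: SubstitutionMatrix,
    gap_penalty: int = DEFAULT_GAP,
) -> np.ndarray:
    """All-vs-all symmetric Smith-Waterman score matrix over the catalog."""
    codes, lengths = encode_catalog(catalog, matrix)
    return sw_score_matrix(codes, lengths, matrix, gap_penalty)


def _window_thresholds(
    S: np.ndarray,
    protein_of: Sequence[str],
    p_threshold: float,
) -> tuple[np.ndarray, list[EVDParams | None]]:
    """Per-window score thresholds from per-window cross-protein populations.

    Windows whose population cannot support a fit get an infinite threshold
    (they can never take part in a significant pair) and a logged warning.
    """
    n = S.shape[0]
    groups: dict[str, list[int]] = {}
    for i, pid in enumerate(protein_of):
        groups.setdefault(pid, []).append(i)
    Sf = S.astype(float)
    total = Sf.sum(axis=1)
    total_sq = (Sf**2).sum(axis=1)
    counts = np.full(n, n, dtype=float)
    for pid, idx in groups.items():
        ii = np.asarray(idx)
        block = Sf[np.ix_(ii, ii)]
        total[ii] -= block.sum(axis=1)
        total_sq[ii] -= (block**2).sum(axis=1)
        counts[ii] -= len(ii)
    thresholds = np.full(n, np.inf)
    params: list[EVDParams | None] = [None] * n
    estar = estar_from_pvalue(p_threshold)
    for i in range(n):
        c = counts[i]
        if c < 2:
            logger.warning("window %d: fewer than 2 cross-protein scores; skipped", i)
            continue
        mean = total[i] / c
        var = (total_sq[i] - c * mean**2) / (c - 1)
        if var <= 0:
            logger.warning("window %d: zero-variance score population; skipped", i)
            continue
        beta = math.sqrt(var) * math.sqrt(6.0) / math.pi
        mu = mean - EULER_GAMMA * beta
        params[i] = EVDParams(mu=mu, beta=beta)
        thresholds[i] = mu - beta * math.log(estar)
    return thresholds, params


def _reciprocal_pairs(
    S: np.ndarray, thresholds: np.ndarray, protein_of: Sequence[str]
) -> list[tuple[int, int]]:
    """Index pairs (i < j) from different proteins whose score meets both
    windows' thresholds."""
    need = np.maximum.outer(thresholds, thresholds)
    ok = S >= need
    ok &= np.triu(np.ones_like(ok, dtype=bool), k=1)
    pids = np.asarray(protein_of, dtype=object)
    ok &= pids[:, None] != pids[None, :]
    return [(int(i), int(j)) for i, j in np.argwhere(ok)]


def find_significant_pairs(
    catalog: WindowCatalog,
    matrix: SubstitutionMatrix,
    gap_penalty: int = DEFAULT_GAP,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[SignificantPair]:
    """All reciprocally significant cross-protein window pairs of a catalog.

    For every window an EVD is fitted to its complete population of scores
    against windows of other proteins, giving a per-window score threshold at
    ``p_threshold``; a pair is emitted iff its score meets both thresholds.
    """
    if len(catalog.index) < 2:
        return []
    S = catalog_score_matrix(catalog, matrix, gap_penalty)
    protein_of = [w.protein_id for w in catalog]
    thresholds, params = _window_thresholds(S, protein_of, p_threshold)
    out: list[SignificantPair] = []
    for i, j in _reciprocal_pairs(S, thresholds, protein_of):
        wa, wb = catalog[i], catalog[j]
        if wb.key < wa.key:
            wa, wb = wb, wa
            i, j = j, i
        ka_a = ka_from_evd(params[i], m=wa.length, n=wb.length)
        ka_b = ka_from_evd(params[j], m=wb.length, n=wa.length)
        s = int(S[i, j])
        out.append(
            SignificantPair(
                window_a=wa,
                window_b=wb,
                score=s,
                pvalue_a=pvalue(evalue(s, ka_a)),
                pvalue_b=pvalue(evalue(s, ka_b)),
            )
        )
    out.sort(key=lambda p: (p.window_a.key, p.window_b.key))
    return out
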