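"""Iterative profile-based clustering of short polypeptides.

Each reciprocally significant window pair seeds a cluster.  The cluster is
grown to a fixpoint: align the current members (progressive multiple
alignment under BLOSUM62 with a linear gap penalty), derive a
position-specific log-odds profile, search the whole window catalog with the
profile, and add every hit whose calibrated E-value passes the threshold.
Because membership only ever grows and is bounded by the catalog, the
iteration terminates.

Grown clusters are then post-processed: exact-duplicate member sets are
collapsed, overlapping clusters are merged under one of three rules (any
shared member / >=10% of the smaller cluster / >=20%), clusters with fewer
than three members are dropped, and optionally clusters spread over too many
proteins (promiscuous, hence uninformative) are dropped.  The surviving
clusters play the role of sequence features ("domains") for interaction
prediction.

Profile hit significance reuses the extreme-value machinery: for each profile
the population of best ungapped placement scores over the whole catalog is
fitted with a Gumbel distribution and converted to E-values with m = profile
length and n = window length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .align import DEFAULT_GAP, SubstitutionMatrix, load_substitution_matrix
from .significance import (
    EULER_GAMMA,
    EstimationError,
    SignificantPair,
    fit_evd,
)
from .windows import PeptideWindow, WindowCatalog

__all__ = [
    "ALPHABET20",
    "ProfileModel",
    "PeptideCluster",
    "build_profile",
    "profile_search",
    "grow_cluster",
    "cluster_all",
    "dedupe_clusters",
    "merge_clusters",
    "filter_clusters",
    "assign_clusters",
    "MERGE_RULES",
]

logger = logging.getLogger(__name__)

#: the 20 standard amino acids, alphabetical
ALPHABET20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(ALPHABET20)}

#: pseudocount added per residue type in profile columns
PSEUDOCOUNT = 1.0
#: uniform background frequency
BACKGROUND = 1.0 / 20.0
#: columns with more than this gap fraction are dropped from the profile
MAX_GAP_FRACTION = 0.5
#: safety cap on fixpoint iterations
MAX_GROW_ITERATIONS = 100

#: default E-value threshold for profile hits, calibrated for the internal
#: log-odds score scale (true members land around 1e-5..1e-8, background
#: stays above ~1e-3; external HMM-style thresholds do not transfer)
DEFAULT_PROFILE_EVALUE = 1e-5

MERGE_RULES = ("any", "frac10", "frac20")


@lru_cache(maxsize=1)
def _default_matrix() -> SubstitutionMatrix:
    return load_substitution_matrix("BLOSUM62")


# ---------------------------------------------------------------------------
# profile model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileModel:
    """Position-specific log-odds scores over the 20 standard residues.

    ``columns[p, r]`` scores residue ``ALPHABET20[r]`` at profile position
    ``p``; ``unseen[p]`` scores any symbol outside the 20-letter alphabet
    (the pseudocount-only log-odds for that column).
    """

    columns: np.ndarray  # (P, 20) float
    unseen: np.ndarray  # (P,) float

    def __post_init__(self) -> None:
        if self.columns.ndim != 2 or self.columns.shape[1] != 20:
            raise ValueError("profile columns must be (P, 20)")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("profile scores must be finite")

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    def score_table(self) -> np.ndarray:
        """(P, 21) table: the 20 residue scores plus the unseen-symbol score."""
        return np.hstack([self.columns, self.unseen[:, None]])

    def score_sequence(self, seq: str) -> float:
        """Best ungapped placement score of the profile against a sequence."""
        codes = encode20(seq)[None, :]
        return float(_placement_scores(self.score_table(), codes)[0])


def encode20(seq: str) -> np.ndarray:
    """Encode residues over the 20-letter alphabet; others get code 20."""
    return np.fromiter(
        (_AA_INDEX.get(c, 20) for c in seq.upper()), dtype=np.int64, count=len(seq)
    )


# ---------------------------------------------------------------------------
# multiple alignment (progressive, percent-identity guide)
# ---------------------------------------------------------------------------


def _identity(a: str, b: str) -> float:
    """Fraction of identical residues under the best ungapped offset."""
    if len(a) > len(b):
        a, b = b, a
    la, lb = len(a), len(b)
    best = 0
    for off in range(lb - la + 1):
        m = sum(1 for x, y in zip(a, b[off : off + la]) if x == y)
        if m > best:
            best = m
    return best / la if la else 0.0


def _overlap_dp(
    score_rows: np.ndarray, lb: int, gap: int
) -> tuple[np.ndarray, int, int]:
    """Shared DP for pairwise overlap alignment (free end gaps).

    ``score_rows[i]`` holds the substitution scores of position ``i`` of the
    first sequence/profile against every position of the second.  Returns the
    DP matrix and the best end cell on the bottom/right border (smallest
    (i, j) on ties).  Internal gaps cost ``gap`` per symbol; terminal
    overhangs are free, which is the right model for equal-length windows
    sampled at different phases of one motif.
    """
    la = score_rows.shape[0]
    H = np.zeros((la + 1, lb + 1))
    for i in range(1, la + 1):
        srow = score_rows[i - 1]
        for j in range(1, lb + 1):
            H[i, j] = max(
                H[i - 1, j - 1] + srow[j - 1], H[i - 1, j] - gap, H[i, j - 1] - gap
            )
    bi, bj, best = la, 0, H[la, 0]
    for j in range(lb + 1):
        if H[la, j] > best:
            bi, bj, best = la, j, H[la, j]
    for i in range(la + 1):
        if H[i, lb] > best:
            bi, bj, best = i, lb, H[i, lb]
    return H, bi, bj


def _nw_align(a: str, b: str, matrix: SubstitutionMatrix, gap: int) -> tuple[str, str]:
    """Pairwise overlap alignment (linear internal gaps, free end gaps)."""
    ext = matrix.extended_scores()
    ca, cb = matrix.encode(a), matrix.encode(b)
    la, lb = len(ca), len(cb)
    score_rows = ext[ca][:, cb].astype(float)
    H, bi, bj = _overlap_dp(score_rows, lb, gap)
    qa: list[str] = []
    sa: list[str] = []
    # trailing overhang
    for i in range(la, bi, -1):
        qa.append(a[i - 1]); sa.append("-")
    for j in range(lb, bj, -1):
        qa.append("-"); sa.append(b[j - 1])
    i, j = bi, bj
    while i > 0 and j > 0:
        if H[i, j] == H[i - 1, j - 1] + ext[ca[i - 1], cb[j - 1]]:
            qa.append(a[i - 1]); sa.append(b[j - 1]); i -= 1; j -= 1
        elif H[i, j] == H[i - 1, j] - gap:
            qa.append(a[i - 1]); sa.append("-"); i -= 1
        else:
            qa.append("-"); sa.append(b[j - 1]); j -= 1
    # leading overhang
    while i > 0:
        qa.append(a[i - 1]); sa.append("-"); i -= 1
    while j > 0:
        qa.append("-"); sa.append(b[j - 1]); j -= 1
    return "".join(reversed(qa)), "".join(reversed(sa))


def _column_profile_scores(
    rows: Sequence[str], matrix: SubstitutionMatrix
) -> np.ndarray:
    """(ncols, n_symbols) mean substitution score of each alignment column
    against each residue symbol; used to align a new sequence to the rows."""
    ext = matrix.extended_scores()
    ncols = len(rows[0])
    out = np.zeros((ncols, matrix.pad_code + 1))
    for c in range(ncols):
        codes = [matrix.encode(r[c])[0] for r in rows if r[c] != "-"]
        if codes:
            out[c] = ext[codes].mean(axis=0)
        else:
            out[c] = -float(DEFAULT_GAP)
    return out


def _align_seq_to_rows(
    rows: list[str], seq: str, matrix: SubstitutionMatrix, gap: int
) -> list[str]:
    """Align one sequence to an existing set of aligned rows (profile),
    overlap-style (free end gaps)."""
    col_scores = _column_profile_scores(rows, matrix)
    cs = matrix.encode(seq)
    nc, ls = col_scores.shape[0], len(cs)
    H, bi, bj = _overlap_dp(col_scores[:, cs], ls, gap)
    # traceback -> list of (column_index or None, seq_index or None)
    path: list[tuple[int | None, int | None]] = []
    for i in range(nc, bi, -1):
        path.append((i - 1, None))
    for j in range(ls, bj, -1):
        path.append((None, j - 1))
    i, j = bi, bj
    while i > 0 and j > 0:
        if H[i, j] == H[i - 1, j - 1] + col_scores[i - 1][cs[j - 1]]:
            path.append((i - 1, j - 1)); i -= 1; j -= 1
        elif H[i, j] == H[i - 1, j] - gap:
            path.append((i - 1, None)); i -= 1
        else:
            path.append((None, j - 1)); j -= 1
    while i > 0:
        path.append((i - 1, None)); i -= 1
    while j > 0:
        path.append((None, j - 1)); j -= 1
    path.reverse()
    new_rows = ["" for _ in rows]
    new_seq_row = []
    for col, sj in path:
        if col is None:  # insertion relative to the profile: gap every old row
            for k in range(len(rows)):
                new_rows[k] += "-"
        else:
            for k, r in enumerate(rows):
                new_rows[k] += r[col]
        new_seq_row.append(seq[sj] if sj is not None else "-")
    new_rows.append("".join(new_seq_row))
    return new_rows


def progressive_msa(
    sequences: Sequence[str],
    matrix: SubstitutionMatrix | None = None,
    gap_penalty: int = DEFAULT_GAP,
) -> list[str]:
    """Progressive multiple alignment guided by pairwise percent identity.

    Sequences are canonically sorted first, so the result depends only on the
    input multiset.  The closest pair is aligned first; remaining sequences
    join in order of mean identity to the aligned set, each aligned against
    the running column profile.
    """
    matrix = matrix or _default_matrix()
    seqs = sorted(sequences)
    if len(seqs) == 1:
        return list(seqs)
    n = len(seqs)
    ident = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = _identity(seqs[i], seqs[j])
    bi, bj = 0, 1
    for i in range(n):
        for j in range(i + 1, n):
            if ident[i, j] > ident[bi, bj]:
                bi, bj = i, j
    rows = list(_nw_align(seqs[bi], seqs[bj], matrix, gap_penalty))
    order = [bi, bj]
    remaining = [k for k in range(n) if k not in (bi, bj)]
    while remaining:
        means = [ident[k, order].mean() for k in remaining]
        k = remaining[int(np.argmax(means))]
        rows = _align_seq_to_rows(rows, seqs[k], matrix, gap_penalty)
        order.append(k)
        remaining.remove(k)
    return rows


# ---------------------------------------------------------------------------
# profile construction and search
# ---------------------------------------------------------------------------


def build_profile(
    member_sequences: Sequence[str],
    matrix: SubstitutionMatrix | None = None,
    gap_penalty: int = DEFAULT_GAP,
) -> ProfileModel:
    """Build a log-odds profile from cluster member sequences.

    Members are multiply aligned, then each retained column scores residue r
    as ``log(((count_r + 1) / (N + 20)) / (1/20))`` with N the number of
    residues observed in the column (pseudocount 1, uniform background).
    Columns that are mostly gaps (>50%) are dropped so the profile tracks the
    conserved core.
    """
    if len(member_sequences) < 2:
        raise ValueError("a profile needs at least 2 member sequences")
    rows = progressive_msa(member_sequences, matrix, gap_penalty)
    ncols = len(rows[0])
    nrows = len(rows)
    cols: list[np.ndarray] = []
    unseen: list[float] = []
    for c in range(ncols):
        residues = [r[c] for r in rows if r[c] != "-"]
        if (nrows - len(residues)) / nrows > MAX_GAP_FRACTION:
            continue
        counts = np.zeros(20)
        n_obs = len(residues)
        for ch in residues:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        denom = n_obs + 20.0 * PSEUDOCOUNT
        cols.append(np.log((counts + PSEUDOCOUNT) / denom / BACKGROUND))
        unseen.append(math.log(PSEUDOCOUNT / denom / BACKGROUND))
    return ProfileModel(columns=np.array(cols), unseen=np.array(unseen))


def _placement_scores(table: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Best ungapped placement score of a profile against each row of codes.

    ``table`` is the (P, 21) profile score table, ``codes`` an (N, n) code
    matrix of equal-length windows.  The profile slides along the window at
    every shift keeping at least half of the shorter side overlapping (only
    overlapping columns score), so windows holding a phase-shifted or
    truncated copy of the motif are still seen.
    """
    P = table.shape[0]
    N, n = codes.shape
    if N == 0:
        return np.zeros(0)
    min_ov = max(1, min(P, n) // 2)
    best = np.full(N, -np.inf)
    for o in range(min_ov - P, n - min_ov + 1):
        c0 = max(0, -o)
        c1 = min(P, n - o)
        cols = np.arange(c0, c1)
        s = table[cols, codes[:, o + c0 : o + c1]].sum(axis=1)
        np.maximum(best, s, out=best)
    return best


def _catalog_codes20(catalog: WindowCatalog) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Catalog windows encoded over the 20-letter alphabet, grouped by length.

    Returns {length: (window_indices, codes)}; cached on the catalog object.
    """
    cached = getattr(catalog, "_codes20", None)
    if cached is not None:
        return cached
    groups: dict[int, list[int]] = {}
    for i, w in enumerate(catalog):
        groups.setdefault(w.length, []).append(i)
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for length, idx in groups.items():
        codes = np.stack([encode20(catalog[i].sequence) for i in idx])
        out[length] = (np.asarray(idx), codes)
    catalog._codes20 = out  # type: ignore[attr-defined]
    return out


def profile_search(
    profile: ProfileModel,
    catalog: WindowCatalog,
    evalue_threshold: float,
) -> list[PeptideWindow]:
    """Windows of the catalog matching the profile at the given E-value.

    Every window is scored by its best ungapped profile placement; the score
    population over the whole catalog calibrates a Gumbel fit which converts
    scores to E-values with m = profile length and n = window length.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be > 0")
    if len(catalog) == 0:
        return []
    table = profile.score_table()
    scores = np.zeros(len(catalog))
    lengths = np.zeros(len(catalog), dtype=np.int64)
    for length, (idx, codes) in _catalog_codes20(catalog).items():
        scores[idx] = _placement_scores(table, codes)
        lengths[idx] = length
    evd = fit_evd(scores)  # raises EstimationError on degenerate populations
    lam = 1.0 / evd.beta
    n_ref = float(lengths.mean())
    K = math.exp(evd.mu / evd.beta) / (profile.length * n_ref)
    evalues = K * profile.length * lengths * np.exp(-lam * scores)
    hits = np.flatnonzero(evalues <= evalue_threshold)
    return [catalog[int(i)] for i in hits]


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptideCluster:
    """A set of peptide windows behaving as one sequence feature.

    The cluster id is the label of its lexicographically smallest member;
    ``profile`` is the profile of the final (fixpoint) member set, absent for
    merged clusters.
    """

    cluster_id: str
    members: tuple[PeptideWindow, ...]
    profile: ProfileModel | None = None
    n_iterations: int = 0

    def __post_init__(self) -> None:
        keys = [m.key for m in self.members]
        if len(set(keys)) != len(keys):
            raise ValueError("cluster members must be unique by (protein_id, start)")
        if keys != sorted(keys):
            raise ValueError("cluster members must be canonically sorted")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_keys(self) -> frozenset[tuple[str, int]]:
        return frozenset(m.key for m in self.members)

    @property
    def protein_set(self) -> frozenset[str]:
        return frozenset(m.protein_id for m in self.members)


def _make_cluster(
    members: Iterable[PeptideWindow],
    profile: ProfileModel | None = None,
    n_iterations: int = 0,
) -> PeptideCluster:
    ms = tuple(sorted(members, key=lambda m: m.key))
    cid = ms[0].label
    return PeptideCluster(cid, ms, profile, n_iterations)


def grow_cluster(
    seed: SignificantPair,
    catalog: WindowCatalog,
    evalue_threshold: float,
    max_iter: int = MAX_GROW_ITERATIONS,
    cache: dict | None = None,
) -> PeptideCluster:
    """Grow one cluster from a seed pair to its fixpoint.

    Each round builds a profile from the current members and adds every
    catalog window the profile finds at the E-value threshold.  Membership is
    monotone non-decreasing and bounded by the catalog, so the iteration
    terminates; a cap guards against a pathological (non-monotone) search
    adapter.  ``cache`` optionally memoizes member-set -> fixpoint across
    seeds; being a pure function of the member set, this cannot change the
    result.
    """
    by_key = {w.key: w for w in catalog}
    members: dict[tuple[str, int], PeptideWindow] = {
        seed.window_a.key: seed.window_a,
        seed.window_b.key: seed.window_b,
    }
    visited: list[frozenset] = []
    profile: ProfileModel | None = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        state = frozenset(members)
        if cache is not None and state in cache:
            final_keys, profile = cache[state]
            members = {k: by_key.get(k) or members[k] for k in final_keys}
            break
        visited.append(state)
        profile = build_profile([w.sequence for w in members.values()])
        try:
            hits = profile_search(profile, catalog, evalue_threshold)
        except EstimationError:
            logger.warning(
                "degenerate profile score population; cluster frozen at %d members",
                len(members),
            )
            break
        before = len(members)
        for h in hits:
            members.setdefault(h.key, h)
        if len(members) == before:
            break
    else:
        logger.warning("cluster growth hit the %d-iteration cap", max_iter)
    if cache is not None:
        final = (frozenset(members), profile)
        for state in visited:
            cache[state] = final
    return _make_cluster(members.values(), profile, iterations)


def cluster_all(
    pairs: Sequence[SignificantPair],
    catalog: WindowCatalog,
    evalue_threshold: float,
) -> list[PeptideCluster]:
    """Grow one cluster per seed pair (before any post-processing).

    Seeds are independent, so results do not depend on execution order; a
    shared memo cache only short-circuits identical member states.  Seeds
    whose growth fails are logged and skipped.
    """
    cache: dict = {}
    out: list[PeptideCluster] = []
    for pair in pairs:
        try:
            out.append(grow_cluster(pair, catalog, evalue_threshold, cache=cache))
        except Exception as exc:  # per-seed isolation
            logger.warning(
                "seed %s/%s failed: %s", pair.window_a.label, pair.window_b.label, exc
            )
    return out


def dedupe_clusters(clusters: Sequence[PeptideCluster]) -> list[PeptideCluster]:
    """Collapse clusters with identical member sets (first occurrence wins)."""
    seen: set[frozenset] = set()
    out: list[PeptideCluster] = []
    for c in clusters:
        if c.member_keys not in seen:
            seen.add(c.member_keys)
            out.append(c)
    return out


def _qualifies(a: frozenset, b: frozenset, rule: str) -> bool:
    shared = len(a & b)
    if shared == 0:
        return False
    if rule == "any":
        return True
    smaller = min(len(a), len(b))
    if rule == "frac10":
        return shared * 10 >= smaller
    if rule == "frac20":
        return shared * 5 >= smaller
    raise ValueError(f"unknown merge rule {rule!r}; expected one of {MERGE_RULES}")


def merge_clusters(
    clusters: Sequence[PeptideCluster], rule: str = "frac10"
) -> list[PeptideCluster]:
    """Merge overlapping clusters until no pair satisfies the rule.

    Rules: ``any`` (>=1 shared member), ``frac10``/``frac20`` (shared members
    are at least 10%/20% of the smaller cluster).  Each round evaluates the
    rule on the current clusters, takes connected components of qualifying
    pairs (union-find closure) and unions their members; rounds repeat until
    nothing qualifies, so the result is independent of input order.
    """
    if rule not in MERGE_RULES:
        raise ValueError(f"unknown merge rule {rule!r}; expected one of {MERGE_RULES}")
    current: list[set[PeptideWindow]] = [set(c.members) for c in clusters]
    while True:
        n = len(current)
        keysets = [frozenset(w.key for w in s) for s in current]
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        merged_any = False
        for i in range(n):
            for j in range(i + 1, n):
                if find(i) != find(j) and _qualifies(keysets[i], keysets[j], rule):
                    parent[find(j)] = find(i)
                    merged_any = True
        if not merged_any:
            break
        groups: dict[int, set[PeptideWindow]] = {}
        for i in range(n):
            groups.setdefault(find(i), set()).update(current[i])
        current = list(groups.values())
    out = [_make_cluster(s) for s in current]
    out.sort(key=lambda c: c.cluster_id)
    return out


def filter_clusters(
    clusters: Sequence[PeptideCluster],
    min_members: int = 3,
    max_proteins: int | None = None,
) -> list[PeptideCluster]:
    """Drop undersized clusters and, optionally, promiscuous ones.

    Two-member clusters carry no predictive signal; clusters present in more
    than ``max_proteins`` proteins (when given) occur in positives and
    negatives alike and are equally uninformative.
    """
    out = [c for c in clusters if len(c) >= min_members]
    if max_proteins is not None:
        out = [c for c in out if len(c.protein_set) <= max_proteins]
    return out


def assign_clusters(
    clusters: Sequence[PeptideCluster],
) -> dict[str, frozenset[str]]:
    """Map each protein to the set of cluster ids containing >=1 of its windows."""
    tmp: dict[str, set[str]] = {}
    for c in clusters:
        for pid in c.protein_set:
            tmp.setdefault(pid, set()).add(c.cluster_id)
    return {pid: frozenset(cids) for pid, cids in tmp.items()}
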