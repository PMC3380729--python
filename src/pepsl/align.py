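"""Smith-Waterman local alignment of peptide windows under BLOSUM62.

Two entry points are provided: :func:`smith_waterman`, a scalar aligner with
traceback for individual pairs, and :func:`sw_scores`, a numpy-vectorized
score-only kernel that aligns one query against many subjects at once.  Both
implement the same dynamic program — local alignment with substitution scores
from the matrix and a *linear* gap penalty (a fixed cost per gap symbol;
default 14).  Mismatch costs come from the substitution matrix itself, which
is what BLOSUM62 encodes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .windows import PeptideWindow, WindowCatalog

__all__ = [
    "SubstitutionMatrix",
    "AlignmentResult",
    "load_substitution_matrix",
    "smith_waterman",
    "sw_scores",
    "encode_catalog",
    "score_window_against_catalog",
]

#: default linear gap penalty per gap symbol
DEFAULT_GAP = 14

# score used for residues absent from the matrix alphabet when no 'X' column
# exists, and for padding columns in the batch kernel
_FALLBACK_SCORE = -1
_PAD_SCORE = -(10**6)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric integer residue-pair scoring matrix.

    ``alphabet`` orders the residue symbols; ``scores[i, j]`` is the score of
    aligning ``alphabet[i]`` with ``alphabet[j]``.  Symbols outside the
    alphabet are mapped to the 'X' column when present, otherwise to a
    constant score of -1 against everything.
    """

    alphabet: str
    scores: np.ndarray  # (A, A) int

    def __post_init__(self) -> None:
        A = len(self.alphabet)
        if self.scores.shape != (A, A):
            raise ValueError("score matrix shape does not match alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")

    @property
    def n_symbols(self) -> int:
        return len(self.alphabet)

    def _code_map(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.alphabet)}

    def encode(self, seq: str) -> np.ndarray:
        """Encode a sequence as integer codes; unknown symbols map to 'X' or a
        dedicated fallback code (the last row of :meth:`extended_scores`)."""
        cmap = self._code_map()
        unknown = cmap.get("X", self.n_symbols)
        return np.fromiter(
            (cmap.get(c, unknown) for c in seq.upper()), dtype=np.int64, count=len(seq)
        )

    def extended_scores(self) -> np.ndarray:
        """Score table with two extra codes appended: a fallback symbol scoring
        -1 against everything, and a padding symbol scoring very negatively so
        padded positions can never take part in an alignment."""
        A = self.n_symbols
        ext = np.full((A + 2, A + 2), _FALLBACK_SCORE, dtype=np.int64)
        ext[:A, :A] = self.scores
        ext[A + 1, :] = _PAD_SCORE
        ext[:, A + 1] = _PAD_SCORE
        return ext

    @property
    def pad_code(self) -> int:
        return self.n_symbols + 1

    def score(self, x: str, y: str) -> int:
        ext = self.extended_scores()
        return int(ext[self.encode(x)[0], self.encode(y)[0]])


def load_substitution_matrix(name_or_path: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a bundled matrix by name (e.g. ``"BLOSUM62"``) or an NCBI-format
    matrix text file by path."""
    if os.path.exists(name_or_path):
        try:
            with open(name_or_path) as fh:
                arr = substitution_matrices.read(fh)
        except Exception as exc:  # malformed file
            raise ValueError(f"cannot parse substitution matrix {name_or_path}: {exc}")
    else:
        try:
            arr = substitution_matrices.load(name_or_path)
        except Exception:
            raise ValueError(f"unknown substitution matrix {name_or_path!r}")
    alphabet = "".join(arr.alphabet)
    scores = np.asarray(arr).astype(np.int64)
    if scores.shape != (len(alphabet), len(alphabet)):
        raise ValueError(f"matrix {name_or_path!r} is not square over its alphabet")
    return SubstitutionMatrix(alphabet, scores)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a local alignment.

    Spans are 0-based half-open intervals on the query/subject; a score of 0
    means no positive-scoring local alignment exists and both spans are empty.
    """

    score: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    query_aligned: str = ""
    subject_aligned: str = ""


def _dp_matrix(ca: np.ndarray, cb: np.ndarray, ext: np.ndarray, gap: int) -> np.ndarray:
    """Full Smith-Waterman score matrix H of shape (|a|+1, |b|+1)."""
    la, lb = len(ca), len(cb)
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    if la == 0 or lb == 0:
        return H
    jg = gap * np.arange(lb)
    for i in range(1, la + 1):
        srow = ext[ca[i - 1]][cb]
        t = np.maximum(H[i - 1, :-1] + srow, H[i - 1, 1:] - gap)
        np.maximum(t, 0, out=t)
        # resolve the in-row (left) dependency with a running max:
        # H[i,j] = max(t_j, H[i,j-1]-gap) = max_{k<=j}(t_k - gap*(j-k))
        H[i, 1:] = np.maximum.accumulate(t + jg) - jg
    return H


def smith_waterman(
    a: str,
    b: str,
    matrix: SubstitutionMatrix,
    gap_penalty: int = DEFAULT_GAP,
) -> AlignmentResult:
    """Optimal local alignment score (and one optimal alignment) of ``a`` vs ``b``.

    Ties on the optimal score are broken toward the smallest
    ``(query_end, subject_end)`` in lexicographic order; the traceback prefers
    diagonal moves, then gaps in the subject, then gaps in the query.
    """
    if gap_penalty < 0:
        raise ValueError("gap_penalty must be non-negative")
    ca, cb = matrix.encode(a), matrix.encode(b)
    ext = matrix.extended_scores()
    H = _dp_matrix(ca, cb, ext, gap_penalty)
    best = int(H.max())
    if best <= 0:
        return AlignmentResult(0, (0, 0), (0, 0))
    # np.argmax returns the first maximum in row-major order, i.e. the
    # smallest (query_end, subject_end) lexicographically
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    i, j = int(i), int(j)
    qa: list[str] = []
    sa: list[str] = []
    ei, ej = i, j
    while i > 0 and j > 0 and H[i, j] > 0:
        if H[i, j] == H[i - 1, j - 1] + ext[ca[i - 1], cb[j - 1]]:
            qa.append(a[i - 1])
            sa.append(b[j - 1])
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - gap_penalty:
            qa.append(a[i - 1])
            sa.append("-")
            i -= 1
        else:
            qa.append("-")
            sa.append(b[j - 1])
            j -= 1
    return AlignmentResult(
        best, (i, ei), (j, ej), "".join(reversed(qa)), "".join(reversed(sa))
    )


def encode_catalog(
    catalog: WindowCatalog, matrix: SubstitutionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Encode all catalog windows as a padded code matrix.

    Returns ``(codes, lengths)`` where ``codes`` has shape (N, Lmax) padded
    with the matrix pad code, so padded columns can never align.
    """
    n = len(catalog)
    lengths = np.fromiter((w.length for w in catalog), dtype=np.int64, count=n)
    lmax = int(lengths.max()) if n else 0
    codes = np.full((n, lmax), matrix.pad_code, dtype=np.int64)
    for i, w in enumerate(catalog):
        codes[i, : w.length] = matrix.encode(w.sequence)
    return codes, lengths


def precompute_symbol_scores(
    subject_codes: np.ndarray, matrix: SubstitutionMatrix
) -> np.ndarray:
    """Per-symbol score planes: ``planes[c]`` is the (N, Lmax) score of query
    symbol ``c`` against every subject position.  Computing this once per
    catalog removes the dominant gather from the inner DP loop."""
    ext = matrix.extended_scores().astype(np.int32)
    return ext[:, subject_codes]  # (n_symbols + 2, N, Lmax)


def _sw_scores_planes(
    query_codes: np.ndarray, planes: np.ndarray, gap_penalty: int
) -> np.ndarray:
    N, lmax = planes.shape[1:]
    if N == 0 or lmax == 0 or len(query_codes) == 0:
        return np.zeros(N, dtype=np.int64)
    jg = (gap_penalty * np.arange(lmax)).astype(np.int32)
    prev = np.zeros((N, lmax + 1), dtype=np.int32)
    cur = np.zeros((N, lmax + 1), dtype=np.int32)
    best = np.zeros(N, dtype=np.int32)
    for qc in query_codes:
        t = np.maximum(prev[:, :-1] + planes[qc], prev[:, 1:] - gap_penalty)
        np.maximum(t, 0, out=t)
        cur[:, 1:] = np.maximum.accumulate(t + jg, axis=1) - jg
        np.maximum(best, cur[:, 1:].max(axis=1), out=best)
        prev, cur = cur, prev
    return best.astype(np.int64)


def sw_scores(
    query_codes: np.ndarray,
    subject_codes: np.ndarray,
    matrix: SubstitutionMatrix,
    gap_penalty: int = DEFAULT_GAP,
) -> np.ndarray:
    """Smith-Waterman scores of one query against many subjects at once.

    ``subject_codes`` is an (N, Lmax) padded code matrix from
    :func:`encode_catalog`.  Returns an (N,) integer score vector identical to
    calling :func:`smith_waterman` per subject.
    """
    planes = precompute_symbol_scores(subject_codes, matrix)
    return _sw_scores_planes(query_codes, planes, gap_penalty)


try:  # optional JIT for the all-vs-all score matrix
    from numba import njit as _njit

    @_njit(cache=False)
    def _sw_matrix_jit(codes, lengths, ext, gap):  # pragma: no cover - jitted
        n = codes.shape[0]
        S = np.zeros((n, n), dtype=np.int32)
        lmax = codes.shape[1]
        prev = np.zeros(lmax + 1, dtype=np.int32)
        cur = np.zeros(lmax + 1, dtype=np.int32)
        for a in range(n):
            la = lengths[a]
            for b in range(a + 1, n):
                lb = lengths[b]
                best = 0
                for j in range(lb + 1):
                    prev[j] = 0
                for i in range(la):
                    ci = codes[a, i]
                    cur[0] = 0
                    for j in range(1, lb + 1):
                        h = prev[j - 1] + ext[ci, codes[b, j - 1]]
                        if prev[j] - gap > h:
                            h = prev[j] - gap
                        if cur[j - 1] - gap > h:
                            h = cur[j - 1] - gap
                        if h < 0:
                            h = 0
                        cur[j] = h
                        if h > best:
                            best = h
                    for j in range(lb + 1):
                        prev[j] = cur[j]
                S[a, b] = best
                S[b, a] = best
        return S

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def sw_score_matrix(
    codes: np.ndarray,
    lengths: np.ndarray,
    matrix: SubstitutionMatrix,
    gap_penalty: int = DEFAULT_GAP,
) -> np.ndarray:
    """Symmetric all-vs-all Smith-Waterman score matrix over encoded windows.

    Uses a JIT-compiled pairwise kernel when numba is importable, otherwise
    the vectorized planes kernel; both compute the identical dynamic program.
    """
    n = codes.shape[0]
    if n == 0:
        return np.zeros((0, 0), dtype=np.int64)
    if HAVE_NUMBA:
        ext = matrix.extended_scores().astype(np.int32)
        S = _sw_matrix_jit(
            codes.astype(np.int32), lengths.astype(np.int32), ext,
            np.int32(gap_penalty),
        )
        return S.astype(np.int64)
    planes = precompute_symbol_scores(codes, matrix)
    S = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        q = codes[i, codes[i] != matrix.pad_code]
        s = _sw_scores_planes(q, planes[:, i + 1 :, :], gap_penalty)
        S[i, i + 1 :] = s
        S[i + 1 :, i] = s
    return S


def score_window_against_catalog(
    query: PeptideWindow,
    catalog: WindowCatalog,
    matrix: SubstitutionMatrix,
    gap_penalty: int = DEFAULT_GAP,
) -> list[tuple[PeptideWindow, int]]:
    """Score a query window against every catalog window from *other* proteins.

    Windows of the query's own protein are excluded both here and from the
    score populations used for significance calibration.  Order is the
    deterministic catalog order.
    """
    codes, _ = encode_catalog(catalog, matrix)
    scores = sw_scores(matrix.encode(query.sequence), codes, matrix, gap_penalty)
    return [
        (w, int(scores[i]))
        for i, w in enumerate(catalog)
        if w.protein_id != query.protein_id
    ]
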