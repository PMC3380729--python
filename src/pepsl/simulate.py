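"""Synthetic proteomes with planted motif families and sampled SLGI networks.

The generator emulates the data regime the pipeline is built for: random
background protein sequences (lengths from a truncated normal matching the
yeast proteome's marginals: mean 450, sd 380, clipped to [16, 4901]) with
conserved ~25-residue motif families embedded at random non-overlapping
offsets under point-substitution noise.  Family-pair interaction
probabilities p* are planted and protein-pair SLGI labels are sampled from
the same noisy-OR rule the predictor assumes, so parameter recovery is
well-posed.  Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clustering import PeptideCluster
from .em import InteractionSet, Pair, canonical_pair
from .windows import ProteinRecord, WindowCatalog

__all__ = [
    "AA20",
    "MotifFamily",
    "PlantedTruth",
    "generate_proteome",
    "plant_probabilities",
    "sample_interactions",
    "split_train_test",
    "generate_assignment",
    "label_windows",
    "pairwise_cluster_metrics",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# yeast proteome length marginals used as generator defaults
DEFAULT_LENGTH_MEAN = 450.0
DEFAULT_LENGTH_SD = 380.0
MIN_PROTEIN_LENGTH = 16
MAX_PROTEIN_LENGTH = 4901


@dataclass(frozen=True)
class MotifFamily:
    """A conserved peptide family: consensus plus noisy planted copies."""

    family_id: str
    consensus: str
    copies: tuple[tuple[str, int], ...]  # (protein_id, start)
    mutation_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5]")


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic proteome."""

    families: dict[str, MotifFamily]
    protein_families: dict[str, frozenset[str]]
    p_star: dict[Pair, float] = field(default_factory=dict)
    labels: InteractionSet | None = None


def _draw_lengths(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lo: int,
    hi: int,
) -> np.ndarray:
    """Truncated-normal protein lengths via rejection."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.normal(mean, sd, size=2 * (n - filled))).astype(np.int64)
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def generate_proteome(
    n_proteins: int,
    n_families: int,
    copies_per_family: int,
    motif_len: int = 25,
    mutation_rate: float = 0.1,
    background_length_mean: float = DEFAULT_LENGTH_MEAN,
    background_length_sd: float = DEFAULT_LENGTH_SD,
    min_length: int = MIN_PROTEIN_LENGTH,
    max_length: int = MAX_PROTEIN_LENGTH,
    seed: int = 0,
    composition: Sequence[float] | None = None,
) -> tuple[list[ProteinRecord], PlantedTruth]:
    """Generate a synthetic proteome with planted motif families.

    Background residues are i.i.d. from a uniform (or supplied) composition.
    Each family draws a uniform-random consensus of ``motif_len`` residues and
    embeds ``copies_per_family`` copies at random offsets that never overlap
    another planted motif of the same protein, substituting each residue
    independently with probability ``mutation_rate``.  Deterministic under
    ``seed``.
    """
    if n_families > 0 and copies_per_family < 2:
        raise ValueError("copies_per_family must be >= 2")
    rng = np.random.default_rng(seed)
    probs = None
    if composition is not None:
        probs = np.asarray(composition, dtype=float)
        probs = probs / probs.sum()
    lengths = _draw_lengths(
        rng, n_proteins, background_length_mean, background_length_sd,
        min_length, max_length,
    )
    aa = np.array(list(AA20))
    seqs = [
        list(aa[rng.choice(20, size=int(L), p=probs)]) for L in lengths
    ]
    pids = [f"P{i:04d}" for i in range(n_proteins)]
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_proteins)}
    families: dict[str, MotifFamily] = {}
    protein_families: dict[str, set[str]] = {}
    eligible = [i for i in range(n_proteins) if lengths[i] >= motif_len]
    if n_families > 0 and not eligible:
        raise RuntimeError("no protein is long enough to host a motif")
    for f in range(n_families):
        fid = f"F{f:02d}"
        consensus = "".join(aa[rng.choice(20, size=motif_len)])
        copies: list[tuple[str, int]] = []
        for _ in range(copies_per_family):
            placed = False
            for _attempt in range(100):
                host = int(rng.choice(eligible))
                start = int(rng.integers(0, lengths[host] - motif_len + 1))
                span = (start, start + motif_len)
                if any(span[0] < e and s < span[1] for s, e in occupied[host]):
                    continue
                occupied[host].append(span)
                copy = list(consensus)
                muts = rng.random(motif_len) < mutation_rate
                for pos in np.flatnonzero(muts):
                    old = copy[pos]
                    choices = [c for c in AA20 if c != old]
                    copy[pos] = choices[int(rng.integers(0, 19))]
                seqs[host][span[0] : span[1]] = copy
                copies.append((pids[host], start))
                protein_families.setdefault(pids[host], set()).add(fid)
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a copy of family {fid} after 100 attempts"
                )
        families[fid] = MotifFamily(fid, consensus, tuple(copies), mutation_rate)
    records = [ProteinRecord(pid, "".join(s)) for pid, s in zip(pids, seqs)]
    truth = PlantedTruth(
        families=families,
        protein_families={
            pid: frozenset(protein_families.get(pid, set())) for pid in pids
        },
    )
    return records, truth


def plant_probabilities(
    feature_ids: Sequence[str],
    levels: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8),
    weights: Sequence[float] = (0.8, 0.05, 0.05, 0.05, 0.05),
    seed: int = 0,
) -> dict[Pair, float]:
    """Assign a planted interaction probability to every unordered feature
    pair (self-pairs included), drawn from ``levels`` with ``weights``."""
    rng = np.random.default_rng(seed)
    ids = sorted(feature_ids)
    out: dict[Pair, float] = {}
    for i, a in enumerate(ids):
        for b in ids[i:]:
            out[(a, b)] = float(rng.choice(levels, p=np.asarray(weights) / np.sum(weights)))
    return out


def _noisy_or(
    fa: frozenset[str], fb: frozenset[str], p_star: Mapping[Pair, float]
) -> float:
    prod = 1.0
    for pair in {canonical_pair(i, j) for i in fa for j in fb}:
        prod *= 1.0 - p_star.get(pair, 0.0)
    return 1.0 - prod


def sample_interactions(
    protein_features: Mapping[str, frozenset[str]],
    p_star: Mapping[Pair, float],
    seed: int = 0,
) -> InteractionSet:
    """Sample SLGI labels for every unordered protein pair from the noisy-OR
    over its true feature pairs.  Pairs with no feature pair get probability 0
    (the empty product) and land in the negatives."""
    rng = np.random.default_rng(seed)
    prots = sorted(protein_features)
    pos: list[Pair] = []
    neg: list[Pair] = []
    for i, a in enumerate(prots):
        for b in prots[i + 1 :]:
            pr = _noisy_or(protein_features[a], protein_features[b], p_star)
            if rng.random() < pr:
                pos.append((a, b))
            else:
                neg.append((a, b))
    return InteractionSet(frozenset(pos), frozenset(neg))


def split_train_test(
    interactions: InteractionSet, fraction: float, seed: int = 0
) -> tuple[InteractionSet, InteractionSet]:
    """Disjoint protein-pair split, stratified by label.

    ``fraction`` is the test share; no pair appears in both sets.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def _split(pairs: frozenset[Pair] | None) -> tuple[frozenset[Pair], frozenset[Pair] | None]:
        if pairs is None:
            return frozenset(), None
        items = sorted(pairs)
        perm = rng.permutation(len(items))
        n_test = int(round(fraction * len(items)))
        test = frozenset(items[i] for i in perm[:n_test])
        train = frozenset(items[i] for i in perm[n_test:])
        return train, test

    train_pos, test_pos = _split(interactions.positives)
    train_neg, test_neg = _split(interactions.negatives)
    return (
        InteractionSet(train_pos, train_neg),
        InteractionSet(test_pos if test_pos is not None else frozenset(), test_neg),
    )


def generate_assignment(
    n_proteins: int,
    feature_ids: Sequence[str],
    mean_features_per_protein: float = 2.0,
    seed: int = 0,
) -> dict[str, frozenset[str]]:
    """Random protein -> feature-set map (1 + Poisson distributed set sizes)."""
    rng = np.random.default_rng(seed)
    ids = sorted(feature_ids)
    out: dict[str, frozenset[str]] = {}
    for i in range(n_proteins):
        k = 1 + int(rng.poisson(max(mean_features_per_protein - 1.0, 0.0)))
        k = min(k, len(ids))
        chosen = rng.choice(len(ids), size=k, replace=False)
        out[f"P{i:04d}"] = frozenset(ids[int(c)] for c in chosen)
    return out


# ---------------------------------------------------------------------------
# evaluation helpers against planted truth
# ---------------------------------------------------------------------------


def label_windows(
    truth: PlantedTruth, catalog: WindowCatalog, min_overlap: int = 13
) -> dict[tuple[str, int], str]:
    """Family label of every catalog window overlapping a planted copy by at
    least ``min_overlap`` residues (a strict majority of a 25-mer, so at most
    one label per window since planted copies never overlap)."""
    copies: dict[str, list[tuple[int, int, str]]] = {}
    for fam in truth.families.values():
        L = len(fam.consensus)
        for pid, start in fam.copies:
            copies.setdefault(pid, []).append((start, start + L, fam.family_id))
    labels: dict[tuple[str, int], str] = {}
    for w in catalog:
        for s, e, fid in copies.get(w.protein_id, ()):
            overlap = min(e, w.start + w.length) - max(s, w.start)
            if overlap >= min_overlap:
                labels[w.key] = fid
                break
    return labels


def pairwise_cluster_metrics(
    clusters: Sequence[PeptideCluster],
    labels: Mapping[tuple[str, int], str],
) -> tuple[float, float]:
    """Pairwise precision/recall of cluster co-membership vs planted labels.

    Only windows with a planted label enter the pair universe; a pair counts
    as predicted when some cluster contains both windows.
    """
    predicted: set[frozenset[tuple[str, int]]] = set()
    for c in clusters:
        mem = [m.key for m in c.members if m.key in labels]
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                predicted.add(frozenset((mem[i], mem[j])))
    tp = sum(1 for pair in predicted if len({labels[k] for k in pair}) == 1)
    by_family: dict[str, list[tuple[str, int]]] = {}
    for key, fid in labels.items():
        by_family.setdefault(fid, []).append(key)
    total_true = sum(len(v) * (len(v) - 1) // 2 for v in by_family.values())
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / total_true if total_true else 0.0
    return precision, recall
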