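"""Verification evaluation: genuine/imposter pairs, cosine scoring, ROC, EER.

Pairing follows the protocol used with round-structured cohorts: all
unordered same-subject segment pairs are genuine (S * C(k,2) for S subjects
with k segments each); for every ordered subject pair (i, j), i != j, the
first half of subject i's segments is crossed with the back half of subject
j's segments, giving S*(S-1)*(k/2)^2 imposter pairs.  The equal error rate
is the operating point where the false-accept rate on imposter scores equals
the false-reject rate on genuine scores, located by linear interpolation on
the threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "PairSet",
    "ROCResult",
    "build_pairs",
    "cosine_score",
    "compute_eer",
    "genuine_fraction",
    "score_pairs",
    "evaluate_embeddings",
]


@dataclass
class PairSet:
    """Genuine (same-subject) and imposter (cross-subject) sample-index pairs."""

    genuine: list[tuple]
    imposter: list[tuple]

    @property
    def genuine_fraction(self) -> float:
        total = len(self.genuine) + len(self.imposter)
        return len(self.genuine) / total if total else float("nan")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    far: np.ndarray  # imposter-accept rate, non-increasing in threshold
    frr: np.ndarray  # genuine-reject rate, non-decreasing in threshold
    eer: float
    eer_threshold: float


def build_pairs(samples: dict[object, list]) -> PairSet:
    """Build genuine and imposter pairs from per-subject ordered segment lists.

    Odd segment counts split floor/ceil: the first half is the first k//2
    segments, the back half the rest.
    """
    subjects = list(samples.keys())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to build imposter pairs")
    genuine: list[tuple] = []
    for s in subjects:
        genuine.extend(combinations(samples[s], 2))
    imposter: list[tuple] = []
    for i in subjects:
        first_half = samples[i][: len(samples[i]) // 2]
        for j in subjects:
            if i == j:
                continue
            back_half = samples[j][len(samples[j]) // 2 :]
            imposter.extend((a, b) for a in first_half for b in back_half)
    return PairSet(genuine=genuine, imposter=imposter)


def genuine_fraction(S: int, k: int) -> float:
    """Closed-form genuine-pair fraction S*C(k,2) / (S*C(k,2) + S(S-1)(k/2)^2)."""
    g = S * k * (k - 1) // 2
    i = S * (S - 1) * (k // 2) * (k - k // 2)
    return g / (g + i)


def cosine_score(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; raises on zero vectors."""
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(v1, v2) / (n1 * n2))


def compute_eer(
    genuine_scores: np.ndarray, imposter_scores: np.ndarray
) -> ROCResult:
    """ROC sweep and equal error rate.

    FAR(t) = fraction of imposter scores >= t (ties accept); FRR(t) =
    fraction of genuine scores < t.  The EER is located where FAR - FRR
    changes sign, with linear interpolation between adjacent thresholds.
    """
    gen = np.asarray(genuine_scores, dtype=float)
    imp = np.asarray(imposter_scores, dtype=float)
    if gen.size == 0 or imp.size == 0:
        raise ValueError("both score lists must be non-empty")
    thresholds = np.unique(np.concatenate([gen, imp]))
    # include a threshold above every score so FAR reaches 0 / FRR reaches 1
    thresholds = np.append(thresholds, thresholds[-1] + 1.0)
    gen_sorted = np.sort(gen)
    imp_sorted = np.sort(imp)
    far = 1.0 - np.searchsorted(imp_sorted, thresholds, side="left") / imp.size
    frr = np.searchsorted(gen_sorted, thresholds, side="left") / gen.size

    diff = far - frr
    k = int(np.flatnonzero(np.diff(np.sign(diff)) != 0)[0]) if np.any(
        np.diff(np.sign(diff)) != 0
    ) else int(np.argmin(np.abs(diff)))
    if diff[k] == 0:
        eer, thr = float(far[k]), float(thresholds[k])
    else:
        k2 = min(k + 1, len(thresholds) - 1)
        d1, d2 = diff[k], diff[k2]
        w = d1 / (d1 - d2) if d1 != d2 else 0.0
        eer = float(far[k] + w * (far[k2] - far[k]))
        # average with FRR interpolation for symmetry at the crossing
        eer_frr = float(frr[k] + w * (frr[k2] - frr[k]))
        eer = (eer + eer_frr) / 2.0
        thr = float(thresholds[k] + w * (thresholds[k2] - thresholds[k]))
    return ROCResult(thresholds=thresholds, far=far, frr=frr, eer=eer, eer_threshold=thr)


def score_pairs(
    embeddings: np.ndarray, pairs: PairSet, index: dict | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cosine scores for every genuine and imposter pair.

    ``index`` maps sample ids to embedding rows (identity mapping if None).
    """
    def rows(pairlist):
        if not pairlist:
            return np.array([]), np.array([])
        a, b = zip(*pairlist)
        if index is not None:
            a = [index[x] for x in a]
            b = [index[x] for x in b]
        return np.asarray(a, dtype=int), np.asarray(b, dtype=int)

    norms = np.linalg.norm(embeddings, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero embedding vector")
    unit = embeddings / norms
    ga, gb = rows(pairs.genuine)
    ia, ib = rows(pairs.imposter)
    gen = np.einsum("ij,ij->i", unit[ga], unit[gb]) if ga.size else np.array([])
    imp = np.einsum("ij,ij->i", unit[ia], unit[ib]) if ia.size else np.array([])
    return gen, imp


def evaluate_embeddings(embeddings: np.ndarray, labels: np.ndarray) -> ROCResult:
    """End-to-end EER of an embedding matrix with subject labels."""
    labels = np.asarray(labels)
    samples = {
        s: list(np.flatnonzero(labels == s)) for s in np.unique(labels)
    }
    pairs = build_pairs(samples)
    gen, imp = score_pairs(embeddings, pairs)
    return compute_eer(gen, imp)
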