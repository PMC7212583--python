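"""Benchmark-blind motif clustering.

Two motifs are compared through the sets of fixed-length words they
"recognize": all words whose log probability under the PFM reaches a
threshold chosen so that the word set has a target tail probability (the
p-value) under a uniform background.  The distance between two motifs is one
minus the best Jaccard index of their word sets over all relative alignment
offsets (overlap >= 1 column) and both orientations; alignment columns
outside a motif's own span impose no constraint (free positions).  Motifs
are then grouped by UPGMA (average linkage), halting before any merge whose
inter-cluster average distance reaches the cutoff, and each cluster is
represented by the member minimizing its mean distance to the others.
"""

from __future__ import annotations

import functools
import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .motif_io import PFM

logger = logging.getLogger("pwmbench")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: largest motif length for which p-value thresholds are computed by exact
#: enumeration of all 4^L word scores (above this, the binned distribution)
EXACT_ENUM_MAX_LEN = 12


@dataclass(frozen=True)
class ClusteringParams:
    """pvalue: target word-set tail probability under uniform background;
    merge_cutoff: UPGMA halt distance; delta: score-binning width (natural
    log units) for the score distribution; word_cap: safety limit on word-set
    size; both_orientations: also align reverse complements."""

    pvalue: float = 0.0005
    merge_cutoff: float = 0.95
    delta: float = 0.01
    word_cap: int = 1 << 20
    both_orientations: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.pvalue < 1):
            raise ValueError("pvalue must be in (0, 1)")
        if not (0 < self.merge_cutoff <= 1):
            raise ValueError("merge_cutoff must be in (0, 1]")


def reverse_complement(word: str) -> str:
    return word.translate(_COMPLEMENT)[::-1]


def all_word_scores(pfm: PFM) -> np.ndarray:
    """Log probability of every L-mer, indexed by the base-4 word integer
    (first position most significant).  Exact enumeration; L must be small."""
    if pfm.length > EXACT_ENUM_MAX_LEN:
        raise ValueError(f"refusing to enumerate 4^{pfm.length} words")
    with np.errstate(divide="ignore"):
        rows = [np.log(row) for row in pfm.probs]
    return functools.reduce(np.add.outer, rows).ravel()


def score_distribution(pfm: PFM, delta: float = 0.01
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of word log-probability scores under a uniform
    background, by position-wise convolution with scores binned at width
    ``delta``.  Returns (scores, masses), scores descending, masses summing
    to 1; each reported score is the bin centre ``k * delta``."""
    if np.any(pfm.probs <= 0):
        raise ValueError(f"{pfm.matrix_id}: regularize before computing the "
                         "score distribution (zero probabilities present)")
    logp = np.log(pfm.probs)
    bins: dict[int, float] = {0: 1.0}
    for i in range(pfm.length):
        new: dict[int, float] = {}
        for key, mass in bins.items():
            base_score = key * delta
            for b in range(4):
                new_key = int(round((base_score + logp[i, b]) / delta))
                new[new_key] = new.get(new_key, 0.0) + mass * 0.25
        bins = new
    keys = np.array(sorted(bins, reverse=True))
    scores = keys * delta
    masses = np.array([bins[k] for k in keys])
    return scores, masses


def threshold_for_pvalue(pfm: PFM, pvalue: float = 0.0005,
                         delta: float = 0.01) -> tuple[float, float]:
    """Smallest score threshold t with P(score >= t) <= pvalue under the
    uniform background.  Returns (t, achieved tail probability).  If even the
    single best word exceeds the p-value, the best-word score is returned
    with a warning.  Exact for L <= 12 (full enumeration); binned otherwise.
    """
    if pfm.length <= EXACT_ENUM_MAX_LEN:
        scores = np.sort(all_word_scores(pfm))[::-1]
        uniq, start = np.unique(-scores, return_index=True)
        levels = -uniq  # descending unique scores
        cum = (np.append(start[1:], scores.size)) / scores.size
    else:
        levels, masses = score_distribution(pfm, delta)
        cum = np.cumsum(masses)
    ok = np.where(cum <= pvalue)[0]
    if ok.size == 0:
        logger.warning("motif %s: best word already exceeds p-value %g "
                       "(tail %.3g)", pfm.matrix_id, pvalue, float(cum[0]))
        return float(levels[0]), float(cum[0])
    i = ok[-1]
    return float(levels[i]), float(cum[i])


#: slack for float comparisons against the threshold (enumeration vs DFS may
#: sum the same log probabilities in different orders)
SCORE_TOL = 1e-9


def word_set(pfm: PFM, t: float, cap: int = 1 << 20) -> frozenset[str]:
    """All L-mers scoring >= t, by depth-first search with
    best-possible-suffix pruning."""
    with np.errstate(divide="ignore"):
        logp = np.log(pfm.probs)
    L = pfm.length
    suffix_best = np.zeros(L + 1)
    for i in range(L - 1, -1, -1):
        suffix_best[i] = suffix_best[i + 1] + logp[i].max()
    words: list[str] = []
    bases = "ACGT"
    stack: list[tuple[int, float, str]] = [(0, 0.0, "")]
    while stack:
        i, score, prefix = stack.pop()
        if i == L:
            words.append(prefix)
            if len(words) > cap:
                raise ValueError(
                    f"word set of {pfm.matrix_id} exceeds cap {cap}; "
                    "use a smaller p-value")
            continue
        for b in range(4):
            s = score + logp[i, b]
            if s + suffix_best[i + 1] >= t - SCORE_TOL:
                stack.append((i + 1, s, prefix + bases[b]))
    return frozenset(words)


def _alignment_similarity(words_a: frozenset[str], words_b: frozenset[str],
                          len_a: int, len_b: int, offset: int) -> float:
    """Jaccard index of the two word sets extended over the aligned span,
    with motif B shifted by ``offset`` columns relative to A.

    Positions covered by only one motif are unconstrained for the other, so
    each set's size over the span is |W| * 4^(free positions); members of the
    intersection correspond one-to-one to (a, b) word pairs that agree on the
    overlap columns.
    """
    o0, o1 = max(0, offset), min(len_a, offset + len_b)
    if o1 <= o0:
        raise ValueError("alignment must overlap by at least one column")
    count_a = Counter(w[o0:o1] for w in words_a)
    count_b = Counter(w[o0 - offset:o1 - offset] for w in words_b)
    inter = sum(n * count_b.get(key, 0) for key, n in count_a.items())
    span = max(len_a, offset + len_b) - min(0, offset)
    size_a = len(words_a) * 4 ** (span - len_a)
    size_b = len(words_b) * 4 ** (span - len_b)
    union = size_a + size_b - inter
    return inter / union if union else 0.0


def jaccard_distance(pfm_a: PFM, pfm_b: PFM,
                     params: ClusteringParams = ClusteringParams(),
                     words_a: frozenset[str] | None = None,
                     words_b: frozenset[str] | None = None) -> float:
    """1 - max Jaccard similarity over all overlapping offsets and (if
    enabled) both orientations of B.  Word sets may be passed in to reuse
    them across many pairwise comparisons."""
    if words_a is None:
        t_a, _ = threshold_for_pvalue(pfm_a, params.pvalue, params.delta)
        words_a = word_set(pfm_a, t_a, params.word_cap)
    if words_b is None:
        t_b, _ = threshold_for_pvalue(pfm_b, params.pvalue, params.delta)
        words_b = word_set(pfm_b, t_b, params.word_cap)
    len_a, len_b = pfm_a.length, pfm_b.length
    orientations = [words_b]
    if params.both_orientations:
        orientations.append(frozenset(reverse_complement(w) for w in words_b))
    best = 0.0
    for wb in orientations:
        for offset in range(-(len_b - 1), len_a):
            best = max(best, _alignment_similarity(words_a, wb, len_a, len_b,
                                                   offset))
    return 1.0 - best


def distance_matrix(pfms: Sequence[PFM],
                    params: ClusteringParams = ClusteringParams()
                    ) -> pd.DataFrame:
    """Symmetric pairwise word-set Jaccard distance matrix (zero diagonal)."""
    ids = [p.matrix_id for p in pfms]
    if len(set(ids)) != len(ids):
        raise ValueError("matrix ids must be unique for clustering")
    words = {}
    for p in pfms:
        t, _ = threshold_for_pvalue(p, params.pvalue, params.delta)
        words[p.matrix_id] = word_set(p, t, params.word_cap)
    d = np.zeros((len(pfms), len(pfms)))
    for i, a in enumerate(pfms):
        for j in range(i + 1, len(pfms)):
            b = pfms[j]
            d[i, j] = d[j, i] = jaccard_distance(
                a, b, params, words_a=words[a.matrix_id],
                words_b=words[b.matrix_id])
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass(frozen=True)
class Merge:
    left: tuple[str, ...]
    right: tuple[str, ...]
    distance: float


def upgma_cluster(dist: pd.DataFrame, cutoff: float = 0.95
                  ) -> tuple[list[list[str]], list[Merge]]:
    """UPGMA (average linkage) on raw distances with a halt rule: no merge is
    performed once the smallest inter-cluster average distance reaches the
    cutoff.  Ties in the minimal distance are broken by the lexicographically
    smallest pair of member tuples.  Returns the final partition (each
    cluster sorted, clusters sorted) and the merge history."""
    if not dist.index.equals(dist.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(dist.to_numpy(), dist.to_numpy().T):
        raise ValueError("distance matrix must be symmetric")
    members: dict[int, tuple[str, ...]] = {
        i: (lab,) for i, lab in enumerate(dist.index)}
    d: dict[frozenset[int], float] = {}
    n = len(dist)
    arr = dist.to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((i, j))] = float(arr[i, j])
    merges: list[Merge] = []
    next_id = n
    while len(members) > 1:
        best_key = min(
            d, key=lambda k: (d[k], tuple(sorted(members[i] for i in k))))
        if d[best_key] >= cutoff:
            break
        i, j = sorted(best_key, key=lambda c: members[c])
        dist_ij = d.pop(best_key)
        mi, mj = members.pop(i), members.pop(j)
        merges.append(Merge(mi, mj, dist_ij))
        si, sj = len(mi), len(mj)
        new_dists = {}
        for k in members:
            dik = d.pop(frozenset((i, k)))
            djk = d.pop(frozenset((j, k)))
            new_dists[k] = (si * dik + sj * djk) / (si + sj)
        members[next_id] = tuple(sorted(mi + mj))
        for k, v in new_dists.items():
            d[frozenset((next_id, k))] = v
        next_id += 1
    clusters = sorted(sorted(m) for m in members.values())
    return clusters, merges


def representative(cluster: Sequence[str], dist: pd.DataFrame) -> str:
    """Cluster member minimizing its mean distance to the other members
    (medoid); a singleton represents itself; ties break lexicographically."""
    cluster = sorted(cluster)
    if not cluster:
        raise ValueError("empty cluster")
    if len(cluster) == 1:
        return cluster[0]
    sub = dist.loc[cluster, cluster].to_numpy()
    means = sub.sum(axis=1) / (len(cluster) - 1)
    return cluster[int(np.argmin(means))]
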