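"""Sequence scoring and performance metrics shared by all three protocols.

The central score is the *sum occupancy score*: for a sequence longer than
the motif, slide the PFM over every window (on both strands by default),
take the probability of each window under the PFM, and sum.  It is a soft,
threshold-free binding score, so a strong site and many weak sites can both
raise it.  Discrimination is measured with the rank-based (Mann-Whitney)
AUC ROC; PBM agreement with the Pearson correlation of log scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .motif_io import PFM

# integer encoding: A=0 C=1 G=2 T=3 N=4; anything else is rejected
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

N_BACKGROUND = 0.25  # an N contributes the uniform background probability


class StrandPolicy(str, Enum):
    both = "both"
    forward_only = "forward_only"


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length DNA strings as a (n, S) uint8 array (N allowed)."""
    if not seqs:
        raise ValueError("no sequences to encode")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length for batch encoding")
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    enc = _CODE[buf].reshape(len(seqs), lengths.pop())
    if np.any(enc == 255):
        raise ValueError("sequences contain characters outside {A,C,G,T,N}")
    return enc


def _log_prob_table(pfm: PFM) -> np.ndarray:
    """(L, 5) table of log probabilities with column 4 = log(N background)."""
    with np.errstate(divide="ignore"):
        lp = np.log(pfm.probs)
    return np.concatenate([lp, np.full((pfm.length, 1), math.log(N_BACKGROUND))],
                          axis=1)


def _window_scores(enc: np.ndarray, logp: np.ndarray) -> np.ndarray:
    """Log window probabilities for every window: (n, S-L+1)."""
    n, s = enc.shape
    L = logp.shape[0]
    if s < L:
        raise ValueError(f"sequence length {s} shorter than motif length {L}")
    w = np.zeros((n, s - L + 1))
    for j in range(L):
        w += logp[j, enc[:, j:j + s - L + 1]]
    return w


def batch_sum_occupancy(seqs: Sequence[str], pfm: PFM,
                        strand: StrandPolicy = StrandPolicy.both,
                        enc: np.ndarray | None = None) -> np.ndarray:
    """Sum occupancy score for each of a batch of equal-length sequences.

    Scanning the reverse strand of the sequence is equivalent to scanning the
    forward strand with the reverse-complemented PFM, which keeps everything
    in one encoded array.  Pass ``enc`` to reuse an encoding across motifs.
    """
    if enc is None:
        enc = encode_sequences(seqs)
    occ = np.exp(_window_scores(enc, _log_prob_table(pfm))).sum(axis=1)
    if StrandPolicy(strand) is StrandPolicy.both:
        rc = pfm.reverse_complement()
        occ = occ + np.exp(_window_scores(enc, _log_prob_table(rc))).sum(axis=1)
    return occ


def window_probability(window: str, pfm: PFM) -> float:
    """Probability of a single window (length == motif length) under the PFM;
    N contributes the background probability 0.25 at its position."""
    if len(window) != pfm.length:
        raise ValueError(
            f"window length {len(window)} != motif length {pfm.length}")
    enc = encode_sequences([window])
    return float(np.exp(_window_scores(enc, _log_prob_table(pfm))[0, 0]))


def sum_occupancy(seq: str, pfm: PFM,
                  strand: StrandPolicy = StrandPolicy.both) -> float:
    """Sum of window probabilities over all windows of ``seq`` (and of its
    reverse complement when both strands are scanned)."""
    return float(batch_sum_occupancy([seq], pfm, strand)[0])


def log_sum_occupancy(seq: str, pfm: PFM,
                      strand: StrandPolicy = StrandPolicy.both) -> float:
    """Natural log of the sum occupancy score (rank-preserving transform)."""
    return math.log(sum_occupancy(seq, pfm, strand))


def batch_log_sum_occupancy(seqs: Sequence[str], pfm: PFM,
                            strand: StrandPolicy = StrandPolicy.both,
                            enc: np.ndarray | None = None) -> np.ndarray:
    return np.log(batch_sum_occupancy(seqs, pfm, strand, enc=enc))


def roc_auc(pos: Sequence[float], neg: Sequence[float]) -> float:
    """AUC ROC by the rank (Mann-Whitney) method.

    Equals the probability that a random positive outscores a random
    negative, with ties counting one half, computed tie-aware from the
    mid-ranks of the pooled scores.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("roc_auc needs non-empty positive and negative sets")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise ValueError("scores must be finite")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; rejects degenerate (constant) inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def top_fraction(scores: Sequence[float], q: float) -> np.ndarray:
    """The ceil(q*n) highest scores, ties at the boundary broken by stable
    input order; returned in original input order."""
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    k = math.ceil(q * scores.size)
    order = np.argsort(-scores, kind="stable")
    keep = np.sort(order[:k])
    return scores[keep]


def auc_standard_error(n_pos: int, n_neg: int) -> float:
    """Null (AUC=0.5) standard error: sqrt((n+m+1)/(12 n m))."""
    return math.sqrt((n_pos + n_neg + 1) / (12.0 * n_pos * n_neg))
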