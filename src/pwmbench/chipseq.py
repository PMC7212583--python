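"""ChIP-seq peak-list benchmarking protocol.

Positives are fixed-width genomic windows centred on the anchors (summit or
mid-point) of the N top-scoring peaks; negatives are same-length windows a
fixed signed distance d away.  Both sets are scored with the sum occupancy
score and discrimination is reported as AUC ROC.  Coordinates are 0-based
half-open (BED convention) throughout; the window around anchor ``a`` is
``[a-w, a+w]`` inclusive of both ends, i.e. 2w+1 bp.

Caveat: negatives whose window happens to overlap another peak are kept —
the protocol applies no such exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .motif_io import PFM
from .scoring import StrandPolicy, batch_sum_occupancy, roc_auc

logger = logging.getLogger("pwmbench")

#: windows with more than this fraction of N bases are dropped (pairwise)
MAX_N_FRACTION = 0.5


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    score: float
    name: str = "."
    summit: int | None = None  # offset from start, if known

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start {self.start} >= end {self.end}")
        if not np.isfinite(self.score):
            raise ValueError(f"peak {self.name}: non-finite score")


@dataclass(frozen=True)
class ChipProtocolParams:
    """w: half-width of scored windows (bp); N: number of top-scoring peaks
    used; d: signed offset of the negative-control window (bp); min_peaks:
    minimum peak-list size for a usable experiment."""

    w: int = 250
    N: int = 2000
    d: int = 500
    min_peaks: int = 5000

    def __post_init__(self) -> None:
        if self.w <= 0 or self.N <= 0 or self.min_peaks <= 0:
            raise ValueError("w, N and min_peaks must be positive")
        if self.d == 0:
            raise ValueError("d must be non-zero")


def read_peaks(path: str | Path) -> list[Peak]:
    """Read a BED-like peak file: chrom, start, end, name, score, and an
    optional summit column (column 6 of a 6-column file, or column 10 of a
    narrowPeak-style 10-column file; -1 means no summit)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 5:
                raise ValueError(f"{path}:{line_no}: expected >= 5 columns")
            try:
                start, end, score = int(f[1]), int(f[2]), float(f[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: {exc}") from None
            summit: int | None = None
            summit_field = f[9] if len(f) >= 10 else (f[5] if len(f) == 6 else None)
            if summit_field is not None:
                try:
                    s = int(summit_field)
                except ValueError:
                    s = -1
                summit = s if s >= 0 else None
            try:
                peaks.append(Peak(f[0], start, end, score, f[3], summit))
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: {exc}") from None
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            summit = p.summit if p.summit is not None else -1
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score!r}"
                     f"\t{summit}\n")


def check_min_peaks(peaks: Sequence[Peak],
                    params: ChipProtocolParams = ChipProtocolParams()) -> bool:
    """True (accepted) iff the list has at least ``min_peaks`` peaks."""
    return len(peaks) >= params.min_peaks


def anchor_point(peak: Peak) -> int:
    """Single-position representation of a peak: the summit if recorded,
    otherwise the (floor) mid-point of the interval."""
    if peak.summit is not None:
        pos = peak.start + peak.summit
        if not (peak.start <= pos < peak.end):
            raise ValueError(
                f"peak {peak.name}: summit {pos} outside [{peak.start},{peak.end})")
        return pos
    return (peak.start + peak.end) // 2


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    return str(genome[chrom][start:end]).upper()


def top_n_peaks(peaks: Sequence[Peak], n: int) -> list[Peak]:
    """N top-scoring peaks; ties at the boundary broken by (chrom, start)."""
    return sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))[:n]


def extract_pairs(peaks: Sequence[Peak], genome: Mapping[str, str],
                  params: ChipProtocolParams) -> tuple[list[str], list[str]]:
    """Positive/negative window sequences for the top-N peaks.

    A pair is dropped (together) when either window leaves its chromosome or
    is mostly Ns.
    """
    w, d = params.w, params.d
    pos_seqs: list[str] = []
    neg_seqs: list[str] = []
    n_dropped = 0
    for peak in top_n_peaks(peaks, params.N):
        a = anchor_point(peak)
        chrom_len = len(genome[peak.chrom])
        ps, pe = a - w, a + w + 1
        ns, ne = a + d - w, a + d + w + 1
        if ps < 0 or ns < 0 or pe > chrom_len or ne > chrom_len:
            n_dropped += 1
            continue
        pos = _fetch(genome, peak.chrom, ps, pe)
        neg = _fetch(genome, peak.chrom, ns, ne)
        if (pos.count("N") > MAX_N_FRACTION * len(pos)
                or neg.count("N") > MAX_N_FRACTION * len(neg)):
            n_dropped += 1
            continue
        pos_seqs.append(pos)
        neg_seqs.append(neg)
    if n_dropped:
        logger.info("chipseq: dropped %d peak pairs (bounds/N content)", n_dropped)
    return pos_seqs, neg_seqs


def run_chipseq_benchmark(peaks: Sequence[Peak], genome: Mapping[str, str],
                          pfm: PFM,
                          params: ChipProtocolParams = ChipProtocolParams(),
                          strand: StrandPolicy = StrandPolicy.both) -> float:
    """AUC ROC of the PFM's sum occupancy scores, top-N peak windows vs
    displaced negative-control windows."""
    pos_seqs, neg_seqs = extract_pairs(peaks, genome, params)
    if len(pos_seqs) < 10:
        raise ValueError(f"only {len(pos_seqs)} usable peak pairs (need >= 10)")
    pos = batch_sum_occupancy(pos_seqs, pfm, strand)
    neg = batch_sum_occupancy(neg_seqs, pfm, strand)
    return roc_auc(pos, neg)
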