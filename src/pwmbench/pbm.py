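"""Protein-binding microarray (PBM) correlation protocol.

Each probe carries a variable sequence plus part of a fixed linker; only the
first 41 bp of the printed sequence are scored (the remainder is linker).
The PFM is slid over that prefix, per-window probabilities are summed and
logged (log sum occupancy), and agreement with the experiment is the Pearson
correlation between these scores and the natural-log normalized intensities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .motif_io import PFM
from .scoring import StrandPolicy, batch_log_sum_occupancy, pearson

logger = logging.getLogger("pwmbench")

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class PbmProbe:
    sequence: str
    intensity: float  # normalized, must be positive (log is taken)

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("probe intensity must be positive")


@dataclass(frozen=True)
class PbmParams:
    prefix_len: int = 41

    def __post_init__(self) -> None:
        if self.prefix_len < 1:
            raise ValueError("prefix_len must be positive")


def read_uniprobe_table(path: str | Path) -> list[PbmProbe]:
    """Read a normalized-probe-data table: whitespace/tab-delimited rows of
    intensity and probe sequence, in either column order (auto-detected by
    which field parses as a number).  Rows with non-positive intensities are
    dropped (count logged)."""
    probes: list[PbmProbe] = []
    n_dropped = 0
    order: tuple[int, int] | None = None  # (intensity_col, sequence_col)
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            f = raw.split()
            if not f:
                continue
            if order is None:
                for cand in ((0, 1), (1, 0)):
                    try:
                        float(f[cand[0]])
                    except (ValueError, IndexError):
                        continue
                    if len(f) > cand[1] and set(f[cand[1]].upper()) <= _ALPHABET:
                        order = cand
                        break
                if order is None:
                    continue  # header line
            if len(f) <= max(order):
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            try:
                intensity = float(f[order[0]])
            except ValueError:
                raise ValueError(f"{path}:{line_no}: no numeric intensity") from None
            seq = f[order[1]].upper()
            if intensity <= 0:
                n_dropped += 1
                continue
            probes.append(PbmProbe(seq, intensity))
    if order is None and not probes:
        raise ValueError(f"{path}: no numeric intensity column found")
    if n_dropped:
        logger.info("pbm: dropped %d probes with non-positive intensity", n_dropped)
    return probes


def write_uniprobe_table(probes: Sequence[PbmProbe], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("intensity\tsequence\n")
        for p in probes:
            fh.write(f"{p.intensity:.8g}\t{p.sequence}\n")


def run_pbm_benchmark(probes: Sequence[PbmProbe], pfm: PFM,
                      params: PbmParams = PbmParams(),
                      strand: StrandPolicy = StrandPolicy.both) -> float:
    """Pearson correlation between log sum occupancy of the probe prefixes
    and the log intensities.  Probes shorter than the prefix are skipped with
    a warning rather than failing the experiment."""
    kept = [p for p in probes if len(p.sequence) >= params.prefix_len]
    if len(kept) < len(probes):
        logger.warning("pbm: skipped %d probes shorter than %d nt",
                       len(probes) - len(kept), params.prefix_len)
    if len(kept) < 3:
        raise ValueError("need at least 3 usable probes")
    prefixes = [p.sequence[: params.prefix_len] for p in kept]
    scores = batch_log_sum_occupancy(prefixes, pfm, strand)
    log_intensity = np.log([p.intensity for p in kept])
    return pearson(scores, log_intensity)
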