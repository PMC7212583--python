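"""Position frequency/weight matrices: parsing, regularization, conversion, features.

A PFM stores one probability distribution over the four bases per motif
position.  Base order is fixed as (A, C, G, T) everywhere in this package,
including every format reader and writer.  A PWM (log-ratio weight matrix) is
obtained from a PFM by ``w = log(p / q)`` against a background distribution
``q``; the two representations are inter-convertible and carry the same
information once the PFM is strictly positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pwmbench")

BASES = "ACGT"
BASE_TO_INDEX = {b: i for i, b in enumerate(BASES)}

#: tolerance under which a parsed column that misses sum-to-1 is silently
#: renormalized (public motif files carry rounded probabilities); larger
#: deviations are treated as corrupt input.
COLUMN_SUM_SLACK = 1e-3


class MotifParseError(ValueError):
    """Raised for malformed motif files; message names the motif and line."""


@dataclass(frozen=True)
class Background:
    """Mononucleotide background distribution q over (A, C, G, T)."""

    probs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise ValueError("background must be a length-4 probability vector")
        if not math.isclose(float(p.sum()), 1.0, abs_tol=1e-6):
            raise ValueError(f"background probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class RegularizationParams:
    """Pseudocount added to every matrix element before renormalization."""

    epsilon: float = 0.0001

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class PFM:
    """Position frequency matrix: ``probs[i]`` is the base distribution at
    position ``i`` in (A, C, G, T) order.

    Parsed matrices are stored exactly as read (possibly containing zeros);
    call :func:`regularize` before converting to weights or computing word
    scores so every entry is strictly positive.
    """

    matrix_id: str
    probs: np.ndarray
    gene_symbol: str | None = None
    source: str = "synthetic"

    def __post_init__(self) -> None:
        m = np.asarray(self.probs, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"{self.matrix_id}: PFM must have shape (L>=1, 4)")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError(f"{self.matrix_id}: PFM entries must be finite and >= 0")
        self.probs = m

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PFM":
        return PFM(self.matrix_id, self.probs[::-1, ::-1].copy(),
                   self.gene_symbol, self.source)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class PWMWeights:
    """Log-ratio weight matrix w[b, i] = log_base(p[b, i] / q[b])."""

    matrix_id: str
    weights: np.ndarray  # shape (L, 4)
    log_base: float


@dataclass(frozen=True)
class MotifFeatures:
    length: int
    gc_content: float
    ic_per_position: float  # mean bits of information per position


def regularize(pfm: PFM, params: RegularizationParams = RegularizationParams()) -> PFM:
    """Add a small pseudocount to every entry and renormalize each position.

    ``p' = (p + eps) / (1 + 4*eps)``.  Prevents zero probabilities (and hence
    log-of-zero) in downstream scoring; positions must already sum to 1
    within 1e-6.
    """
    sums = pfm.probs.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
    if bad.size:
        raise ValueError(
            f"{pfm.matrix_id}: position {bad[0]} sums to {sums[bad[0]]:.6g}, not 1"
        )
    eps = params.epsilon
    out = (pfm.probs + eps) / (1.0 + 4.0 * eps)
    return PFM(pfm.matrix_id, out, pfm.gene_symbol, pfm.source)


def pfm_to_pwm(pfm: PFM, bg: Background = Background(),
               log_base: float = math.e) -> PWMWeights:
    """Convert probabilities to log-ratio weights against the background."""
    if np.any(pfm.probs <= 0):
        raise ValueError(
            f"{pfm.matrix_id}: PFM contains zero probabilities; regularize first"
        )
    w = np.log(pfm.probs / bg.probs[None, :]) / math.log(log_base)
    return PWMWeights(pfm.matrix_id, w, log_base)


def pwm_to_pfm(pwm: PWMWeights, bg: Background = Background()) -> PFM:
    """Invert :func:`pfm_to_pwm` (exact for weights produced by it)."""
    p = bg.probs[None, :] * np.power(pwm.log_base, pwm.weights)
    return PFM(pwm.matrix_id, p / p.sum(axis=1, keepdims=True))


def motif_features(pfm: PFM) -> MotifFeatures:
    """Length, GC content and mean per-position information content (bits).

    IC at a position is ``2 - H`` where H is the Shannon entropy of the base
    distribution in bits; the 0*log(0) convention gives zero contribution for
    zero-probability bases.
    """
    p = pfm.probs
    gc = float(p[:, 1:3].sum(axis=1).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    entropy = -plogp.sum(axis=1)
    return MotifFeatures(pfm.length, gc, float((2.0 - entropy).mean()))


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def parse_meme_collection(path: str | Path, source: str = "synthetic") -> list[PFM]:
    """Parse a MEME minimal-format motif file into a list of PFMs.

    One PFM per MOTIF block, in file order, stored exactly as printed
    (un-regularized).  The motif id is the first token after ``MOTIF``.
    """
    pfms: list[PFM] = []
    motif_id: str | None = None
    rows: list[list[float]] = []
    expected: int | None = None

    def flush(line_no: int) -> None:
        nonlocal motif_id, rows, expected
        if motif_id is None:
            return
        if not rows:
            raise MotifParseError(
                f"{path}: motif {motif_id}: no probability rows before line {line_no}"
            )
        if expected is not None and len(rows) != expected:
            raise MotifParseError(
                f"{path}: motif {motif_id}: expected {expected} rows, got {len(rows)}"
            )
        m = np.array(rows, dtype=float)
        sums = m.sum(axis=1)
        off = np.abs(sums - 1.0)
        if np.any(off > COLUMN_SUM_SLACK):
            i = int(np.argmax(off))
            raise MotifParseError(
                f"{path}: motif {motif_id}: position {i} sums to {sums[i]:.6g}"
            )
        if np.any(off > 1e-6):
            logger.warning("motif %s: renormalizing %d rounded position(s)",
                           motif_id, int((off > 1e-6).sum()))
            m = m / sums[:, None]
        pfms.append(PFM(motif_id, m, source=source))
        motif_id, rows, expected = None, [], None

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("MOTIF"):
                flush(line_no)
                parts = line.split()
                if len(parts) < 2:
                    raise MotifParseError(f"{path}:{line_no}: MOTIF line without an id")
                motif_id = parts[1]
            elif line.startswith("letter-probability matrix"):
                if motif_id is None:
                    raise MotifParseError(
                        f"{path}:{line_no}: matrix block outside a MOTIF")
                # pick up "w= <int>" (declared motif width) if present
                toks = line.replace("=", " ").split()
                for i, t in enumerate(toks):
                    if t == "w" and i + 1 < len(toks) and toks[i + 1].isdigit():
                        expected = int(toks[i + 1])
            elif motif_id is not None and line[:1] in set("0123456789."):
                fields = line.split()
                if len(fields) != 4:
                    raise MotifParseError(
                        f"{path}:{line_no}: motif {motif_id}: expected 4 fields, "
                        f"got {len(fields)}"
                    )
                try:
                    vals = [float(x) for x in fields]
                except ValueError as exc:
                    raise MotifParseError(
                        f"{path}:{line_no}: motif {motif_id}: {exc}") from None
                if any(v < 0 for v in vals):
                    raise MotifParseError(
                        f"{path}:{line_no}: motif {motif_id}: negative probability")
                rows.append(vals)
        flush(line_no=-1)
    return pfms


def write_meme_collection(pfms: Sequence[PFM], path: str | Path) -> None:
    """Write motifs in MEME minimal format (6 decimal places)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pfm in pfms:
            fh.write(f"MOTIF {pfm.matrix_id}\n")
            # large nsites keeps count-based downstream readers lossless
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pfm.length} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in pfm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def parse_cisbp_matrix(path: str | Path, matrix_id: str | None = None) -> PFM:
    """Parse a CIS-BP per-matrix text file (position rows, 4 probability
    columns, optional leading position column; header detected by a
    non-numeric first field)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            fields = raw.split()
            if not fields:
                continue
            try:
                float(fields[0])
            except ValueError:
                continue  # header row
            vals = [float(x) for x in fields]
            if len(vals) == 5:
                vals = vals[1:]  # leading position index
            if len(vals) != 4:
                raise MotifParseError(
                    f"{path}:{line_no}: expected 4 probability columns, "
                    f"got {len(vals)}"
                )
            rows.append(vals)
    if not rows:
        raise MotifParseError(f"{path}: no matrix rows found")
    m = np.array(rows)
    sums = m.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > COLUMN_SUM_SLACK):
        i = int(np.argmax(np.abs(sums - 1.0)))
        raise MotifParseError(f"{path}: position {i} sums to {sums[i]:.6g}")
    m = m / sums[:, None]
    return PFM(matrix_id or path.stem, m, source="CISBP")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a matrix annotation TSV: matrix_id, gene_symbol, tfclass_family,
    cisbp_family (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"matrix_id", "gene_symbol"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    return df
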