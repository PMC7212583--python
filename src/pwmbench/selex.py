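"""HT-SELEX benchmarking protocol.

HT-SELEX reads are random inserts of a library-specific length flanked by a
library-specific barcode pair inside constant sequencing primers.  Because
the barcode/primer context was physically present (and bindable) during
selection, inserts are re-extended with 20 bp of that context on each side
before scoring: binding sites straddling the insert boundary are missed if
only the insert is scanned.

Library names encode the experiment, e.g. ``ELK3_TCGGGG20NGGT_AG``: gene
symbol, 5' barcode, insert length, 3' barcode, optional batch tag.

Because SELEX pools are often only weakly enriched for true binding
sequences, discrimination is computed on a top percentile (default 10%) of
the positive and negative score lists rather than on the full lists.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .motif_io import PFM
from .scoring import StrandPolicy, batch_sum_occupancy, roc_auc, top_fraction

logger = logging.getLogger("pwmbench")

_NAME_RE = re.compile(
    r"^(?P<gene>[^_]+)_(?P<bc5>[ACGT]*)(?P<len>\d+)N(?P<bc3>[ACGT]*)"
    r"(?:_(?P<batch>.+))?$"
)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class SelexLibraryName:
    gene_symbol: str
    barcode5: str
    insert_len: int
    barcode3: str
    batch: str | None = None

    def __post_init__(self) -> None:
        if self.insert_len <= 0:
            raise ValueError("insert_len must be positive")
        for bc in (self.barcode5, self.barcode3):
            if not set(bc) <= _ACGT:
                raise ValueError(f"barcode {bc!r} not over A/C/G/T")


@dataclass(frozen=True)
class SelexConstants:
    """Constant flanking primers of the sequencing construct and the number
    of context base pairs kept adjacent to the insert on each side."""

    primer5: str = ("TCCATCACGAATGATACGGCGACCACCGAACACTCTTTCCCTACACGACGCT"
                    "CTTCCGATC")
    primer3: str = "ATCGTATGCCGTCTTCTGCTTGCCGACTCCG"
    flank_len: int = 20

    def __post_init__(self) -> None:
        if self.flank_len <= 0:
            raise ValueError("flank_len must be positive")


@dataclass(frozen=True)
class SelexProtocolParams:
    """q: top score fraction used for the AUC (0.10 and 0.50 in routine use);
    subsample_cap: pooled-library size limit; negative_mode: how the negative
    set is obtained."""

    q: float = 0.10
    subsample_cap: int = 1_000_000
    negative_mode: str = "shuffled_inserts"  # or "input_library"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.q <= 1):
            raise ValueError("q must be in (0, 1]")


def parse_library_name(name: str) -> SelexLibraryName:
    """Split a library name GENE_{bc5}{len}N{bc3}[_batch] into its fields."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse SELEX library name {name!r}")
    return SelexLibraryName(
        gene_symbol=m.group("gene"),
        barcode5=m.group("bc5"),
        insert_len=int(m.group("len")),
        barcode3=m.group("bc3"),
        batch=m.group("batch"),
    )


def read_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTQ or FASTA (format chosen by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    fmt = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def write_fastq(reads: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read{i}\n{r}\n+\n{'I' * len(r)}\n")


def filter_reads(reads: Iterable[str], insert_len: int) -> list[str]:
    """Keep reads that are exactly ``insert_len`` long and A/C/G/T-only."""
    kept, total = [], 0
    for r in reads:
        total += 1
        if len(r) == insert_len and set(r) <= _ACGT:
            kept.append(r)
    if total - len(kept):
        logger.info("selex: filtered out %d of %d reads (length/alphabet)",
                    total - len(kept), total)
    return kept


def pool_dedup_subsample(cycles: Sequence[Sequence[str]],
                         params: SelexProtocolParams = SelexProtocolParams()
                         ) -> list[str]:
    """Pool reads from all cycles of one experiment, drop exact duplicates
    (first occurrence kept — duplicates are assumed PCR copies), then
    subsample uniformly to the cap when larger."""
    pooled = list(dict.fromkeys(r for cycle in cycles for r in cycle))
    if len(pooled) > params.subsample_cap:
        rng = np.random.default_rng(params.seed)
        idx = rng.choice(len(pooled), size=params.subsample_cap, replace=False)
        pooled = [pooled[i] for i in np.sort(idx)]
        logger.info("selex: subsampled pooled library to %d reads", len(pooled))
    return pooled


def flanks(libname: SelexLibraryName,
           consts: SelexConstants = SelexConstants()) -> tuple[str, str]:
    """The ``flank_len`` bases of primer+barcode context adjacent to the
    insert on each side."""
    left = (consts.primer5 + libname.barcode5)[-consts.flank_len:]
    right = (libname.barcode3 + consts.primer3)[:consts.flank_len]
    return left, right


def extend_insert(insert: str, libname: SelexLibraryName,
                  consts: SelexConstants = SelexConstants()) -> str:
    """Re-add the barcode/primer context around an insert, truncated to
    ``flank_len`` bp on each side."""
    if len(insert) != libname.insert_len:
        raise ValueError(
            f"insert length {len(insert)} != library insert_len "
            f"{libname.insert_len}")
    left, right = flanks(libname, consts)
    return left + insert + right


def extend_library(inserts: Sequence[str], libname: SelexLibraryName,
                   consts: SelexConstants = SelexConstants()) -> list[str]:
    return [extend_insert(r, libname, consts) for r in inserts]


def shuffle_negatives(extended_reads: Sequence[str], libname: SelexLibraryName,
                      consts: SelexConstants = SelexConstants(),
                      seed: int = 0) -> list[str]:
    """Mononucleotide-shuffle the insert of each extended read, leaving the
    flanking context untouched; per-read base composition of the insert is
    preserved exactly."""
    left, right = flanks(libname, consts)
    rng = np.random.default_rng(seed)
    out = []
    for read in extended_reads:
        insert = read[len(left):len(read) - len(right)]
        if len(insert) != libname.insert_len:
            raise ValueError("read does not match the extended-library layout")
        shuffled = "".join(np.array(list(insert))[rng.permutation(len(insert))])
        out.append(read[:len(left)] + shuffled + read[len(read) - len(right):])
    return out


def run_selex_benchmark(pos_lib: Sequence[str], neg_lib: Sequence[str],
                        pfm: PFM,
                        params: SelexProtocolParams = SelexProtocolParams(),
                        strand: StrandPolicy = StrandPolicy.both) -> float:
    """AUC ROC on the top-q fractions of the positive and negative sum
    occupancy score lists (applied to each list independently)."""
    if not pos_lib or not neg_lib:
        raise ValueError("both libraries must be non-empty")
    pos = top_fraction(batch_sum_occupancy(list(pos_lib), pfm, strand), params.q)
    neg = top_fraction(batch_sum_occupancy(list(neg_lib), pfm, strand), params.q)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("top-fraction score sets are empty")
    return roc_auc(pos, neg)
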