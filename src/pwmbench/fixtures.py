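"""Seeded synthetic-data generators with planted ground truth.

Every benchmarking input format (genome FASTA + peak BED, per-cycle SELEX
read libraries, normalized PBM probe tables, MEME motif collections) can be
emulated offline with a known generating PFM, so the protocols and the rank
aggregation can be validated by recovery: the planted matrix should win.

The generators model planted consensus-like sites in an i.i.d. mononucleotide
background; they do not model read errors, nucleosome positioning, probe
de Bruijn structure, or PCR bias.  All generators are deterministic given
their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import PerformanceMatrix
from .chipseq import ChipProtocolParams, Peak, extract_pairs, write_peaks
from .motif_io import BASES, PFM, write_meme_collection
from .pbm import PbmProbe, PbmParams, write_uniprobe_table
from .scoring import (StrandPolicy, batch_log_sum_occupancy,
                      batch_sum_occupancy, encode_sequences, roc_auc,
                      top_fraction)
from .selex import (SelexConstants, SelexLibraryName, extend_library, flanks,
                    shuffle_negatives)


@dataclass
class PlantedTruth:
    """The generating motif and planting regime of a synthetic experiment."""

    true_pfm: PFM
    planting_rate: float = 1.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.planting_rate <= 1):
            raise ValueError("planting_rate must be in [0, 1]")
        self.background = np.asarray(self.background, dtype=float)
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background must sum to 1")


def random_pfm(L: int, concentration: float = 0.5, seed: int = 0,
               matrix_id: str = "synthetic") -> PFM:
    """PFM with positions drawn i.i.d. from a symmetric Dirichlet; smaller
    concentration gives more peaked (higher-information) columns."""
    if L < 1 or concentration <= 0:
        raise ValueError("need L >= 1 and concentration > 0")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(4, concentration), size=L)
    return PFM(matrix_id, probs, source="synthetic")


def noisy_copy(pfm: PFM, noise: float, seed: int,
               matrix_id: str | None = None) -> PFM:
    """Mix each position with a random distribution: (1-noise)*p + noise*u."""
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(4), size=pfm.length)
    probs = (1.0 - noise) * pfm.probs + noise * u
    return PFM(matrix_id or f"{pfm.matrix_id}_noisy", probs, source="synthetic")


def random_sequence(rng: np.random.Generator, length: int,
                    bg: np.ndarray | None = None) -> str:
    bg = np.full(4, 0.25) if bg is None else np.asarray(bg, dtype=float)
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=bg))


def sample_site(rng: np.random.Generator, pfm: PFM) -> str:
    """Draw one binding-site word from the PFM's per-position distributions."""
    return "".join(BASES[rng.choice(4, p=row / row.sum())]
                   for row in pfm.probs)


def write_fasta(genome: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# ChIP-seq fixture
# ---------------------------------------------------------------------------

@dataclass
class ChipFixture:
    genome: dict[str, str]
    peaks: list[Peak]
    planted: np.ndarray  # bool per peak, in peak order


def synth_chipseq(truth: PlantedTruth, n_peaks: int, genome_len: int,
                  params: ChipProtocolParams = ChipProtocolParams(),
                  out_dir: str | Path | None = None,
                  chrom: str = "chr1") -> ChipFixture:
    """Background genome with evenly spaced peak anchors; a site sampled from
    the true PFM is planted at each anchor with probability
    ``planting_rate``, and planted peaks receive higher scores.

    Anchors are spaced widely enough that a peak's displaced negative-control
    window cannot contain a neighbouring planted site.
    """
    rng = np.random.default_rng(truth.seed)
    L = truth.true_pfm.length
    spacing = genome_len // (n_peaks + 1)
    needed = 2 * params.w + abs(params.d) + L + 10
    if spacing < needed:
        raise ValueError(
            f"genome_len {genome_len} too small for {n_peaks} peaks "
            f"(spacing {spacing} < required {needed})")
    seq = list(random_sequence(rng, genome_len, truth.background))
    peaks: list[Peak] = []
    planted = np.zeros(n_peaks, dtype=bool)
    for i in range(n_peaks):
        anchor = spacing * (i + 1)
        is_planted = bool(rng.random() < truth.planting_rate)
        planted[i] = is_planted
        if is_planted:
            site = sample_site(rng, truth.true_pfm)
            start = anchor - L // 2
            seq[start:start + L] = list(site)
        score = rng.normal(8.0, 1.0) if is_planted else rng.normal(4.0, 1.0)
        half = min(100, spacing // 4)
        peaks.append(Peak(chrom, anchor - half, anchor + half, float(score),
                          name=f"peak{i}", summit=half))
    genome = {chrom: "".join(seq)}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out_dir / "genome.fa")
        write_peaks(peaks, out_dir / "peaks.bed")
    return ChipFixture(genome, peaks, planted)


# ---------------------------------------------------------------------------
# HT-SELEX fixtures
# ---------------------------------------------------------------------------

def synth_selex(truth: PlantedTruth, libname: SelexLibraryName, n_reads: int,
                rounds: int) -> list[list[str]]:
    """Per-cycle insert libraries under iterative selection.

    Cycle 0 is uniform random; each subsequent cycle resamples (with
    replacement) from the previous one with probability proportional to the
    insert's sum occupancy under the true PFM, giving geometric enrichment.
    """
    rng = np.random.default_rng(truth.seed)
    cycle = [random_sequence(rng, libname.insert_len, truth.background)
             for _ in range(n_reads)]
    cycles = [cycle]
    for _ in range(rounds):
        occ = batch_sum_occupancy(cycle, truth.true_pfm)
        p = occ / occ.sum()
        idx = rng.choice(len(cycle), size=n_reads, replace=True, p=p)
        cycle = [cycle[i] for i in idx]
        cycles.append(cycle)
    return cycles


def synth_selex_planted(truth: PlantedTruth, libname: SelexLibraryName,
                        n_reads: int) -> list[str]:
    """Weak-enrichment library: a fraction ``planting_rate`` of inserts carry
    a site sampled from the true PFM at a random position; the rest are
    background."""
    rng = np.random.default_rng(truth.seed)
    L = truth.true_pfm.length
    if L > libname.insert_len:
        raise ValueError("motif longer than the insert")
    reads = []
    for _ in range(n_reads):
        insert = list(random_sequence(rng, libname.insert_len,
                                      truth.background))
        if rng.random() < truth.planting_rate:
            pos = int(rng.integers(0, libname.insert_len - L + 1))
            insert[pos:pos + L] = list(sample_site(rng, truth.true_pfm))
        reads.append("".join(insert))
    return reads


def boundary_truth(libname: SelexLibraryName,
                   consts: SelexConstants = SelexConstants(),
                   overlap: int = 4, core_len: int = 6,
                   concentration: float = 0.2, seed: int = 0,
                   matrix_id: str = "straddle") -> PFM:
    """A motif that straddles the insert boundary: its first ``overlap``
    positions are near-deterministic matches to the last bases of the 5'
    flank, followed by ``core_len`` informative random positions that fall
    inside the insert when the core is planted at insert position 0."""
    left, _ = flanks(libname, consts)
    rng_core = random_pfm(core_len, concentration, seed, matrix_id)
    eps = 0.01
    flank_cols = np.full((overlap, 4), eps)
    for i, base in enumerate(left[-overlap:]):
        flank_cols[i, BASES.index(base)] = 1.0 - 3 * eps
    return PFM(matrix_id, np.vstack([flank_cols, rng_core.probs]),
               source="synthetic")


def synth_selex_boundary(libname: SelexLibraryName, n_reads: int,
                         planted_fraction: float, seed: int,
                         consts: SelexConstants = SelexConstants(),
                         overlap: int = 4, core_len: int = 6
                         ) -> tuple[PFM, list[str]]:
    """Library whose planted signal is the insert-resident *core* of a
    boundary-straddling motif, planted flush at insert position 0 so the full
    site only exists in barcode/primer-extended reads."""
    truth = boundary_truth(libname, consts, overlap, core_len, seed=seed)
    core = PFM("core", truth.probs[overlap:], source="synthetic")
    rng = np.random.default_rng(seed)
    reads = []
    for _ in range(n_reads):
        insert = list(random_sequence(rng, libname.insert_len))
        if rng.random() < planted_fraction:
            insert[:core_len] = list(sample_site(rng, core))
        reads.append("".join(insert))
    return truth, reads


# ---------------------------------------------------------------------------
# PBM fixture
# ---------------------------------------------------------------------------

def synth_pbm(truth: PlantedTruth, n_probes: int, probe_len: int = 60,
              noise_sd: float = 0.5, seed: int | None = None,
              params: PbmParams = PbmParams(),
              plant_fraction: float = 0.3) -> list[PbmProbe]:
    """Probe table whose log intensities are the true PFM's log sum occupancy
    over the scored prefix (standardized to unit spread, so ``noise_sd`` is
    expressed relative to the signal standard deviation) plus Gaussian noise;
    a fraction of probes carries a planted site inside the prefix to widen
    the dynamic range."""
    if probe_len < params.prefix_len:
        raise ValueError(f"probe_len must be >= {params.prefix_len}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    L = truth.true_pfm.length
    seqs = []
    for _ in range(n_probes):
        probe = list(random_sequence(rng, probe_len, truth.background))
        if rng.random() < plant_fraction:
            pos = int(rng.integers(0, params.prefix_len - L + 1))
            probe[pos:pos + L] = list(sample_site(rng, truth.true_pfm))
        seqs.append("".join(probe))
    log_occ = batch_log_sum_occupancy([s[: params.prefix_len] for s in seqs],
                                      truth.true_pfm)
    spread = log_occ.std()
    signal = (log_occ - log_occ.mean()) / spread if spread > 0 else log_occ
    log_intensity = signal + rng.normal(0.0, noise_sd, size=n_probes)
    return [PbmProbe(s, float(np.exp(v)))
            for s, v in zip(seqs, log_intensity)]


# ---------------------------------------------------------------------------
# Best-matrix recovery cohort (all three protocols end-to-end)
# ---------------------------------------------------------------------------

#: desk-scale protocol parameters used by the recovery cohort: the full-scale
#: region width and negative offset are kept, the top-N and minimum-peak
#: requirements are scaled to the fixture size
RECOVERY_CHIP_PARAMS = ChipProtocolParams(w=250, N=200, d=500, min_peaks=100)


@dataclass
class RecoveryCohort:
    truths: dict[str, str]          # gene symbol -> generating matrix_id
    candidates: list[PFM]           # truths + decoys, benchmark candidates
    perf: PerformanceMatrix


def _eval_auc(pos_seqs: list[str], neg_seqs: list[str],
              candidates: Sequence[PFM], q: float = 1.0) -> dict[str, float]:
    """AUC per candidate, reusing one encoding of each sequence set."""
    enc_pos = encode_sequences(pos_seqs)
    enc_neg = encode_sequences(neg_seqs)
    out = {}
    for m in candidates:
        pos = batch_sum_occupancy(pos_seqs, m, enc=enc_pos)
        neg = batch_sum_occupancy(neg_seqs, m, enc=enc_neg)
        if q < 1.0:
            pos, neg = top_fraction(pos, q), top_fraction(neg, q)
        out[m.matrix_id] = roc_auc(pos, neg)
    return out


def _eval_pbm(probes: Sequence[PbmProbe], candidates: Sequence[PFM],
              params: PbmParams = PbmParams()) -> dict[str, float]:
    prefixes = [p.sequence[: params.prefix_len] for p in probes]
    enc = encode_sequences(prefixes)
    log_intensity = np.log([p.intensity for p in probes])
    out = {}
    for m in candidates:
        scores = np.log(batch_sum_occupancy(prefixes, m, enc=enc))
        out[m.matrix_id] = float(np.corrcoef(scores, log_intensity)[0, 1])
    return out


def build_recovery_cohort(seed: int, n_tfs: int = 8, n_decoys: int = 32,
                          motif_len: int = 9, concentration: float = 0.3,
                          n_peaks: int = 250, genome_len: int = 420_000,
                          n_chip: int = 3, selex_reads: int = 3000,
                          pbm_probes: int = 400) -> RecoveryCohort:
    """Generate a full synthetic cohort and benchmark every candidate matrix
    on every experiment: per TF, ``n_chip`` ChIP-seq peak lists, one SELEX
    library scored at the top-10% cut-off and one at top-50%, and one PBM
    table; candidates are the generating PFMs plus unrelated decoys."""
    rng = np.random.default_rng(seed)
    genes = [f"TF{i + 1}" for i in range(n_tfs)]
    truths = {g: random_pfm(motif_len, concentration,
                            seed=int(rng.integers(2 ** 31)),
                            matrix_id=f"M_{g}") for g in genes}
    decoys = [random_pfm(motif_len, concentration,
                         seed=int(rng.integers(2 ** 31)),
                         matrix_id=f"D{i + 1:02d}") for i in range(n_decoys)]
    candidates = list(truths.values()) + decoys

    rows: list[dict] = []
    for g in genes:
        for rep in range(n_chip):
            fx = synth_chipseq(
                PlantedTruth(truths[g], 0.85, seed=int(rng.integers(2 ** 31))),
                n_peaks, genome_len, RECOVERY_CHIP_PARAMS)
            pos, neg = extract_pairs(fx.peaks, fx.genome, RECOVERY_CHIP_PARAMS)
            for mid, auc in _eval_auc(pos, neg, candidates).items():
                rows.append(dict(experiment_id=f"{g}_chip{rep}",
                                 gene_symbol=g, assay="chipseq",
                                 matrix_id=mid, value=auc))
        libname = SelexLibraryName(g, "TCGGGG", 20, "GGT")
        for assay, q in (("selex10", 0.10), ("selex50", 0.50)):
            sel_truth = PlantedTruth(truths[g], planting_rate=0.15,
                                     seed=int(rng.integers(2 ** 31)))
            inserts = synth_selex_planted(sel_truth, libname, selex_reads)
            extended = extend_library(inserts, libname)
            negs = shuffle_negatives(extended, libname,
                                     seed=int(rng.integers(2 ** 31)))
            for mid, auc in _eval_auc(extended, negs, candidates, q=q).items():
                rows.append(dict(experiment_id=f"{g}_{assay}", gene_symbol=g,
                                 assay=assay, matrix_id=mid, value=auc))
        probes = synth_pbm(PlantedTruth(truths[g], seed=int(
            rng.integers(2 ** 31))), pbm_probes, noise_sd=0.5)
        for mid, r in _eval_pbm(probes, candidates).items():
            rows.append(dict(experiment_id=f"{g}_pbm", gene_symbol=g,
                             assay="pbm", matrix_id=mid, value=r))
    perf = PerformanceMatrix.from_long(pd.DataFrame(rows))
    return RecoveryCohort({g: truths[g].matrix_id for g in genes},
                          candidates, perf)


@dataclass
class FamilyCohort:
    """One motif family (noisy copies of a truth) plus unrelated motifs,
    benchmarked on several ChIP-seq datasets from the same truth."""

    candidates: list[PFM]           # regularized: noisy copies + unrelated
    dataset_aucs: list[dict[str, float]]  # per dataset: matrix_id -> AUC
    perf: PerformanceMatrix


def build_family_cohort(seed: int, n_noisy: int = 5, n_unrelated: int = 5,
                        motif_len: int = 8, n_datasets: int = 3,
                        n_peaks: int = 200, genome_len: int = 340_000
                        ) -> FamilyCohort:
    """Cohort for comparing benchmark-based and clustering-based motif
    selection: noise levels of the family copies are spread so the
    benchmarks can order them."""
    from .motif_io import regularize

    truth_pfm = random_pfm(motif_len, 0.3, 3000 + seed, "truth")
    noises = np.linspace(0.05, 0.65, n_noisy)
    family = [noisy_copy(truth_pfm, float(nz), 100 * seed + i, f"N{i + 1}")
              for i, nz in enumerate(noises)]
    unrelated = [random_pfm(motif_len, 0.3, 5000 + 100 * seed + i, f"U{i + 1}")
                 for i in range(n_unrelated)]
    candidates = [regularize(p) for p in family + unrelated]
    rows, dataset_aucs = [], []
    for ds in range(n_datasets):
        fx = synth_chipseq(PlantedTruth(truth_pfm, 0.9, seed=10 * seed + ds),
                           n_peaks, genome_len, RECOVERY_CHIP_PARAMS)
        pos, neg = extract_pairs(fx.peaks, fx.genome, RECOVERY_CHIP_PARAMS)
        res = _eval_auc(pos, neg, candidates)
        dataset_aucs.append(res)
        rows += [dict(experiment_id=f"d{ds}", gene_symbol="TF1",
                      assay="chipseq", matrix_id=mid, value=v)
                 for mid, v in res.items()]
    return FamilyCohort(candidates, dataset_aucs,
                        PerformanceMatrix.from_long(pd.DataFrame(rows)))


def write_cohort(cohort: RecoveryCohort, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_meme_collection(cohort.candidates, out_dir / "candidates.meme")
    cohort.perf.to_long().to_csv(out_dir / "performance.tsv", sep="\t",
                                 index=False)
    pd.Series(cohort.truths, name="matrix_id").rename_axis(
        "gene_symbol").to_csv(out_dir / "planted_truth.tsv", sep="\t")
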