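# Methods

## Scope

`pwmbench` evaluates position weight matrices (PWMs) against three kinds of
experimental data — ChIP-seq peak lists, HT-SELEX read libraries and
protein-binding microarray (PBM) probe tables — and aggregates the resulting
performance values to pick, per transcription factor, the matrix that
predicts its binding best.  A second, benchmark-blind route groups motifs by
the similarity of the word sets they recognize and picks a representative
per cluster; the package lets the two selection strategies be compared on
synthetic data with planted ground truth.

## Matrix model

A motif of length L is a position frequency matrix (PFM): one probability
distribution over (A, C, G, T) per position, positions independent.  Before
any scoring, every matrix is regularized by adding a pseudocount
`eps = 1e-4` to each entry followed by per-position renormalization,
`p' = (p + eps) / (1 + 4 eps)`.  This guarantees strictly positive entries,
so logarithms exist; it also slightly flattens over-confident public
matrices.  The log-ratio weight representation
`w[b,i] = log(p[b,i] / q[b])` against a background `q` (uniform by default)
is provided for completeness and round-trips exactly; all benchmark scoring
uses the probabilities directly, so the choice of log base (natural log by
default) cannot affect any benchmark result.

## Sum occupancy score

For a sequence S longer than the motif, the binding score is the *sum
occupancy score*: the sum over all length-L windows of the window's
probability under the PFM, scanning both strands by default (scanning the
reverse strand is implemented as scanning the forward strand with the
reverse-complemented matrix).  It is threshold-free: one strong site or
several weak sites both raise the score.  `N` bases contribute the uniform
background probability 0.25 at their position; other ambiguity codes are
rejected.  Strand policy is exposed (`both` / `forward_only`) because a
single-stranded variant is occasionally useful for diagnostics; `both` is
the default used everywhere.

## Protocols

**ChIP-seq.**  Each peak is reduced to a single anchor: the recorded summit
if present, else the floor mid-point.  The N top-scoring peaks (ties at the
boundary broken by chromosome then start, for determinism) give positive
windows `[a-w, a+w]` — inclusive on both ends, hence 2w+1 bp — and negative
windows of the same size displaced by a signed offset d.  Defaults
w = 250 bp, N = 2000, d = +500 bp, and a 5000-peak minimum for a usable
experiment.  Pairs whose windows leave the chromosome, or are more than 50%
N, are dropped together, keeping the sets paired and equal-sized.
Negatives that happen to overlap another peak are *not* excluded; this is a
known caveat of the fixed-offset design.  Performance is the rank-based
(Mann–Whitney) AUC ROC of positives versus negatives, computed from
mid-ranks so ties contribute exactly one half.

**HT-SELEX.**  Library names of the form `GENE_{bc5}{len}N{bc3}[_batch]`
carry the 5'/3' barcodes and insert length.  Reads are kept only if exactly
insert-length long and A/C/G/T-only; cycles of one experiment are pooled;
exact duplicates are removed (first occurrence kept, treating copies as PCR
clones); pools beyond one million reads are subsampled to that cap with the
run's seed.  Each insert is then re-embedded in its sequencing context:
the last 20 bp of (5' primer + 5' barcode) on the left and the first 20 bp
of (3' barcode + 3' primer) on the right, because sites straddling the
insert boundary are invisible to insert-only scanning.  Negatives default
to per-read mononucleotide shuffling of the insert (flanks untouched,
per-read composition preserved exactly); an input (cycle-0) library can be
supplied instead.  Because selection pools are often only weakly enriched,
the AUC is computed on the top fraction q of each score list separately
(q = 0.10 and 0.50 in routine use; `ceil(q n)` scores, boundary ties broken
by stable input order).

**PBM.**  Probe tables are two whitespace-delimited columns — normalized
intensity and probe sequence, either order, auto-detected — with
non-positive intensities dropped (logs must exist).  Only the first 41 bp
of each probe are scored (the remainder is fixed linker); probes shorter
than 41 nt are skipped with a warning.  Performance is the Pearson
correlation between log sum occupancy and natural-log intensity; both logs
make the value invariant to intensity rescaling and occupancy scaling.

## Rank aggregation and reporting

Within each experiment row of the performance matrix, values are converted
to ranks (rank 1 = best, ties get the average of the spanned ranks,
unevaluated matrices excluded rather than imputed).  A matrix's *aggregate
rank score* for a gene is the geometric mean of its ranks over the gene's
experiments, computed per assay group (chipseq, selex10, selex50, pbm) and
pooled over all assays for a globally best pick; lower is better and 1 is
optimal.  Note the rank direction: since rank 1 is best, "best aggregate
rank" means the *minimal* geometric-mean rank.  Ties are broken by higher
mean raw performance, then lexicographic matrix id.  Reports can be
restricted by quality thresholds — best raw value strictly greater than
0.75 (AUC assays) or 0.35 (PBM r), a gene passing if any assay passes — and
collapsed into a non-redundant library (union of best matrices over genes).
Family-level tables average all values of matrices from one family against
experiments whose TF belongs to another, omitting families with fewer than
2 matrices or 2 datasets.

## Motif clustering

A motif "recognizes" the set of L-mers whose log probability reaches a
threshold chosen so that the tail probability of the word-score
distribution under a uniform background is at most a target p-value
(default 5e-4, configurable; tests pin it explicitly).  The distribution is
computed exactly by enumerating all 4^L scores for L ≤ 12, and by
position-wise convolution with scores binned at width 0.01 (natural-log
units) above that; if even the best word exceeds the p-value, its score is
used with a warning.  Word sets are enumerated by depth-first search with
best-possible-suffix pruning and a configurable size cap.

The distance between two motifs is 1 minus the maximal Jaccard index of
their word sets over all alignment offsets with at least one overlapping
column and both orientations.  Over an aligned span, positions outside a
motif's own columns are unconstrained for that motif, so each set extends
to `|W| * 4^(free positions)` span-words and the intersection is counted by
grouping words on the overlap columns — no span enumeration is needed.
Clustering is UPGMA on raw distances, halting before any merge whose
average inter-cluster distance reaches 0.95; minimal-distance ties are
broken by the lexicographically smallest member pair.  Each cluster is
represented by its medoid (minimal mean distance to the other members,
lexicographic tie-break).

## Synthetic data

The generators emulate every input format with planted ground truth and are
bitwise reproducible per seed:

- **Motifs** are drawn with i.i.d. symmetric-Dirichlet positions; the
  concentration sets informativeness (0.3 for "realistic" motifs of ~0.8–1
  bit/position, 0.05 for near-consensus motifs used where a planted
  consensus is wanted).
- **ChIP-seq**: an i.i.d. background genome with evenly spaced anchors;
  a site *sampled from the true PFM* is planted at each anchor with the
  planting rate (0.85 in the recovery cohort), and planted peaks draw
  higher scores (Normal(8,1) vs Normal(4,1)).  Anchor spacing is checked so
  displaced negative windows cannot reach a neighbouring planted site.
- **HT-SELEX**: either iterative selection (resampling each cycle with
  probability proportional to true-PFM occupancy) or a weak-enrichment
  library with a fixed fraction of site-carrying inserts (10–15% in the
  fixtures); a boundary variant plants the insert-resident core of a motif
  whose first positions match the 5' flank, flush at insert position 0.
- **PBM**: random probes, 30% with a planted site inside the scored prefix;
  log intensity is the true PFM's log occupancy standardized to unit
  spread, plus Gaussian noise — `noise_sd` is therefore expressed relative
  to the signal standard deviation (0.5 in routine fixtures, i.e. an
  expected attenuation to r ≈ 0.89).

The recovery cohort runs the full loop at desk scale: 8 TFs, per TF three
ChIP-seq lists (250 peaks, top-200 used, w = 250, d = +500), one SELEX
library scored at q = 0.10 and one at q = 0.50 (2000 reads of 20 bp,
extended and shuffled), and one PBM table (400 probes), against 40
candidate matrices (the 8 generating PFMs plus 32 unrelated decoys).
These sizes are the package's chosen study conditions for synthetic
validation; the protocol parameters themselves keep their full-scale
defaults except top-N and the minimum-peak gate, which are scaled to the
fixture size.

What the generators do *not* model: read errors, PCR bias beyond exact
duplicates, nucleosome or chromatin context, de Bruijn probe structure,
dinucleotide background correlation, and GC heterogeneity (a GC-skewed
background is available but not default).  Passing recovery tests therefore
demonstrates the machinery's correctness and calibration, not performance
on real data.

## Numerical choices

- Scoring is done in log space and exponentiated per window; batch scoring
  encodes each sequence set once and reuses the encoding across matrices.
- AUC uses the rank method, never a thresholded curve, so the Mann–Whitney
  pair-counting identity holds exactly (verified against brute force).
- Word-set membership compares scores with a 1e-9 slack because different
  summation orders of the same log probabilities can differ in the last ulp.
- Geometric means of a single rank return that rank exactly.
- MEME files are written with six decimals and `nsites=1000000` so
  count-reconstructing readers stay lossless to write precision; parsed
  columns off unity by ≤1e-3 are renormalized with a warning, worse
  deviations are errors.
- Peak scores are written with `repr` precision so BED round-trips are
  lossless.

## Known limitations

- The fixed-offset ChIP-seq negatives can overlap true bound regions in
  dense clusters; no exclusion is applied by design.
- The word-set p-value convention and the use of both orientations in the
  Jaccard distance are parameters, not fixed truths; defaults are 5e-4 and
  both-orientations.
- `StrandPolicy.forward_only` halves palindromic-motif scores by
  construction; it exists for diagnostics only.
- The binned score distribution (L > 12) makes thresholds conservative to
  within the bin width times motif length.
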