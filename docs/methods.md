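# Methods

`fmribic` evaluates biclustering of parcellated fMRI data stored as
Region × Time matrices `A` (n region rows, p time-point columns).  A
bicluster `B = (I, J)` is a submatrix selected by a row set `I` and a
column set `J`.  This note records the models, conventions and numerical
choices behind the package; the README shows how to run it.

## Pattern families

Three coherence families are distinguished, following the standard
biclustering taxonomy:

- **constant**: `b_ij = π`
- **shifting** (additive): `b_ij = π_i + β_j`
- **scaling** (multiplicative): `b_ij = π_i · β_j`

## Quality indices

All four indices are means over the `|I| × |J|` cells of a materialized
bicluster (original data values, never discretized ones):

- **VAR** `= mean((b_ij − b_IJ)²)` — zero only for constant biclusters.
  The centering constant `b_IJ` is the bicluster's own mean by default.
  The phrase "global mean" is ambiguous between the bicluster and the
  whole matrix; the bicluster reading makes VAR a proper constancy
  measure (Hartigan's variance criterion), so it is the default, with the
  matrix-mean reading available as `variance(b, grand_mean=...)`.
- **MSR** `= mean((b_ij − b_iJ − b_Ij + b_IJ)²)` — zero for every
  shifting bicluster; invariant under per-row and per-column shifts.
- **SMSR** `= mean((b_iJ·b_Ij − b_ij·b_IJ)² / (b_iJ²·b_Ij²))` — zero for
  every scaling bicluster with nonzero means.  When any row or column
  mean is exactly zero the index is *undefined* and reported as missing
  (NaN), excluded pairwise from summaries and correlations.  Epsilon-
  padding the denominator was rejected: it manufactures arbitrary
  magnitudes instead of admitting the index does not apply.
- **VE (virtual error)**: rows are z-scored with the *population*
  standard deviation (a descriptive normalizer, not an inferential
  estimate), the *virtual pattern* `ρ̂_j` is the column-wise mean of the
  standardized rows, and `VE = mean(|b̂_ij − ρ̂_j|)`.  VE is zero whenever
  the rows are positive affine transforms of one another, which covers
  shifting and positive-scaling patterns alike, and it grows roughly
  linearly with injected noise.

Degenerate rows (zero spread) are standardized to all-zero rows and
flagged, so a perfectly constant bicluster scores VE = 0 (constant is a
degenerate shifting pattern) rather than raising a division error.
Exact constancy is detected by a zero row *range*, not a zero standard
deviation: a row of identical floats can have sd ≈ 1e-16 when its mean
rounds inexactly, and z-scoring that rounding noise would turn a perfect
block into an apparently incoherent one.  Degenerate rows stay in the VE
average (as zeros-versus-pattern differences).

## Post-processing protocol

Raw algorithm output is always (1) materialized onto the original matrix
values, (2) stripped of biclusters with fewer than two rows or columns,
(3) deduplicated on exact (scan, I, J) — first occurrence wins, so
repeated stochastic runs never multiply-count a bicluster — and
(4) pooled across the scans of a collection.  Pooling happens after
deduplication; collection statistics are computed over the pooled set.

## Algorithms

- **CCC** (exhaustive, contiguous columns): all maximal biclusters whose
  rows carry an identical symbol string over a contiguous column
  interval.  Implemented by interval enumeration with incremental row
  grouping — O(p²·n) hashing work — rather than suffix trees; the output
  equivalence class is identical and the implementation is verifiable
  against a brute-force oracle at small sizes.  With transition symbols,
  symbol interval `[j1..j2]` maps back to time points `[j1..j2+1]`; this
  off-by-one is covered by a dedicated test because getting it wrong
  silently corrupts every downstream result.
- **Bimax-style**: inclusion-maximal all-ones submatrices of a binarized
  matrix.  These are exactly the closed (row set, column set) pairs of
  the binary relation, enumerated by a prefix-preserving closure DFS
  (columns visited in decreasing density).  On noisy 30×150 matrices the
  number of maximal all-ones submatrices can reach millions, so the DFS
  stops at an exploration cap (default 5× `max_biclusters`) and the
  largest-area-first truncation is then best-effort; at oracle scale
  (n, p ≤ 8) the enumeration is exact and tested against brute force.
- **xMotifs-style greedy**: random seed columns plus random
  discriminating column subsets group rows by their symbol string over
  the selected columns; each agreeing group is extended to every column
  on which it stays conserved.  This is a simplified conserved-state
  search faithful to the greedy random-projection idea, not a
  byte-identical replica of the original tool.
- **Clustering baselines**: k-means and Ward on row profiles (region
  clustering) or column profiles (temporal clustering), each cluster
  viewed as a bicluster spanning the full other dimension.  The wrappers
  return the complete partition; the ≥2×2 filter is applied at
  evaluation time, so a k = p temporal clustering legitimately yields an
  empty evaluated set while the partition contract still holds.
- **Repeated runs**: stochastic algorithms are run `n_runs` times
  (default 30) with seeds derived from one master seed, then pooled and
  deduplicated.

Discretizations: per-row equal-width binning into k symbols (top bin
right-closed, constant rows → symbol 0); transition coding of
consecutive-time-point differences (2 symbols: sign; 3 symbols: NoChange
within `t = 0.2` row-sd, else Up/Down); row-wise binarization above the
row median (strict) or above mean + c·sd.  The symbol counts follow the
chosen study configurations (5 symbols row-wise, 2–3 transition symbols,
binary for Bimax); bin placement itself is a package convention since
only the symbol counts are prescribed.

## Synthetic data

Each scan = smooth per-region baseline + planted blocks + i.i.d.
Gaussian noise.  The baseline is Gaussian-filtered white noise (kernel
sd 3 time points) rescaled to mean `baseline_mean` (default 0) and sd
`baseline_amplitude` (default 1) per region — a transparent stand-in for
slow spontaneous fluctuations of parcellated BOLD signals.  Defaults
mirror the artificial-collection geometry: 20 scans of 30 regions × 150
time points; a 463 × 94 real-scale preset exists for scalability checks.
Noise sd defaults to 0.1 (10% of baseline amplitude) — the amplitude and
noise level of the original simulated scans are not published, so these
are package conventions, chosen once.

Planted blocks overwrite the baseline by default (a superposition flag
exists), which makes the zero-noise identities exact: VAR = 0 for
constant, MSR = VE = 0 for shifting, SMSR = VE = 0 for scaling blocks.
Effect distributions are deliberate:

- *Shifting*: row offsets `π_i ~ N(0, amp)`; time profile `β_j` with
  alternating signs and magnitudes `U(0.5, 1.5)·amp` — event-like on/off
  responses.  Consecutive time-point changes are therefore ≥ amp, far
  above the 5%-of-amplitude noise regime used in the recovery studies,
  and the jagged signature is essentially impossible for a smooth
  background row to match by chance.  Smooth (random-walk) profiles
  would put a few percent of in-block transitions below any realistic
  noise floor and make symbolic recovery of the *true* block impossible
  for any method.
- *Scaling*: strictly positive log-uniform gains `π_i, β_j ∈ [1/3, 3]`
  (9-fold dynamic range).  With near-unit gains a multiplicative block
  is numerically indistinguishable from an additive one (its additive
  residue `var(π)·var(β)` vanishes), so wide gains are what makes the
  scaling family a genuinely distinct hypothesis.  A flag allows
  negative gains for adversarial tests (VE is sign-sensitive).
- *Constant*: plateau level `±U(2.5, 3.5)·amp`, well outside the
  baseline range so the block occupies its own symbol under row-wise
  binning.

Ground truth is returned with final index sets; recovery is the Jaccard
index of cell sets, and `best_recovery` takes the maximum over a found
set.

What the generator does *not* model: hemodynamic response convolution,
spatial autocorrelation between regions, inter-subject variability,
scanner drift and motion artefacts.  Passing recovery and comparison
tests on these collections therefore demonstrates correctness of the
machinery and qualitative behaviour of the indices, not performance on
real BOLD data.

## Evaluation pipeline

Summaries report median ± sample standard deviation per algorithm (sd of
a single value is 0).  Top-K selection removes records with VE < 0.01
(near-zero VE on real output is typically an artifact of tiny or
degenerate biclusters), sorts ascending by VE — ties broken by larger
area, then input order, for a reproducible ordering — and keeps K
(50 at artificial scale, 500 at real scale).  Size summaries take the
median of the area distribution itself, not the product of medians.

Pattern-type inference computes the squared Pearson correlation of VE
with VAR, MSR and SMSR across a bicluster population (pairwise-complete;
a zero-variance partner gives r² = 0) and labels the population by the
argmax: VAR → constant, MSR → shifting, SMSR → scaling;
fewer than 3 usable records or all r² below 0.01 → undetermined.
The inference studies use a *dilution* population — each planted block
plus variants with extra background rows and columns — emulating the
imperfect output of a real search; the dilution gradient is what makes
all indices vary jointly with VE.  Scaling-family studies run on a
positive-mean background (`baseline_mean = 2`): multiplicative structure,
like SMSR's denominators, is only meaningful for signals bounded away
from zero, and raw BOLD values are positive.

Group comparisons pool records across algorithms within each super-group
(biclustering / region clustering / temporal clustering) and compare
pooled medians; no significance testing is attached.

## Problem sizes and determinism

The bundled studies use 20-scan collections at full 30 × 150 geometry
for recovery, and 6-scan collections for the full algorithm-suite
benchmark; both finish in tens of seconds on one CPU while leaving the
qualitative ordering of the methods unchanged.  Every source of
randomness flows from one master seed (per-scan and per-run seeds are
derived deterministically and kept below 2³¹), outputs are sorted and
newline-terminated, and identical configuration + seed reproduces every
file byte for byte.

## Known limitations

- A planted block whose boundary transition happens to carry the same
  symbol in *every* block row (probability ≈ 2·k⁻|I| per boundary) is
  reported by CCC with a one-column maximal extension; its best Jaccard
  recovery is then |J|/(|J|+1), not 1.0.  This is correct maximal-
  bicluster semantics, not a bug, and is why zero-noise recovery is
  asserted on the median and the overwhelming majority of blocks.
- Bimax-style truncation beyond the exploration cap is best-effort (the
  global largest-area guarantee requires full enumeration).
- SMSR is numerically fragile near zero row/column means by
  construction; it is reported as missing there rather than stabilized.
- External algorithms (BicPAM, FABIA, ISA, spectral biclustering) enter
  only through the JSON import adapter; the package does not
  re-implement them.
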