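# fmribic

Biclustering evaluation for parcellated fMRI data.

Functional MRI scans, once parcellated with a cortical atlas, become
Region × Time matrices: `n` brain regions observed over `p` time points.
Clustering such a matrix groups whole rows (regions) or whole columns
(time points); *biclustering* relaxes both constraints at once and looks
for submatrices `(I, J)` — subsets of regions coherent over subsets of
time — which is the natural shape of transient, spatially local brain
activity.  `fmribic` is for researchers who want to run and *compare*
biclustering and clustering approaches on this kind of data (the same
machinery applies to any samples × conditions matrix, e.g. gene
expression): it provides the internal quality indices used for the
comparison, reference algorithm implementations, clustering baselines,
a synthetic generator with planted ground truth, and the study-level
reporting pipeline.

## The indices

For a bicluster `B` with rows `I`, columns `J`, cell values `b_ij`, row
means `b_iJ`, column means `b_Ij` and overall mean `b_IJ`:

- **VAR** `= (1/|I||J|) Σ (b_ij − b_IJ)²` — zero only for *constant*
  patterns `b_ij = π`.
- **MSR** `= (1/|I||J|) Σ (b_ij − b_iJ − b_Ij + b_IJ)²` — zero for
  *shifting* (additive) patterns `b_ij = π_i + β_j`.
- **SMSR** `= (1/|I||J|) Σ (b_iJ·b_Ij − b_ij·b_IJ)² / (b_iJ²·b_Ij²)` —
  zero for *scaling* (multiplicative) patterns `b_ij = π_i·β_j`;
  undefined (reported missing) when a row or column mean is zero.
- **VE (virtual error)**: z-score each row, average the standardized
  rows into a *virtual pattern* `ρ̂_j`, then
  `VE = (1/|I||J|) Σ |b̂_ij − ρ̂_j|`.  VE is zero for shifting *and*
  positive-scaling patterns and grows roughly linearly with noise —
  the pattern-agnostic yardstick used throughout the pipeline.

A population of biclusters is labeled constant / shifting / scaling by
whichever of VAR / MSR / SMSR has the largest squared Pearson
correlation with VE across the population.

## Algorithms included

- `ccc` — exhaustive enumeration of maximal biclusters with contiguous
  time intervals over a discretized matrix (identical symbol strings).
- `bimax_like` — inclusion-maximal all-ones submatrices of a binarized
  matrix.
- `xmotifs_greedy` — greedy conserved-state search on discretized data,
  with a repeated-runs protocol for stochastic searches.
- `cluster_regions` / `cluster_times` — k-means and Ward baselines
  expressed as degenerate biclusters (full other dimension).
- A JSON import adapter through which outputs of external tools
  (BicPAM, FABIA, ISA, spectral biclustering, ...) enter the same
  evaluation.

All outputs are materialized on the original data values, size-filtered
(≥ 2×2), deduplicated, and pooled per collection before scoring.

## Worked example

Plant shifting blocks in five synthetic scans, recover them with CCC on
transition symbols, and score the pooled result:

```python
import numpy as np
from fmribic import (ScanSpec, BlockSpec, generate_collection,
                     compute_all, union_collection, summarize_metrics,
                     infer_pattern_type, topk_filter)
from fmribic.algorithms import ccc, discretize_transitions
from fmribic.synthetic import best_recovery

template = ScanSpec(blocks=(BlockSpec(pattern_type="shifting"),), noise_sd=0.05)
collection = generate_collection(template, n_scans=5, seed=1)

per_scan, scores = [], []
for matrix, truth in collection:
    found = ccc(matrix, discretize_transitions(matrix, n_symbols=3))
    per_scan.append(found)
    scores.extend(best_recovery(found, t) for t in truth)

records = compute_all(union_collection(per_scan))
print(f"{len(records)} biclusters pooled over {len(collection)} scans")
print(f"median recovery of planted blocks: {np.median(scores):.3f}")

summary = summarize_metrics(records)
ve = summary[summary.metric == "ve"].iloc[0]
print(f"CCC virtual error: median {ve['median']:.3f} +/- {ve['sd']:.3f}")

top = topk_filter(records, k=50)
report = infer_pattern_type(top)
print(f"top-50 pattern type: {report.inferred_label} "
      f"(r2 var={report.r2_var:.3f}, msr={report.r2_msr:.3f}, smsr={report.r2_smsr:.3f})")
```

Output:

```
10628 biclusters pooled over 5 scans
median recovery of planted blocks: 1.000
CCC virtual error: median 0.164 +/- 0.350
top-50 pattern type: shifting (r2 var=0.009, msr=0.053, smsr=0.000)
```

CCC pools every maximal coherent bicluster, so most of the 10 628 are
short coincidental fragments — which is exactly why the pipeline ranks
by virtual error.  The planted blocks are recovered perfectly (median
Jaccard 1.0), the low median VE reflects the dominance of coherent
structure, and the VE/MSR correlation correctly identifies the planted
family as shifting.

The same flow is available from the shell:

```sh
fmribic simulate --scans 5 --seed 1 --out-dir data/
fmribic run --algorithm ccc --input data/collection-scan00.tsv --seed 1 --out b0.json
fmribic evaluate --biclusters b0.json --matrices data/ --seed 1 --out metrics.csv
fmribic report --metrics metrics.csv --topk 50 --out report/
```

## Layout

- `src/fmribic/data_model.py` — matrices, biclusters, post-processing
- `src/fmribic/metrics.py` — VAR, MSR, SMSR, virtual error
- `src/fmribic/algorithms.py` — discretizations, CCC, Bimax-style,
  xMotifs-style, clustering baselines
- `src/fmribic/synthetic.py` — planted-bicluster scan generator
- `src/fmribic/pipeline.py` — summaries, top-K, pattern inference
- `src/fmribic/study.py` — pre-configured study protocols
- `src/fmribic/io.py`, `src/fmribic/cli.py` — formats and CLI
- `docs/methods.md` — models, conventions and numerical choices
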