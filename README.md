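# idseq

Analysis toolkit for **immuno-detection by sequencing (ID-seq)**: highly
multiplexed (phospho-)protein quantification in which each antibody carries a
DNA tag, tags released from stained cells are barcoded per well and
sequenced, and protein levels are read out as counts of distinct unique
molecular identifiers (UMIs).  The package takes an experiment from raw
triple-barcoded FASTQ reads to screen-level biology:

1. **demux** — stream reads, locate the anchor, extract UMI / antibody
   barcode / well barcode with error-tolerant correction, remove PCR
   duplicates, and count distinct UMIs per (antibody, well);
2. **normalize** — median-of-ratios size factors for per-well sequencing
   depth;
3. **diff** — a per-antibody negative-binomial regression
   `y_w ~ NB(s_w·exp(x_w'β), α)` with depth offset and replicate/batch
   blocking, a likelihood-ratio test for the treatment term, BH q-values and
   signed p-values `sign(β̂)·(−log₁₀ p)`;
4. **screen** — for kinase-inhibitor screens: PCA of the probes × phenotypes
   signed-p matrix, PC annotation by phenotype correlation, top-vs-bottom
   decile contrasts, probe-set assignment per kinase from a %-inhibition
   matrix by robust (median/MAD) outlier statistics, weighted
   Kolmogorov–Smirnov set enrichment with permutation FDR, and per-set
   molecular phenotype profiles;
5. **synth** — ground-truthed generators for every stage (reads with PCR
   duplication and barcode errors, NB count matrices with planted effects,
   screen matrices with planted axes and kinase sets), so the whole pipeline
   is testable offline.

It is aimed at labs running antibody-DNA-tag assays (ID-seq, and by extension
other ADT-style counting readouts) who need a reproducible, testable path
from reads to per-treatment effect sizes and screen-level hit calling.

## Worked example

```python
import numpy as np
from idseq import (ReadLayout, random_panel, random_plate, simulate_counts,
                   simulate_fastq, count_umis, size_factors, ModelSpec,
                   differential_table)

layout = ReadLayout()                      # UMI(15) – anchor – BC1(10) – BC2(10)
panel  = random_panel(40, seed=0)          # antibody id -> 10-nt barcode
plate  = random_plate(24, seed=1)          # well id -> barcode + covariates

# ground truth: 40 antibodies x 24 wells, two planted treatment effects
truth, _ = simulate_counts(plate, n_antibodies=40, effects={0: 1.5, 1: -1.2},
                           dispersion=0.2, base_mean_range=(50, 300), seed=2)
reads, _ = simulate_fastq(panel, plate, layout, truth.counts,
                          duplication_rate=0.012, barcode_error_rate=0.002, seed=3)

matrix = count_umis([s for _, s in reads], layout, panel, plate, tolerance=1)
print(f"reads: {matrix.reads_total}   assigned: {matrix.assignment_rate:.4f}   "
      f"duplicate rate: {matrix.duplicate_rate:.4f}")

sf  = size_factors(matrix)
res = differential_table(matrix, ModelSpec(blocking=("replicate",)), sf,
                         plate_df=plate.wells)
print(res.summary(alpha=0.01))
```

Output:

```
reads: 143278   assigned: 0.9997   duplicate rate: 0.0114
Differential NB analysis
  antibodies: 40    treatment: treatment
  significant at q<0.01: 1 up, 1 down

   antibody_id  estimate  dispersion  lrt_stat    p_value  signed_logp  ...    q_value
1        Ab002    -1.492      0.6114     19.45  1.032e-05       -4.986  ...  0.0004128
0        Ab001     1.093      0.4045     16.57  4.689e-05        4.329  ...  0.0009379
10       Ab011    0.4892      0.2206      6.18    0.01292        1.889  ...     0.1723
...
```

The 143,278 simulated reads are assigned at 99.97% and deduplicated at the
planted 1.2% UMI duplicate rate; the two planted effects (antibodies Ab001
up, Ab002 down) are the two panel members significant at 1% FDR, with
effect estimates on the natural-log scale and `signed_logp` the score a
screen would aggregate across treatments.

The same stages are available from the shell:

```bash
idseq run-all --config config.yaml --outdir out/   # simulate → demux → … → profiles
idseq demux --fastq reads.fastq --panel panel.tsv --plate plate.csv --out counts.tsv
idseq diff  --counts counts.tsv --plate plate.csv --treatment-col treatment --out diff.tsv
```

`run-all` writes every intermediate (counts, size factors, differential
table, PCA, contrasts, probe sets, enrichment, profiles) plus a provenance
manifest with all seeds and SHA-256 hashes; re-running from the saved config
reproduces every output byte for byte.

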