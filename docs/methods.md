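# Methods

This note documents the statistical model, the algorithms, the synthetic-data
generators and the numerical choices behind `idseq`, in the spirit of a model
description a user should be able to audit.

## The measurement and its data model

Immuno-detection by sequencing (ID-seq) reads out antibody binding by
sequencing DNA tags released from antibody–DNA conjugates.  Each sequenced
read carries, at fixed positions relative to a constant anchor sequence:

* a 15-nt unique molecular identifier (UMI) — a random sequence private to
  one released DNA tag, so that PCR copies of the same tag can be collapsed;
* a 10-nt antibody-dedicated barcode (BC1) identifying the conjugate;
* a well/sample barcode (BC2) added during plate-level PCR.

The assay signal for antibody *a* in well *w* is the number of **distinct**
UMIs observed among reads whose corrected barcodes map to (*a*, *w*).  Reads
sharing the corrected (well, antibody, UMI) triple are PCR duplicates and are
counted once.  UMIs are not error-collapsed: with 4^15 ≈ 10^9 possible UMIs
and 10^2–10^3 molecules per (antibody, well), collision and one-off error
artefacts are second-order, and exact-triple deduplication keeps the counter
order-independent and exactly testable against a set-based oracle.

The segment geometry is declarative (`ReadLayout`); the shipped default
(UMI–anchor–BC1–BC2, anchor `GTAGCGACTCAG`) is a placeholder layout with the
element lengths above, not a claim about any particular deposited dataset.
Assay-specific anchors and orders belong in the run configuration.

### Barcode correction

A barcode set is usable at correction tolerance *t* only if its minimum
pairwise Hamming distance is ≥ 2*t* + 1; `validate_panel` enforces this and
`BarcodeIndex` refuses unsafe panels.  At the default tolerance of one
substitution, matching uses a precomputed dictionary of all single-mismatch
neighbours over the alphabet {A, C, G, T, N} (an N counts as one mismatch),
giving O(1) lookups; other tolerances fall back to an exhaustive
minimum-distance scan with ambiguity rejection (two barcodes tied at the
minimal distance → no match).  For a validated panel the correction is
provably exact on reads with ≤ *t* substitutions, which the test suite
verifies by brute force.

## Depth normalisation

Sequencing depth differs per well, so counts are normalised by
median-of-ratios size factors: with geometric mean
*g_a* = (∏_w k_aw)^(1/W) per antibody row, the size factor of well *w* is

    s_w = median_a ( k_aw / g_a ),

taken over rows positive in every well, then re-centred so the factors have
geometric mean 1 (keeping the model intercept identifiable).  A
`poscounts`-style fallback (row geometric means over positive entries only)
is available for sparse plates.  The estimator is implemented directly
because its exact conventions (row exclusion, centring) are part of the
method's contract and are pinned by hand-computed tests.

A property worth knowing: global normalisation partially absorbs real
signal.  If a large fraction of the panel responds to treatment in the same
direction, the per-well medians shift and treatment estimates attenuate —
with a single responding antibody in a 70-plex panel the attenuation is below
0.01 on the natural-log scale, but a panel-wide response would be silently
re-baselined.  This is intrinsic to median-of-ratios, not an implementation
artefact.

## The per-antibody count model

Distinct-UMI counts are overdispersed relative to Poisson.  For one antibody,
counts across wells are modelled as NB2:

    y_w ~ NB(mu_w, alpha),   mu_w = s_w * exp(x_w' beta),
    Var(y_w) = mu_w + alpha * mu_w^2,

with log link, the log size factor as offset, a treatment factor and
replicate/batch as fixed blocking covariates.  The original analysis used a
random-effects formulation for the blocking terms; this package treats them
as fixed effects — at screen scale the treatment contrast is the same
inference target, the fixed-effect NB GLM is fully reproducible without a
mixed-model dependency, and its small-sample calibration could be verified
directly (below).

**Fitting.**  Coefficients and dispersion are estimated by alternating
maximisation: an IRLS step for β at fixed α (a negative-binomial GLM solve),
then a bounded one-dimensional ML step for α on log scale at the current
fitted means, iterated to a relative log-likelihood tolerance of 1e-8
(maximum 100 iterations), starting from a Poisson fit with a
method-of-moments α.  α is bounded to [1e-8, 1e4]; at the lower bound the
model degenerates to Poisson regression, and fitted coefficients agree with a
Poisson GLM to 1e-4 (tested against an independent Poisson oracle).  Because
the likelihood is flat in α near that boundary, coefficient stability is
accepted as convergence there.  All-zero rows are flagged degenerate (NA
p-value) rather than raising; non-convergence is flagged, never thrown.

**Testing.**  The treatment effect is assessed by a likelihood-ratio test of
the full design against the design without the treatment term, with the
statistic 2(ℓ_full − ℓ_reduced) clipped at zero and referred to a chi-square
with df equal to the number of treatment coefficients.  The nuisance
dispersion is estimated by maximum likelihood **under the reduced (null)
model** and held fixed in both fits.  This choice is deliberate: estimating α
under the full model biases it downward in small samples (the fitted means
absorb noise), which inflates the test — in null simulations at n = 12 wells
the full-model-ML LRT rejected at 4–5% for a nominal 1%.  With the
null-model dispersion the rejection rate is 0.5–0.9% across dispersions
0.1–1.0, verified by 2,000-replicate simulations per condition in the test
suite.  The trade-off is mild conservatism under strong alternatives (the
null fit inflates α when a real effect is present), which costs power but
not validity; effect estimates are essentially unaffected.

Per-antibody results carry the treatment coefficient ("estimate", natural-log
scale), dispersion, LRT statistic and p-value, Benjamini–Hochberg q-values
across the panel, and the **signed p-value**
sign(estimate) · (−log10 p), the per-probe per-phenotype score consumed by
the screen layer (p floored at 1e-300; exactly 0 when p = 1).  A "shared"
dispersion mode (median of per-antibody estimates, refit fixed) is available
for very small panels.

## Screen-level analytics

The screen layer consumes a probes × phenotypes matrix of signed p-values
(or model estimates).

* **PCA** is computed by SVD on per-phenotype mean-centred values; no
  unit-variance scaling by default, since signed p-values already share a
  scale (scaling is a flag).  Components are deterministic up to sign; the
  sign is fixed so each component's largest-magnitude loading is positive.
* **PC annotation** correlates each phenotype with each PC score vector
  (Pearson) and average-linkage-clusters phenotypes and PCs together on
  correlation distance, the view used to identify, e.g., a differentiation
  component by its marker phenotypes.
* **Decile contrasts** compare the top and bottom 10% of probes ranked by a
  PC with per-phenotype Welch t-tests, BH q-values, and a significance call
  requiring p < 0.01 and q < 0.01 (all thresholds are parameters).
* **Probe-set assignment** turns a probes × kinases %-inhibition matrix into
  per-kinase probe sets by robust outlier statistics: z = (x − median) /
  (MAD · 1.4826) per kinase column, upper-tail normal p, membership at
  p < 0.01.  The original rule is not printed in the available description,
  so the statistic is a pluggable strategy; the MAD = 0, non-constant column
  falls back to a mean/sd z-score, and constant columns yield empty sets with
  a warning.  Under normal null columns the false-assignment rate matches α
  (tested).
* **Set enrichment** uses the weighted Kolmogorov–Smirnov running-sum score
  (weight exponent 1): walking the ranking, the sum rises by |score|/NR at
  members and falls by 1/(N − m) otherwise; the enrichment score is the
  deviation of largest magnitude.  Significance comes from resampling member
  labels (m probes drawn uniformly, default 10,000 permutations for final
  runs, 1,000 in tests), with the p-value one-sided within the sign of the
  observed score against same-signed permutation scores — under a random set
  this p is uniform, which the suite checks by Kolmogorov–Smirnov test over
  500 null sets.  BH FDR across sets; ranking ties break lexicographically
  by probe id for determinism.
* **Profiles** average member-probe estimates per kinase set (± s.e.m.,
  NA for singletons), feed k-means (50 restarts, fixed seed) for mechanism
  grouping, and per-phenotype Welch t-tests against a reference kinase's
  member estimates.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed) and serialise their
ground truth (`TruthRecord`) next to the data.

**Reads** (`simulate_fastq`): for each (antibody, well) the stated number of
distinct UMIs is drawn; each molecule is emitted Geometric(1 − d) times
(support ≥ 1), so the expected duplicate fraction equals d — the default
d = 0.012 mirrors the duplicate rate of a high-quality run.  Substitution
errors hit barcode segments at a per-base rate; there are no indels (barcodes
are fixed-position), no quality scores, and no PCR bias or optical
duplicates.  At zero noise, demultiplexing reproduces the truth matrix
exactly, which anchors the pipeline's round-trip tests.

**Counts** (`simulate_counts`): NB2 counts at mean s_w · μ_a · exp(x_w β_a)
with log-uniform well depths (default 0.5–2×), log-uniform baselines and
per-antibody planted log fold changes.  Dispersion is a single value per
call; real panels have antibody-dependent dispersion, which the model
estimates per antibody anyway.

**Screen** (`simulate_screen`): the signed-p matrix is planted low-rank
structure plus unit-variance noise.  Two orthonormal axes emulate the
dominant screen structure — a "signalling" axis over half the phenotypes and
a "differentiation" axis over a marker block — with per-probe activities
N(0, 5²) and N(0, 3.5²); these scales put roughly 45% of total variance in
the top components, the regime the method operates in.  A pool of 18
differentiation-inducing probes is shifted by +12 on the differentiation
axis, and each of 13 true kinases draws its 14 inhibitory probes from that
pool — overlapping sets that mirror the cross-reactivity of real
kinase-inhibitor probes (at the cost of making the true sets mutually
similar, so their mechanism profiles are close).  The inhibition matrix
gives planted members 70–95% inhibition over an approximately normal
background (N(10, 4), clipped to [0, 100]) so that the outlier-assignment
false-positive rate is calibrated.  Passing the planted-recovery tests
therefore shows the analytics recover strong, concentrated set signal at
screen scale; it does not certify behaviour on weaker, partially overlapping
real probe sets.

## Problem sizes and reproducibility

Defaults mirror the assay geometry (70 antibodies, 96/384-well plates,
~300 probes × 225 kinases).  The test suite runs the demultiplexer on
~10⁵ simulated reads against an independent set-based oracle, the null
calibration at 2,000 replicates per dispersion, fold-change recovery at 500
replicates, and enrichment calibration over 500 null sets; the end-to-end
driver is checked for byte-identical re-execution from its saved
configuration.  `scripts/acceptance.py` recomputes the headline quantities
at these sizes from a single `--seed`.  Every stochastic step in the CLI
takes an explicit seed recorded in the run manifest alongside SHA-256 hashes
of all inputs and outputs.

## Known limitations

* Fixed-effect blocking instead of random effects; with very many small
  batches the fixed-effect parameterisation spends degrees of freedom.
* Null-model dispersion costs some power under strong effects (validity
  first).
* Median-of-ratios attenuates panel-wide responses (see above).
* Exact-triple UMI deduplication slightly overcounts at very high UMI error
  rates; directional UMI clustering is not implemented.
* The GSEA weighted-KS null is heavy-tailed when a few probes dominate the
  ranking's |score| mass; permutation (not analytic) significance handles
  this, at permutation-resolution cost for very small p-values.
* Spike-in barcodes are counted and reported but play no role downstream;
  no spike-in-based normalisation is attempted.
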