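# Example run configuration for `idseq run-all`.
# Every threshold of the analysis is a named parameter; omitted keys take the
# documented defaults (see idseq.pipeline.DEFAULT_CONFIG).
version: 1
seed: 7
tolerance: 1          # barcode correction: max substitutions
layout: {}            # default UMI(15) - anchor - BC1(10) - BC2(10)
simulate:
  n_antibodies: 40
  n_wells: 24
  dispersion: 0.2
  duplication_rate: 0.012
  barcode_error_rate: 0.002
  n_up: 13            # planted increased proteins
  n_down: 7           # planted decreased proteins
  effect_size: 0.9    # natural-log fold change of planted effects
model:
  treatment: treatment
  reference: control
  blocking: [replicate, batch]
  dispersion: ml      # or "shared"
screen:
  n_probes: 294
  n_phenotypes: 70
  n_kinases: 225
  n_true_kinases: 13
  k: 4                # principal components
  fraction: 0.10      # decile contrast
  alpha: 0.01
  fdr: 0.01
  n_perm: 10000       # enrichment permutations
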