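# Self-contained simulated run of the full pipeline.
seed: 0
alpha: 0.05
strict_enrichment_confirm: true
divergence_threshold: 0.3
n_top: 50
simulate:
  n_genes: 2000
  n_replicates: 6
  effect_lfc: 2.0
  dispersion: 0.05
  seed: 0
  n_transcript_genes: 100
simulate_images:
  width: 256
  height: 256
  n_puncta_ch1: 200
  n_puncta_ch2: 200
  coloc_fraction: 0.5
  background_mean: 2.0
  background_sd: 0.5
  seed: 0
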