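# Small end-to-end pipeline configuration:
#   trafficgwis all --config examples/config_small.yaml --out-dir gwis_run
sim:
  n_per_stratum: [300, 150]
  stratum_names: [EA, AA]
  n_snps: 2000
  block_size: 10
  rho: 0.7
  fst: 0.1
  seed: 1
covariates: primary
n_pcs:
  EA: 2
  AA: 2
maf: 0.05
callrate: 0.98
suggestive: 1.0e-5
genome_wide: 5.0e-8
seed: 1
out_dir: gwis_run
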