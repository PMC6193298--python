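# Example pipeline configuration: full HCC-style dual-transcriptome profile
# on simulated input (supply `inputs: {mrna: ..., mirna: ..., catalog: ...}`
# to run on your own matrices instead).
profile: hcc_dual
seed: 1
outdir: holoseq_out/hcc
params:
  n_clusters: 3
  alpha: 0.05
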