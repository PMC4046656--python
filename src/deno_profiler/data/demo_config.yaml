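# Demo configuration: a small two-tissue synthetic experiment run end to end.
outdir: demo_run
seed: 7
sim:
  n_genes: 120
  library_sizes: [199075, 198382]
phi: 0.1
alpha: 0.01
pseudocount: 0.5
use_slim: true
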