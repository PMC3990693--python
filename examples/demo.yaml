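# Desk-scale demo: three 30 kbp populations across three depths.
# Runs the full pipeline in about two minutes on one CPU.
seed: 11
outdir: demo_out
simulate:
  genome_length: 30000
  n_reads: 600
  islands:
    n_loci: 40
    locus_len: 300
    n_islands: 6
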