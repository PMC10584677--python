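# End-to-end roadblock scan over the default study locus
# (chr12:104,286,383-104,372,549, 500-bp bins -> 173 bins).
# dCas9 targets the non-template strand inside the gene body (bin 40);
# 80% of elongation complexes reaching the block terminate there.
gene:
  chrom: chr12
  locus_start: 104286383
  locus_end: 104372549
  tss: 104286383
  pas_positions: [104362549]
  gene_length: 76166
block:
  position: 104306652   # mid-bin 40; stall point = position - 19
  orientation: NT
  term_prob: 0.8
  pause_dwell: 20.0
  pause_width: 50
  pause_offset: 19
elongation:
  term_hazard: 5.0e-4
  pas_commit: [1.0]
  inter_pas_rescue: true
library:
  n_ec: 200000
  n_fragments: 200000
  frag_len: 150
bin_size: 500
bin_test:
  alpha: 1.0e-5
  n_sim: 1000000
  method: exact        # switch to "mc" for the simulated-null fidelity mode
  pseudocount: 1.0
checkpoints:
  us: [104363549, 104364549]   # between PAS and block
  ds: [104364852, 104365852]   # downstream of the block
seed: 7
outdir: scan_out
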