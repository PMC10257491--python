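# Small tortoiseshell: ~400 bp satellite (AuSat-like) with variable monomer
# length (252-408 bp), about 2 kb arrays; rare R2-bearing units.
name: aglais_urticae
gene_lengths: {18S: 1900, ITS1: 550, 5.8S: 160, ITS2: 600, 28S: 3900}
satellite:
  monomer_len: 400
  monomer_len_range: [252, 408]
  copies_range: [5, 8]
  copy_divergence: 0.02
r2_insertion_fraction: 0.017
r2_length: 3000
n_units: 12
unit_divergence: 0.003
igs_spacer_len: 3000
flank_len: 5000
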