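# Peacock butterfly: 157 bp IGS satellite (IiSat-like) with strong per-unit
# copy-number variation; an R2-type element inserted in one third of 28S
# copies.
name: inachis_io
gene_lengths: {18S: 1900, ITS1: 550, 5.8S: 160, ITS2: 600, 28S: 3900}
satellite:
  monomer_len: 157
  copies_range: [30, 100]
  copy_divergence: 0.02
r2_insertion_fraction: 0.3333333333
r2_length: 3000
n_units: 12
unit_divergence: 0.003
igs_spacer_len: 500
flank_len: 5000
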