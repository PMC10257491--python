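# Hepialid with a compact IGS: telomeric-motif run plus a 231 bp TTATG
# microsatellite region; whole unit about 10 kb.
name: phymatopus_californicus
gene_lengths: {18S: 1900, ITS1: 550, 5.8S: 160, ITS2: 600, 28S: 3900}
microsatellites:
  - [TTAGG, 560]
  - [TTATG, 231]
n_units: 12
unit_divergence: 0.002
igs_spacer_len: 600
flank_len: 5000
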