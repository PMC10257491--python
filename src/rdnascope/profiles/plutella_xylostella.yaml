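# Diamondback moth: single terminal rDNA locus adjacent to the telomere;
# ~252 bp satellite (PxSat-like, monomers 248-258 bp); occasional R1-type
# insertions.
name: plutella_xylostella
gene_lengths: {18S: 1900, ITS1: 550, 5.8S: 160, ITS2: 600, 28S: 3900}
satellite:
  monomer_len: 252
  monomer_len_range: [248, 258]
  copies_range: [6, 12]
  copy_divergence: 0.01
r2_insertion_fraction: 0.033
r2_length: 2500
r2_label: R1
n_units: 30
unit_divergence: 0.001
igs_spacer_len: 800
flank_len: 5000
telomere_flank: true
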