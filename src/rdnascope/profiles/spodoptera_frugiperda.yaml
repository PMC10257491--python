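# Fall armyworm: single rDNA locus, plain spacer without annotated repeats.
name: spodoptera_frugiperda
gene_lengths: {18S: 1900, ITS1: 550, 5.8S: 160, ITS2: 600, 28S: 3900}
n_units: 12
unit_divergence: 0.001
igs_spacer_len: 2500
flank_len: 5000
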