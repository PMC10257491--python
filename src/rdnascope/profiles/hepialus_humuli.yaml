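# Ghost moth: expanded IGS carrying eight nonautonomous mobile-element
# fragments (fragment sizes span the reported 588 bp to 4.3 kb range).
name: hepialus_humuli
gene_lengths: {18S: 1900, ITS1: 550, 5.8S: 160, ITS2: 600, 28S: 3900}
igs_elements:
  - [Ty3_gypsyA, 2500]
  - [Ty3_gypsyB, 1800]
  - [Ty3_gypsyC, 1200]
  - [L2, 4300]
  - [RTE_RTE, 588]
  - [PIF_Harbinger, 900]
  - [PIF_Spy, 1100]
  - [P_element, 1500]
n_units: 12
unit_divergence: 0.002
igs_spacer_len: 300
flank_len: 5000
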