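# Nominal helix boundaries (1-based, inclusive) of the spidroin C-terminal
# domain five-helix bundle.  Helix N4 spans residues 51-80, the region covered
# by the synthetic CT_51-80 peptide; the remaining boundaries are nominal
# placeholders for a ~100-residue CT model and are meant to be replaced by a
# structure-derived annotation when one is available.
helices:
  N1: [6, 18]
  N2: [22, 35]
  N3: [38, 49]
  N4: [51, 80]
  N5: [83, 96]
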