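# Residue and modification registry.
#
# Residue formulas are elemental compositions of the *residue* (amino acid
# minus water), so a peptide's neutral mass is the sum of residue masses
# plus one water.  Tokens may be extended or overridden by user registries.
residues:
  G: C2H3NO
  A: C3H5NO
  S: C3H5NO2
  P: C5H7NO
  V: C5H9NO
  T: C4H7NO2
  C: C3H5NOS
  L: C6H11NO
  I: C6H11NO
  N: C4H6N2O2
  D: C4H5NO3
  Q: C5H8N2O2
  K: C6H12N2O
  E: C5H7NO3
  M: C5H9NOS
  H: C6H7N3O
  F: C9H9NO
  R: C6H12N4O
  Y: C9H9NO2
  W: C11H10N2O
  # Noncanonical residues used in the library building blocks
  O: C5H10N2O    # ornithine
  B: C4H8N2O     # 2,4-diaminobutyric acid (Dab)
  U: C3H6N2O     # 2,3-diaminopropionic acid (Dap)
  J: C6H9NO      # beta-cyclopropyl-alanine
  Z: C6H6N2OS    # 4-thiazolyl-alanine
  X: C5H7NO2     # 4-hydroxyproline
  # Dpa = Dap with a 2,4-dinitrophenyl group on the side-chain amine
  # (quencher residue); kept as a standalone multi-letter token.
  Dpa: C9H8N4O5

modifications:
  # 3-nitration of a tyrosine ring position: +NO2, -H
  NO2:
    attachment: side_chain
    delta: +N O2 -H
  # ortho-aminobenzoyl, amide-linked to a side-chain or N-terminal amine
  Abz:
    attachment: [side_chain, n_terminus]
    delta: +C7H5NO
  # 7-methoxycoumarin-4-acetyl, N-terminal acyl
  Mca:
    attachment: n_terminus
    delta: +C12H9O4
  # C-terminal amide: replace the acid -OH with -NH2
  NH2:
    attachment: c_terminus
    delta: +N H -O
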