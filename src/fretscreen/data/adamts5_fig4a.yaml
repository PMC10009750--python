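# ADAMTS-5 combinatorial FRET-substrate library design.
#
# Built on the parent substrate KY(NO2)TESESRGK(Abz)IYYKKG: fixed positions
# carry the quencher Y(NO2) at P5, the fluorophore K(Abz) at P4', the
# consensus-preferred E at P1 and S at P1', solubilizing K at P6/P9' and the
# C-terminal G at P10'.  Variable positions hold conservative natural swaps
# plus the unnatural building blocks O (ornithine), B (2,4-diaminobutyric
# acid), J (beta-cyclopropyl-alanine) and U (2,3-diaminopropionic acid).
# The per-position option sets multiply to exactly 12288 unique sequences;
# the loader refuses the design if the product or the required-member gate
# fails.
name: adamts5_fig4a
scissile_index: 6   # residues N-terminal of the cleaved bond (P1 | P1')
positions:
  - {label: P6,   options: [K]}
  - {label: P5,   options: ["Y(NO2)"]}
  - {label: P4,   options: [T, S, P, A]}
  - {label: P3,   options: [E, D]}
  - {label: P2,   options: [S, N, G, A]}
  - {label: P1,   options: [E]}
  - {label: "P1'", options: [S]}
  - {label: "P2'", options: [R, O, B]}
  - {label: "P3'", options: [G, A]}
  - {label: "P4'", options: ["K(Abz)"]}
  - {label: "P5'", options: [I, J]}
  - {label: "P6'", options: [Y, F]}
  - {label: "P7'", options: [Y, F, L, J]}
  - {label: "P8'", options: [K, O, B, U]}
  - {label: "P9'", options: [K]}
  - {label: "P10'", options: [G]}
expected_size: 12288
# Sequences that must be members (library parent and characterized hits).
required_members:
  - "KY(NO2)TESESRGK(Abz)IYYKKG"   # parent (peptide 3)
  - "KY(NO2)TENESRGK(Abz)IYYKKG"   # hit 19
  - "KY(NO2)SESESRGK(Abz)IYYKKG"   # hit 23
  - "KY(NO2)SENESRGK(Abz)IYYKKG"   # hit 26
  - "KY(NO2)SEGESRGK(Abz)JYFKKG"   # decoded screening hit
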