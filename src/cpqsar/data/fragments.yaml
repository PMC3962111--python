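# Substructure patterns behind the four fragment-count descriptors.
# nRNNOx / nPO4 are functional-group counts; N-067 / N-078 are
# Ghose-Crippen atom-centred nitrogen types (R = carbon attachment,
# X = heteroatom attachment, Al = aliphatic, Ar = aromatic).
# count_atom: index of the pattern atom that identifies one occurrence
# (occurrences are counted as distinct molecule atoms mapped there, so
# symmetric environments are not double- or under-counted).
version: "fragments-1.0"
fragments:
  nRNNOx:
    description: "number of aliphatic N-nitroso groups (R2N-N=O)"
    count_atom: 1
    patterns:
      - "[NX3;!$([NX3]a)][NX2]=[OX1]"
  nPO4:
    description: "number of phosphate / thiophosphate groups"
    count_atom: 0
    patterns:
      - "[PX4](=[OX1,SX1])([OX2,SX2])([OX2,SX2])[OX2,SX2]"
  N-067:
    description: "Al2-NH: secondary amine nitrogen bonded to two aliphatic carbons"
    count_atom: 0
    patterns:
      - "[NX3;H1;!$([NX3]a);!$([NX3][CX3]=[OX1,SX1,NX2])]([CX4])[CX4]"
  N-078:
    description: "Ar-N=X / X-N=X: nitrogen double-bonded to a heteroatom-or-carbon X with an aromatic or heteroatom single-bond neighbour"
    count_atom: 0
    patterns:
      - "[NX2;$([NX2]a)]=[N,O,S,P]"
      - "[NX2;$([NX2][!#6;!#1])]=[N,O,S,P]"
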