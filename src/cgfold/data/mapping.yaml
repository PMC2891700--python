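# Default residue -> CG site mapping.
#
# Per residue: an ordered list of sidechain site blocks.  The backbone site
# (the C-alpha atom) is implicit for every residue and carries local index 0;
# sidechain blocks are indexed 1..n in file order.  "bonds" lists intra-residue
# site-site bonds by local index (0 = backbone); when omitted the sites form a
# chain 0-1-2-...  "hydrogens" is the number of implicit hydrogens attached to
# the block's heavy atoms, used only for site-mass bookkeeping.  "improper"
# marks a planarity-restrained quadruple of local site indices.
#
# Constraints honoured by the scheme: one backbone site per residue at CA,
# at most four sidechain sites, 1-3 heavy atoms each (single-atom sites occur
# only for the smallest sidechains: Ala CB, Asp CB), and no heavy atom is a
# member of more than one site.  This grouping is a reconstruction and can be
# overridden with a user file of the same layout.
ALA:
  sites:
    - {type: apolar, atoms: [CB], hydrogens: 3}
ARG:
  sites:
    - {type: apolar, atoms: [CB, CG, CD], hydrogens: 6}
    - {type: positive, atoms: [NE, CZ], hydrogens: 1}
    - {type: positive, atoms: [NH1, NH2], hydrogens: 4}
ASN:
  sites:
    - {type: apolar, atoms: [CB, CG], hydrogens: 2}
    - {type: polar, atoms: [OD1, ND2], hydrogens: 2}
ASP:
  sites:
    - {type: apolar, atoms: [CB], hydrogens: 2}
    - {type: negative, atoms: [CG, OD1, OD2], hydrogens: 0}
CYS:
  sites:
    - {type: polar, atoms: [CB, SG], hydrogens: 3}
GLN:
  sites:
    - {type: apolar, atoms: [CB, CG], hydrogens: 4}
    - {type: polar, atoms: [CD, OE1, NE2], hydrogens: 2}
GLU:
  sites:
    - {type: apolar, atoms: [CB, CG], hydrogens: 4}
    - {type: negative, atoms: [CD, OE1, OE2], hydrogens: 0}
GLY:
  sites: []
HIS:
  sites:
    - {type: apolar, atoms: [CB, CG], hydrogens: 2}
    - {type: polar, atoms: [ND1, CE1], hydrogens: 2}
    - {type: polar, atoms: [CD2, NE2], hydrogens: 1}
  bonds: [[0, 1], [1, 2], [1, 3]]
ILE:
  sites:
    - {type: apolar, atoms: [CB, CG2], hydrogens: 4}
    - {type: apolar, atoms: [CG1, CD1], hydrogens: 5}
LEU:
  sites:
    - {type: apolar, atoms: [CB, CG], hydrogens: 3}
    - {type: apolar, atoms: [CD1, CD2], hydrogens: 6}
LYS:
  sites:
    - {type: apolar, atoms: [CB, CG, CD], hydrogens: 6}
    - {type: positive, atoms: [CE, NZ], hydrogens: 5}
MET:
  sites:
    - {type: apolar, atoms: [CB, CG], hydrogens: 4}
    - {type: apolar, atoms: [SD, CE], hydrogens: 3}
PHE:
  sites:
    - {type: apolar, atoms: [CB, CG], hydrogens: 2}
    - {type: apolar, atoms: [CD1, CE1], hydrogens: 2}
    - {type: apolar, atoms: [CD2, CE2, CZ], hydrogens: 3}
  bonds: [[0, 1], [1, 2], [1, 3]]
PRO:
  sites:
    - {type: apolar, atoms: [CB, CG, CD], hydrogens: 6}
SER:
  sites:
    - {type: polar, atoms: [CB, OG], hydrogens: 3}
THR:
  sites:
    - {type: polar, atoms: [CB, OG1, CG2], hydrogens: 5}
TRP:
  sites:
    - {type: apolar, atoms: [CB, CG, CD2], hydrogens: 2}
    - {type: polar, atoms: [CD1, NE1, CE2], hydrogens: 2}
    - {type: apolar, atoms: [CE3, CZ3], hydrogens: 2}
    - {type: apolar, atoms: [CZ2, CH2], hydrogens: 2}
  bonds: [[0, 1], [1, 2], [1, 3], [2, 4]]
  improper: [1, 2, 3, 4]
TYR:
  sites:
    - {type: apolar, atoms: [CB, CG], hydrogens: 2}
    - {type: apolar, atoms: [CD1, CE1], hydrogens: 2}
    - {type: apolar, atoms: [CD2, CE2], hydrogens: 2}
    - {type: polar, atoms: [CZ, OH], hydrogens: 1}
  bonds: [[0, 1], [1, 2], [1, 3], [2, 4]]
  improper: [1, 2, 3, 4]
VAL:
  sites:
    - {type: apolar, atoms: [CB, CG1, CG2], hydrogens: 7}
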