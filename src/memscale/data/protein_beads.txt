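# Protein coarse-grained bead templates (~4 heavy atoms : 1 bead).
#
# Format (whitespace separated):
#   BACKBONE <class> <charge> <parent-atoms,comma-separated>
#   <RESNAME> <bead-name> <class> <charge> <parent-atoms,comma-separated>
#
# Classes: P polar, N intermediate, C apolar, Q charged.  A residue may
# list 0, 1 or 2 side-chain beads; glycine and alanine have none in this
# table.  Parent atom names are fnmatch patterns against atom names of
# the residue; a bead is placed at the centre of mass of the parent
# atoms actually present (bead mass = sum of matched atom masses), so
# the same table maps both full atomistic residues and reduced fixtures
# that carry only N, CA, C, O and a pseudo side-chain atom named CB.
# Charge must be nonzero only for class Q.

BACKBONE P 0 N,CA,C,O

SER SC1 P 0 CB,OG
THR SC1 P 0 CB,OG1,CG2
CYS SC1 N 0 CB,SG
VAL SC1 C 0 CB,CG1,CG2
LEU SC1 C 0 CB,CG,CD1,CD2
ILE SC1 C 0 CB,CG1,CG2,CD1
MET SC1 C 0 CB,CG,SD,CE
PRO SC1 C 0 CB,CG,CD
ASN SC1 P 0 CB,CG,OD1,ND2
GLN SC1 P 0 CB,CG,CD,OE1,NE2
ASP SC1 Q -1 CB,CG,OD1,OD2
GLU SC1 Q -1 CB,CG,CD,OE1,OE2
LYS SC1 N 0 CB,CG,CD
LYS SC2 Q 1 CE,NZ
ARG SC1 N 0 CB,CG,CD
ARG SC2 Q 1 NE,CZ,NH1,NH2
HIS SC1 N 0 CB,CG
HIS SC2 P 0 ND1,CD2,CE1,NE2
PHE SC1 C 0 CB,CG,CD1,CD2
PHE SC2 C 0 CE1,CE2,CZ
TYR SC1 C 0 CB,CG,CD1,CD2
TYR SC2 P 0 CE1,CE2,CZ,OH
TRP SC1 C 0 CB,CG,CD1,CD2
TRP SC2 N 0 NE1,CE2,CE3,CZ2,CZ3,CH2
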