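# Lipid coarse-grained templates.
#
# Format:
#   LIPID <resname>
#   BEAD <name> <class> <charge> <default-mass-amu> <parent-atoms,comma>
#   BOND <bead1> <bead2> <r0 Å> <k kJ/mol/Å²>
#   ANGLE <bead1> <bead2> <bead3> <theta0 deg> <k kJ/mol/rad²>
#   PHOSPHATE <bead-name>
#
# Beads appear in template order.  Parent atoms are fnmatch patterns
# used when mapping an atomistic lipid; when a lipid is built directly
# at CG resolution the default mass is used.  PHOSPHATE names the bead
# treated as the phosphate marker for leaflet/headgroup analysis.

# -- POPC-like 13-bead lipid: choline/phosphate head pair (zwitterionic),
#    two glycerol linkers, a 4-bead palmitoyl tail and a 5-bead oleoyl tail.
LIPID POPC
BEAD NC3 Q 1 72 N,C12,C13,C14,C15
BEAD PO4 Q -1 72 P,O11,O12,O13,O14
BEAD GL1 N 0 72 C1,C2,O21,C21,O22
BEAD GL2 N 0 72 C3,O31,C31,O32
BEAD C1A C 0 72 C22,C23,C24,C25
BEAD C2A C 0 72 C26,C27,C28,C29
BEAD C3A C 0 72 C210,C211,C212,C213
BEAD C4A C 0 72 C214,C215,C216,C217,C218
BEAD C1B C 0 72 C32,C33,C34,C35
BEAD C2B C 0 72 C36,C37,C38,C39
BEAD C3B C 0 72 C310,C311,C312
BEAD C4B C 0 72 C313,C314,C315
BEAD C5B C 0 72 C316
BOND NC3 PO4 4.7 12.5
BOND PO4 GL1 4.7 12.5
BOND GL1 GL2 3.7 12.5
BOND GL1 C1A 4.7 12.5
BOND C1A C2A 4.7 12.5
BOND C2A C3A 4.7 12.5
BOND C3A C4A 4.7 12.5
BOND GL2 C1B 4.7 12.5
BOND C1B C2B 4.7 12.5
BOND C2B C3B 4.7 12.5
BOND C3B C4B 4.7 12.5
BOND C4B C5B 4.7 12.5
ANGLE PO4 GL1 C1A 120 10
ANGLE GL1 C1A C2A 180 10
ANGLE C1A C2A C3A 180 10
ANGLE C2A C3A C4A 180 10
ANGLE GL2 C1B C2B 180 10
ANGLE C1B C2B C3B 180 10
ANGLE C2B C3B C4B 180 10
ANGLE C3B C4B C5B 180 10
PHOSPHATE PO4

# -- toy 4-bead lipid used by the desk-scale fixtures: one
#    intermediate-polarity head, three apolar tail beads.
LIPID TOY4
BEAD HD N 0 54 N1,O1
BEAD T1 C 0 54 C1,C2
BEAD T2 C 0 54 C3,C4
BEAD T3 C 0 54 C5,C6
BOND HD T1 4.7 12.5
BOND T1 T2 4.7 12.5
BOND T2 T3 4.7 12.5
ANGLE HD T1 T2 180 8
ANGLE T1 T2 T3 180 8
PHOSPHATE HD

# -- minimal 3-bead toy lipid (chain topology demonstrations)
LIPID TOY3
BEAD HD N 0 54 N1,O1
BEAD T1 C 0 54 C1,C2
BEAD T2 C 0 54 C3,C4
BOND HD T1 4.7 12.5
BOND T1 T2 4.7 12.5
PHOSPHATE HD
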