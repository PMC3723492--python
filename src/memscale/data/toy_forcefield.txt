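# Toy coarse-grained force-field class table.
#
# This is NOT a published parameter set: it is a reduced, configurable
# table with four polarity classes (P polar, N intermediate, C apolar,
# Q charged) plus W (CG water), chosen so that the packaged toy lipid
# self-assembles into a bilayer and an amphipathic helix anchors at its
# surface in desk-scale runs.
#
# Format:
#   PAIR <class1> <class2> <epsilon kJ/mol> <sigma Å>
#   MASS <class> <amu>
# Pairs are symmetric; unlisted pairs fall back to Lorentz-Berthelot
# combination of the like pairs.

PAIR P P 4.5 4.7
PAIR P N 4.0 4.7
PAIR P C 2.0 4.7
PAIR P Q 4.5 4.7
PAIR P W 4.5 4.7
PAIR N N 3.5 4.7
PAIR N C 2.5 4.7
PAIR N Q 3.5 4.7
PAIR N W 3.5 4.7
PAIR C C 4.5 4.7
PAIR C Q 1.8 4.7
PAIR C W 1.2 4.7
PAIR Q Q 4.0 4.7
PAIR Q W 4.5 4.7
PAIR W W 4.0 4.7

MASS P 54
MASS N 54
MASS C 54
MASS Q 54
MASS W 54
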