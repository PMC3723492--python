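"""Unit system and physical constants.

The whole package works in one internal unit system:

====================  =========================
quantity              unit
====================  =========================
length                angstrom (Å)
time                  femtosecond (fs)
mass                  atomic mass unit (amu)
energy                kJ mol⁻¹
temperature           kelvin (K)
pressure              bar
charge                elementary charge (e)
====================  =========================

Derived units follow: velocity Å fs⁻¹, force kJ mol⁻¹ Å⁻¹.  Because
kJ mol⁻¹ and amu·Å²·fs⁻² are not the same energy unit, two conversion
factors appear wherever forces turn into accelerations or velocities
turn into kinetic energy; they are defined once here and nowhere else.
"""

#: Boltzmann constant, kJ mol⁻¹ K⁻¹
KB = 8.314462618e-3

#: Coulomb prefactor  e² → kJ mol⁻¹ Å   (1 / 4πε₀ in these units)
COULOMB_K = 1389.35457644382

#: acceleration conversion: (kJ mol⁻¹ Å⁻¹) / amu  →  Å fs⁻²
ACCEL = 1.0e-4

#: kinetic-energy conversion: amu (Å fs⁻¹)² → kJ mol⁻¹
KE2KJ = 1.0e4

#: pressure conversion: kJ mol⁻¹ Å⁻³ → bar
P2BAR = 16605.390671738

#: Avogadro constant, mol⁻¹
N_AVOGADRO = 6.02214076e23

#: standard atomic masses (amu) for the elements the package meets
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "F": 18.998, "ZN": 65.38, "FE": 55.845, "D": 2.014,
}


def element_mass(element: str) -> float:
    """Mass (amu) for an element symbol; 0.0 for unknown/virtual sites."""
    return ATOMIC_MASSES.get(element.strip().upper(), 0.0)
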