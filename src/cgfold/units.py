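"""Internal unit system and physical constants.

Lengths are nm, time ps, energy kJ/mol, mass amu, temperature K.
Angstrom values are accepted/emitted only at I/O boundaries.
"""

KB = 0.008314462618153239  # kJ/mol/K

A_PER_NM = 10.0
NM_PER_A = 0.1

# monoisotopic-ish standard atomic weights, amu
ELEMENT_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}


def element_mass(element: str) -> float:
    try:
        return ELEMENT_MASS[element.upper()]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {element!r}")
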