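"""Physical constants and unit conventions.

Everything in this package is in Hartree atomic units: lengths in bohr,
current-density susceptibilities in the c-scaled convention described in
``docs/methods.md`` (the diamagnetic Larmor tensor is ``-1/2 rho(r) eps``
with no factor of 1/c), and shielding densities dimensionless.  Shielding
constants are reported in ppm, i.e. the dimensionless value times 1e6.
"""

from __future__ import annotations

#: Fine-structure constant (CODATA 2018).
ALPHA = 7.2973525693e-3

#: Speed of light in atomic units, 1/alpha.
SPEED_OF_LIGHT = 1.0 / ALPHA

#: Dimensionless shielding -> ppm.
PPM = 1.0e6

#: 1 angstrom in bohr.
ANGSTROM = 1.8897261254578281

#: Element symbols indexed by atomic number (Z = 1..54 suffices here).
ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
    "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
    "Rb", "Sr", "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "In", "Sn", "Sb", "Te", "I", "Xe",
]

SYMBOL_TO_Z = {s: z for z, s in enumerate(ELEMENTS) if z > 0}

# Bragg-Slater covalent radii in angstrom (J. C. Slater, J. Chem. Phys. 41,
# 3199 (1964)), with the customary H value 0.35 A used in fuzzy-cell
# partitioning.  Converted to bohr on access.
_BRAGG_SLATER_ANGSTROM = {
    "H": 0.35, "He": 0.31, "Li": 1.45, "Be": 1.05, "B": 0.85, "C": 0.70,
    "N": 0.65, "O": 0.60, "F": 0.50, "Ne": 0.38, "Na": 1.80, "Mg": 1.50,
    "Al": 1.25, "Si": 1.10, "P": 1.00, "S": 1.00, "Cl": 1.00, "Ar": 0.71,
    "K": 2.20, "Ca": 1.80, "Sc": 1.60, "Ti": 1.40, "V": 1.35, "Cr": 1.40,
    "Mn": 1.40, "Fe": 1.40, "Co": 1.35, "Ni": 1.35, "Cu": 1.35, "Zn": 1.35,
    "Ga": 1.30, "Ge": 1.25, "As": 1.15, "Se": 1.15, "Br": 1.15, "Kr": 0.88,
}


def bragg_slater_radius(symbol: str) -> float:
    """Bragg-Slater radius of an element in bohr."""
    try:
        return _BRAGG_SLATER_ANGSTROM[symbol] * ANGSTROM
    except KeyError:
        raise KeyError(f"no Bragg-Slater radius tabulated for element {symbol!r}")
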