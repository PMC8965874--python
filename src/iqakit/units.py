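"""Unit conventions and physical constants.

All internal quantities are atomic units (bohr, hartree, electron charge).
File I/O happens in the units native to each format (Å, kcal/mol, Amber
charge units); conversion happens exactly once, at the I/O boundary.
"""

HARTREE_TO_KCAL = 627.509
"""1 hartree in kcal/mol."""

BOHR_TO_ANGSTROM = 0.529177
"""1 bohr in Å."""

ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

EBOHR_TO_DEBYE = 2.541746
"""1 e·bohr in debye."""

COULOMB_KCAL = 332.0637
"""Coulomb constant in kcal·Å/(mol·e²), the Amber convention."""

AMBER_CHARGE_FACTOR = 18.2223
"""prmtop charges are stored as q·18.2223 so that q1*q2/r is in kcal/mol."""

R_GAS_KCAL = 0.0019872
"""Gas constant in kcal/(mol·K)."""

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
    "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
]

_Z_BY_SYMBOL = {s.lower(): z for z, s in enumerate(ELEMENTS)}


def atomic_number(symbol: str) -> int:
    """Atomic number for an element symbol (case-insensitive)."""
    key = symbol.strip().lower()
    if key not in _Z_BY_SYMBOL:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return _Z_BY_SYMBOL[key]


def element_symbol(z: int) -> str:
    if not 1 <= z < len(ELEMENTS):
        raise ValueError(f"atomic number out of range: {z}")
    return ELEMENTS[z]
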