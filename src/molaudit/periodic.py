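"""Element tables used across the package.

Covalent radii follow the Cordero et al. single-bond compilation (Å);
atomic masses are standard atomic weights (g/mol). Default valences are
the organic-subset bookkeeping values used by the synthetic generator.
"""

from __future__ import annotations

# Cordero-style single-bond covalent radii, Å.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "As": 1.19, "Se": 1.20, "Br": 1.20,
    "I": 1.39, "Te": 1.38,
    "Au": 1.36,
}

# Standard atomic weights, g/mol.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.098, "Ca": 40.078, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "I": 126.904, "Te": 127.60,
    "Au": 196.967,
}

# Bookkeeping valences for neutral, closed-shell organic atoms.
VALENCES: dict[str, int] = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "Si": 4, "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1,
    "Se": 2, "Au": 1,
}


def covalent_radius(symbol: str) -> float:
    """Return the covalent radius of ``symbol`` in Å.

    Raises ``ValueError`` naming the symbol when it is not tabulated.
    """
    try:
        return COVALENT_RADII[symbol]
    except KeyError:
        raise ValueError(f"no covalent radius tabulated for element {symbol!r}") from None


def atomic_mass(symbol: str) -> float:
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise ValueError(f"no atomic mass tabulated for element {symbol!r}") from None
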