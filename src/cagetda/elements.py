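"""Element constants used for bond perception and component weighing.

Covalent radii are the Cordero single-bond values (Å); for carbon the sp3
radius is used, for Mn/Fe/Co the high-spin radius.  Atomic masses are the
conventional standard atomic weights.  The pseudo-element ``X`` is a dummy
site symbol emitted by the synthetic-shape writer so that geometric fixtures
can travel through the same file readers as real molecules; it carries a
carbon-like mass and radius.
"""

from __future__ import annotations

# symbol: (covalent radius / Å, atomic mass / u)
_ELEMENTS: dict[str, tuple[float, float]] = {
    "H": (0.31, 1.008), "He": (0.28, 4.003),
    "Li": (1.28, 6.94), "Be": (0.96, 9.012), "B": (0.84, 10.81),
    "C": (0.76, 12.011), "N": (0.71, 14.007), "O": (0.66, 15.999),
    "F": (0.57, 18.998), "Ne": (0.58, 20.180),
    "Na": (1.66, 22.990), "Mg": (1.41, 24.305), "Al": (1.21, 26.982),
    "Si": (1.11, 28.085), "P": (1.07, 30.974), "S": (1.05, 32.06),
    "Cl": (1.02, 35.45), "Ar": (1.06, 39.948),
    "K": (2.03, 39.098), "Ca": (1.76, 40.078), "Sc": (1.70, 44.956),
    "Ti": (1.60, 47.867), "V": (1.53, 50.942), "Cr": (1.39, 51.996),
    "Mn": (1.61, 54.938), "Fe": (1.52, 55.845), "Co": (1.50, 58.933),
    "Ni": (1.24, 58.693), "Cu": (1.32, 63.546), "Zn": (1.22, 65.38),
    "Ga": (1.22, 69.723), "Ge": (1.20, 72.630), "As": (1.19, 74.922),
    "Se": (1.20, 78.971), "Br": (1.20, 79.904), "Kr": (1.16, 83.798),
    "Rb": (2.20, 85.468), "Sr": (1.95, 87.62), "Y": (1.90, 88.906),
    "Zr": (1.75, 91.224), "Nb": (1.64, 92.906), "Mo": (1.54, 95.95),
    "Tc": (1.47, 98.0), "Ru": (1.46, 101.07), "Rh": (1.42, 102.906),
    "Pd": (1.39, 106.42), "Ag": (1.45, 107.868), "Cd": (1.44, 112.414),
    "In": (1.42, 114.818), "Sn": (1.39, 118.710), "Sb": (1.39, 121.760),
    "Te": (1.38, 127.60), "I": (1.39, 126.904), "Xe": (1.40, 131.293),
    "Cs": (2.44, 132.905), "Ba": (2.15, 137.327), "La": (2.07, 138.905),
    "Ce": (2.04, 140.116), "Pr": (2.03, 140.908), "Nd": (2.01, 144.242),
    "Pm": (1.99, 145.0), "Sm": (1.98, 150.36), "Eu": (1.98, 151.964),
    "Gd": (1.96, 157.25), "Tb": (1.94, 158.925), "Dy": (1.92, 162.500),
    "Ho": (1.92, 164.930), "Er": (1.89, 167.259), "Tm": (1.90, 168.934),
    "Yb": (1.87, 173.045), "Lu": (1.87, 174.967), "Hf": (1.75, 178.49),
    "Ta": (1.70, 180.948), "W": (1.62, 183.84), "Re": (1.51, 186.207),
    "Os": (1.44, 190.23), "Ir": (1.41, 192.217), "Pt": (1.36, 195.084),
    "Au": (1.36, 196.967), "Hg": (1.32, 200.592), "Tl": (1.45, 204.38),
    "Pb": (1.46, 207.2), "Bi": (1.48, 208.980), "Po": (1.40, 209.0),
    "At": (1.50, 210.0), "Rn": (1.50, 222.0),
    "Th": (2.06, 232.038), "U": (1.96, 238.029),
    # dummy site for synthetic geometric fixtures
    "X": (0.76, 12.011),
}

KNOWN_ELEMENTS = frozenset(_ELEMENTS)


def covalent_radius(symbol: str) -> float:
    """Covalent radius in Å; raises ValueError for unknown symbols."""
    try:
        return _ELEMENTS[symbol][0]
    except KeyError:
        raise ValueError(f"no covalent radius tabulated for element {symbol!r}") from None


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight in u; raises ValueError for unknown symbols."""
    try:
        return _ELEMENTS[symbol][1]
    except KeyError:
        raise ValueError(f"no atomic mass tabulated for element {symbol!r}") from None
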