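"""Element tables: covalent and van der Waals radii, supported elements.

Radii in Angstrom. Covalent radii follow Cordero et al. consensus values;
vdW radii follow Bondi with the common H = 1.10 revision.
"""

from __future__ import annotations

COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "K": 2.03,
    "Br": 1.20,
    "I": 1.39,
}

VDW_RADIUS: dict[str, float] = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Na": 2.27,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "K": 2.75,
    "Br": 1.85,
    "I": 1.98,
}

SUPPORTED_ELEMENTS = frozenset(COVALENT_RADIUS)


def normalize_element(symbol: str) -> str:
    """Canonicalise an element symbol ('CL', ' c' -> 'Cl', 'C')."""
    s = symbol.strip()
    if not s:
        raise ValueError("empty element symbol")
    s = s[0].upper() + s[1:].lower()
    if s not in SUPPORTED_ELEMENTS:
        raise ValueError(f"unsupported element: {symbol!r}")
    return s
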