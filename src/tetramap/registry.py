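"""Registry of the 15 chromatographically separated brGDGT compounds.

Branched glycerol dialkyl glycerol tetraethers (brGDGTs) are bacterial
membrane lipids whose degree of methylation and cyclization in soils tracks
temperature, pH and moisture.  Fifteen structures are routinely separated:
tetramethylated (I-series), pentamethylated (II-series) and hexamethylated
(III-series), each with 0-2 cyclopentane moieties (a/b/c) and, for the
penta- and hexamethylated series, a 5-methyl or 6-methyl positional isomer
(the 6-methyl isomer carries a prime mark, e.g. IIa′).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "Compound",
    "COMPOUNDS",
    "COMPOUND_NAMES",
    "SIX_METHYL",
    "FIVE_METHYL",
    "TETRAMETHYLATED",
    "canonical_name",
]

PRIME = "′"  # typographic prime used in compound names


@dataclass(frozen=True)
class Compound:
    """One brGDGT structure.

    Attributes
    ----------
    name : str
        Canonical identifier with a typographic prime for 6-methyl isomers
        (``IIa′``).
    methylation : str
        ``"tetra"``, ``"penta"`` or ``"hexa"``.
    cyclization : int
        Number of cyclopentane rings (0, 1 or 2).
    methyl_position : int | None
        5 or 6 for penta/hexamethylated compounds; ``None`` for the
        tetramethylated series, which has no positional isomerism.
    ion_mass : int
        Protonated molecular ion ([M+H]+) m/z monitored in SIM mode.
    """

    name: str
    methylation: str
    cyclization: int
    methyl_position: int | None
    ion_mass: int


def _series(prefix: str, methylation: str, masses: tuple[int, int, int],
            position: int | None) -> list[Compound]:
    suffix = PRIME if position == 6 else ""
    return [
        Compound(f"{prefix}{ring}{suffix}", methylation, i, position, m)
        for i, (ring, m) in enumerate(zip("abc", masses))
    ]


# [M+H]+ masses per series; a 5-methyl compound and its 6-methyl isomer share
# a mass and are distinguished chromatographically, not by m/z.
COMPOUNDS: tuple[Compound, ...] = tuple(
    _series("I", "tetra", (1022, 1020, 1018), None)
    + _series("II", "penta", (1036, 1034, 1032), 5)
    + _series("II", "penta", (1036, 1034, 1032), 6)
    + _series("III", "hexa", (1050, 1048, 1046), 5)
    + _series("III", "hexa", (1050, 1048, 1046), 6)
)

# registry order used everywhere a vector over compounds appears
COMPOUND_NAMES: tuple[str, ...] = tuple(c.name for c in COMPOUNDS)

SIX_METHYL: frozenset[str] = frozenset(
    c.name for c in COMPOUNDS if c.methyl_position == 6
)
FIVE_METHYL: frozenset[str] = frozenset(
    c.name for c in COMPOUNDS if c.methyl_position == 5
)
TETRAMETHYLATED: frozenset[str] = frozenset(
    c.name for c in COMPOUNDS if c.methyl_position is None
)

# SIM ion list monitored during LC-APCI-MS/MS acquisition; 744 is the C46
# glycerol trialkyl glycerol tetraether internal standard.
SIM_IONS: tuple[int, ...] = (
    1304, 1302, 1300, 1298, 1296, 1292,
    1050, 1048, 1046, 1036, 1034, 1032, 1020, 1018, 744,
)

INTERNAL_STANDARD_ION = 744

_ASCII_ALIASES = {name.replace(PRIME, "'"): name for name in COMPOUND_NAMES}
_ALL_NAMES = {name: name for name in COMPOUND_NAMES} | _ASCII_ALIASES


def canonical_name(name: str) -> str:
    """Map a compound label to its canonical spelling.

    Accepts both the typographic prime (``IIa′``) and the ASCII apostrophe
    (``IIa'``) used by different laboratories.

    Raises
    ------
    KeyError
        If the label is not one of the 15 brGDGTs.
    """
    key = name.strip()
    if key in _ALL_NAMES:
        return _ALL_NAMES[key]
    raise KeyError(f"unknown brGDGT compound: {name!r}")


def canonical_names(names: Iterable[str]) -> list[str]:
    """Vectorized :func:`canonical_name`."""
    return [canonical_name(n) for n in names]
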