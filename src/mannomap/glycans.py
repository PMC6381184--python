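"""Galactomannan oligosaccharides: names, formulas, and adduct masses.

A (galacto)mannooligosaccharide is modelled as a linear β-1,4-mannose
backbone of ``backbone_length`` units, numbered 1..n **from the reducing
end**, of which a subset carries a single α-1,6-galactosyl decoration.
Two naming conventions are supported and interconverted:

* the short M/G string, written non-reducing → reducing end, with ``G``
  marking a galactosylated backbone mannose (``MGGMM``), or ``Mn`` for an
  undecorated backbone of length *n*;
* the systematic form ``α-6^4-6^3-di-galactosyl-mannopentaose``, whose
  superscripts are the 1-based reducing-end positions of the decorations.

Masses are monoisotopic.  The sodium adduct is the neutral mass plus the
Na atomic mass with **no electron-mass subtraction** — this convention
reproduces the conventional MALDI-TOF reference masses for sodiated
mannotriose (527.159 Da) and mannotetraose (689.212 Da) exactly at three
decimals.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "MONOISOTOPIC_MASS",
    "Glycan",
    "ParseError",
    "parse_name",
    "format_name",
    "formula",
    "monoisotopic_mass",
    "residue_at_subsite",
]

# IUPAC monoisotopic atomic masses (Da)
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.0078250,
    "O": 15.9949146,
    "Na": 22.9897693,
}

WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]


class ParseError(ValueError):
    """A species name could not be parsed."""


@dataclass(frozen=True)
class Glycan:
    """A linear β-1,4-mannan backbone with α-1,6-galactosyl decorations.

    Parameters
    ----------
    backbone_length
        Number of backbone mannose units (≥ 1).
    decorations
        1-based backbone positions, counted from the reducing end, that
        carry one galactosyl unit.
    """

    backbone_length: int
    decorations: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "decorations", frozenset(self.decorations))
        if self.backbone_length < 1:
            raise ValueError("backbone_length must be >= 1")
        for d in self.decorations:
            if not 1 <= d <= self.backbone_length:
                raise ValueError(
                    f"decoration position {d} outside backbone 1..{self.backbone_length}"
                )

    @property
    def hexose_count(self) -> int:
        """Total hexose units: backbone mannoses plus galactosyl decorations."""
        return self.backbone_length + len(self.decorations)

    def __str__(self) -> str:
        return format_name(self, "short")


# ---------------------------------------------------------------------------
# name parsing / formatting

_BACKBONE_NAMES = {
    1: "mannose",
    2: "mannobiose",
    3: "mannotriose",
    4: "mannotetraose",
    5: "mannopentaose",
    6: "mannohexaose",
    7: "mannoheptaose",
    8: "mannooctaose",
    9: "mannononaose",
    10: "mannodecaose",
    11: "mannoundecaose",
    12: "mannododecaose",
}
_BACKBONE_FROM_NAME = {v: k for k, v in _BACKBONE_NAMES.items()}

_MULTIPLIER = {
    1: "",
    2: "di-",
    3: "tri-",
    4: "tetra-",
    5: "penta-",
    6: "hexa-",
    7: "hepta-",
    8: "octa-",
    9: "nona-",
    10: "deca-",
    11: "undeca-",
    12: "dodeca-",
}
_MULTIPLIER_FROM_PREFIX = {v.rstrip("-"): k for k, v in _MULTIPLIER.items() if v}

_SHORT_MN = re.compile(r"^M(\d+)$")
_SHORT_LETTERS = re.compile(r"^[MG]+$")
_SYSTEMATIC = re.compile(
    r"^(?:α|a|alpha)-"
    r"(?P<supers>(?:6\^\d+\^?-)+)"
    r"(?:(?P<mult>di|tri|tetra|penta|hexa|hepta|octa|nona|deca|undeca|dodeca)-)?"
    r"galactosyl-(?P<backbone>[a-z]+)$"
)


def parse_name(name: str) -> Glycan:
    """Parse a short (``MGGMM``, ``M5``) or systematic species name.

    The short-string letters run non-reducing → reducing end; systematic
    superscripts are 1-based reducing-end backbone positions.
    """
    name = name.strip()
    if not name:
        raise ParseError("empty species name")

    m = _SHORT_MN.match(name)
    if m:
        n = int(m.group(1))
        if n < 1:
            raise ParseError(f"invalid backbone length in {name!r}")
        return Glycan(n)

    if _SHORT_LETTERS.match(name):
        n = len(name)
        # left-to-right letter i (1-based) sits at backbone position n - i + 1
        dec = {n - i for i, letter in enumerate(name) if letter == "G"}
        return Glycan(n, frozenset(dec))

    m = _SYSTEMATIC.match(name)
    if m:
        backbone_name = m.group("backbone")
        if backbone_name not in _BACKBONE_FROM_NAME:
            raise ParseError(f"unknown backbone name {backbone_name!r} in {name!r}")
        n = _BACKBONE_FROM_NAME[backbone_name]
        supers = [int(s) for s in re.findall(r"6\^(\d+)", m.group("supers"))]
        mult = m.group("mult")
        expected = _MULTIPLIER_FROM_PREFIX[mult] if mult else 1
        if len(supers) != expected:
            raise ParseError(
                f"multiplier prefix {mult or 'mono'!r} does not match "
                f"{len(supers)} superscripts in {name!r}"
            )
        if len(set(supers)) != len(supers):
            raise ParseError(f"repeated decoration position in {name!r}")
        for s in supers:
            if not 1 <= s <= n:
                raise ValueError(
                    f"decoration superscript {s} exceeds backbone length {n} in {name!r}"
                )
        return Glycan(n, frozenset(supers))

    # plain systematic backbone name, e.g. "mannopentaose"
    if name in _BACKBONE_FROM_NAME:
        return Glycan(_BACKBONE_FROM_NAME[name])

    raise ParseError(f"unrecognised species name {name!r}")


def format_name(g: Glycan, style: Literal["short", "systematic"] = "short") -> str:
    """Format a glycan in the short or systematic convention.

    ``parse_name(format_name(g, style)) == g`` for both styles.
    """
    if style == "short":
        if not g.decorations:
            return f"M{g.backbone_length}"
        n = g.backbone_length
        return "".join(
            "G" if (n - i) in g.decorations else "M" for i in range(n)
        )
    if style == "systematic":
        if g.backbone_length not in _BACKBONE_NAMES:
            raise ValueError(f"no systematic name for backbone length {g.backbone_length}")
        base = _BACKBONE_NAMES[g.backbone_length]
        if not g.decorations:
            return base
        supers = sorted(g.decorations, reverse=True)
        prefix = "-".join(f"6^{s}" for s in supers)
        return f"α-{prefix}-{_MULTIPLIER[len(supers)]}galactosyl-{base}"
    raise ValueError(f"unknown style {style!r}")


# ---------------------------------------------------------------------------
# formulas and masses


def formula(g: Glycan) -> Counter:
    """Neutral molecular formula: h hexoses condensed with loss of h−1 waters.

    For h total hexoses this is C(6h) H(10h+2) O(5h+1).
    """
    h = g.hexose_count
    return Counter({"C": 6 * h, "H": 10 * h + 2, "O": 5 * h + 1})


def monoisotopic_mass(
    f: Counter | dict[str, int],
    adduct: Literal["neutral", "sodium"] = "neutral",
) -> float:
    """Monoisotopic mass of a formula, optionally as the sodium adduct.

    The sodium adduct adds the Na atomic mass (22.9897693 Da) with no
    electron-mass correction.
    """
    mass = 0.0
    for element, count in f.items():
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r}")
        if count < 0:
            raise ValueError(f"negative count for element {element!r}")
        mass += MONOISOTOPIC_MASS[element] * count
    if adduct == "sodium":
        mass += MONOISOTOPIC_MASS["Na"]
    elif adduct != "neutral":
        raise ValueError(f"unknown adduct {adduct!r}")
    return mass


def adduct_mz(g: Glycan) -> float:
    """Sodium-adduct monoisotopic m/z of a glycan (singly charged)."""
    return monoisotopic_mass(formula(g), "sodium")


def residue_at_subsite(g: Glycan, mode, subsite: int) -> tuple[int, bool]:
    """Backbone position and decoration flag of the residue bound at a subsite.

    ``mode`` is any object with ``k_neg``/``k_pos`` attributes describing a
    contiguous productive placement over subsites −k_neg..−1, +1..+k_pos.
    The reducing-most bound residue sits in the most positive subsite, so a
    residue at subsite +j is backbone position k_pos − j + 1 and a residue
    at −i is position k_pos + i.
    """
    if subsite == 0:
        raise ValueError("there is no subsite 0")
    if subsite > 0:
        if subsite > mode.k_pos:
            raise ValueError(f"subsite {subsite:+d} not occupied by mode {mode}")
        pos = mode.k_pos - subsite + 1
    else:
        if -subsite > mode.k_neg:
            raise ValueError(f"subsite {subsite:+d} not occupied by mode {mode}")
        pos = mode.k_pos - subsite  # k_pos + |subsite|
    if not 1 <= pos <= g.backbone_length:
        raise ValueError(
            f"mode {mode} does not fit substrate of backbone length {g.backbone_length}"
        )
    return pos, pos in g.decorations
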