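"""Elemental-composition algebra for CHNOS formula assignments.

Everything downstream of a molecular-formula assignment — double-bond
equivalents, van Krevelen coordinates, heteroatom-class keys, Kendrick
conversion — is a pure function of the neutral elemental composition.
Compositions here are always *neutral* formulas: the deprotonation implied
by negative-ion electrospray detection (the ``[H]`` suffix seen on class
labels) is rendering metadata, never an H-count change.

Scope is deliberately CHNOS-only with singly charged monoisotopic species;
isotopologues, adducts and other elements are out of scope.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "ElementalComposition",
    "HeteroatomClassKey",
    "VKPoint",
    "KendrickCoordinates",
    "FormulaError",
    "MONOISOTOPIC_MASS",
    "CH2_MASS",
    "parse_formula",
    "render_formula",
    "monoisotopic_mass",
    "dbe",
    "vk_point",
    "heteroatom_class",
    "kendrick",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid compositions."""


#: Exact masses of the most abundant isotope of each supported element (Da).
#: Carbon is 12 by definition of the unified atomic mass scale.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Exact mass of the CH2 repeat unit (Da), the Kendrick base.
CH2_MASS: float = MONOISOTOPIC_MASS["C"] + 2.0 * MONOISOTOPIC_MASS["H"]

_ELEMENT_ORDER = ("C", "H", "N", "O", "S")
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True, order=True)
class ElementalComposition:
    """Integer CHNOS element counts of a neutral molecular formula."""

    c: int
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise FormulaError(f"element count {name!r} must be an integer, got {value!r}")
            if value < 0:
                raise FormulaError(f"element count {name!r} must be >= 0, got {value}")

    @property
    def counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s}

    def __str__(self) -> str:  # pragma: no cover - convenience
        return render_formula(self)


class VKPoint(NamedTuple):
    """A point in van Krevelen compositional space."""

    oc: float
    hc: float


class KendrickCoordinates(NamedTuple):
    kendrick_mass: float
    kendrick_mass_defect: float


@dataclass(frozen=True)
class HeteroatomClassKey:
    """Heteroatom class of a composition: its (N, O, S) counts.

    Two compositions with equal (n, o, s) share a class regardless of their
    carbon and hydrogen content.  ``label`` renders like ``"O2"``,
    ``"O19S3"`` or ``"N1O4S1"``; pure hydrocarbons render as ``"HC"``.
    ``group`` is the coarse family used in class-distribution tables:
    one of ``"Oo"``, ``"OoSs"``, ``"NnOo"``, ``"NnOoSs"``, ``"HC"``.
    """

    n: int
    o: int
    s: int

    @property
    def label(self) -> str:
        if self.n == 0 and self.o == 0 and self.s == 0:
            return "HC"
        parts = []
        if self.n:
            parts.append(f"N{self.n}")
        if self.o:
            parts.append(f"O{self.o}")
        if self.s:
            parts.append(f"S{self.s}")
        return "".join(parts)

    @property
    def group(self) -> str:
        has_n, has_o, has_s = self.n > 0, self.o > 0, self.s > 0
        if not (has_n or has_o or has_s):
            return "HC"
        key = ""
        if has_n:
            key += "Nn"
        if has_o:
            key += "Oo"
        if has_s:
            key += "Ss"
        return key


def parse_formula(text: str) -> ElementalComposition:
    """Parse an element-count string like ``"C9H12O2"``.

    Only C, H, N, O and S are accepted, each at most once, optionally
    followed by a positive integer count (implicit 1 when absent).
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"empty or non-string formula: {text!r}")
    stripped = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN_RE.finditer(stripped):
        if match.start() != pos:
            raise FormulaError(
                f"malformed formula {stripped!r}: unexpected token "
                f"{stripped[pos:match.start()]!r}"
            )
        if not match.group(0):
            break
        symbol, digits = match.group(1), match.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {symbol!r} in {stripped!r}")
        if symbol in counts:
            raise FormulaError(f"repeated element {symbol!r} in {stripped!r}")
        if digits and int(digits) == 0:
            raise FormulaError(f"zero count for element {symbol!r} in {stripped!r}")
        counts[symbol] = int(digits) if digits else 1
        pos = match.end()
    if pos != len(stripped):
        raise FormulaError(f"malformed formula {stripped!r}: trailing {stripped[pos:]!r}")
    if not counts:
        raise FormulaError(f"no elements found in {stripped!r}")
    return ElementalComposition(
        c=counts.get("C", 0),
        h=counts.get("H", 0),
        n=counts.get("N", 0),
        o=counts.get("O", 0),
        s=counts.get("S", 0),
    )


def render_formula(comp: ElementalComposition) -> str:
    """Render in Hill-like C, H, N, O, S order; count 1 is implicit."""
    parts = []
    for symbol in _ELEMENT_ORDER:
        count = comp.counts[symbol]
        if count == 1:
            parts.append(symbol)
        elif count > 1:
            parts.append(f"{symbol}{count}")
    if not parts:
        raise FormulaError("cannot render the empty composition")
    return "".join(parts)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Exact neutral monoisotopic mass in Da."""
    return math.fsum(count * MONOISOTOPIC_MASS[sym] for sym, count in comp.counts.items())


def dbe(comp: ElementalComposition) -> float:
    """Double-bond equivalents: c - h/2 + n/2 + 1.

    The raw formula value is returned even when half-integral
    (odd-electron or odd-nitrogen cases); callers decide how to treat it.
    """
    return comp.c - comp.h / 2.0 + comp.n / 2.0 + 1.0


def vk_point(comp: ElementalComposition) -> VKPoint:
    """Van Krevelen coordinates (O/C, H/C) of a composition."""
    if comp.c < 1:
        raise FormulaError(f"van Krevelen ratios undefined for c=0 composition {comp!r}")
    return VKPoint(oc=comp.o / comp.c, hc=comp.h / comp.c)


def heteroatom_class(comp: ElementalComposition) -> HeteroatomClassKey:
    return HeteroatomClassKey(n=comp.n, o=comp.o, s=comp.s)


def kendrick(mz: float) -> KendrickCoordinates:
    """Convert an IUPAC m/z to Kendrick mass and Kendrick mass defect.

    The Kendrick scale rescales mass by 14/(exact CH2 mass), i.e.
    14.00000/14.0156500641, so that members of a CH2 homologous series
    share a mass defect that is constant to machine precision (the
    commonly printed factor 14.01565 is this constant rounded).  The
    nominal mass used for the defect is the *nearest* integer of the
    Kendrick mass, keeping defects in (-0.5, 0.5].
    """
    if not (mz > 0):
        raise ValueError(f"m/z must be positive, got {mz!r}")
    km = mz * 14.0 / CH2_MASS
    kmd = round(km) - km
    return KendrickCoordinates(kendrick_mass=km, kendrick_mass_defect=kmd)
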