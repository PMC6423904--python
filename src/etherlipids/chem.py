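"""Elemental-formula algebra and exact monoisotopic mass computation.

All masses in the package flow through this module: formulas are immutable
element->count maps, masses are sums of IUPAC monoisotopic atomic masses, and
singly charged adduct ions ([M+H]+, [M+NH4]+, [M+Na]+) use electron-corrected
adduct deltas so that theoretical m/z values are directly comparable with
high-resolution (Orbitrap) measurements at the ppm level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "Formula",
    "AtomicMassTable",
    "Adduct",
    "ADDUCTS",
    "DEFAULT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "mz",
    "cation_mz",
    "ppm_error",
]

# IUPAC monoisotopic masses of the most abundant isotope (Da).
DEFAULT_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

PROTON_MASS = 1.007276466  # H minus one electron
ELECTRON_MASS = 0.00054857990907


class FormulaError(ValueError):
    """Raised for malformed formula strings, unknown elements or negative counts."""


class AtomicMassTable:
    """Immutable element -> monoisotopic mass lookup.

    The default table covers every element used by the lipid library; a
    user-supplied mapping (e.g. loaded from a YAML config) overrides or
    extends it.
    """

    def __init__(self, overrides: Mapping[str, float] | None = None):
        masses = dict(DEFAULT_MASSES)
        if overrides:
            masses.update(overrides)
        self._masses = masses

    def __getitem__(self, element: str) -> float:
        try:
            return self._masses[element]
        except KeyError:
            raise FormulaError(f"unknown element symbol: {element!r}") from None

    def __contains__(self, element: str) -> bool:
        return element in self._masses


_DEFAULT_TABLE = AtomicMassTable()

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """An elemental formula: an immutable map from element symbol to count.

    Supports element-wise addition, subtraction (negative results raise),
    and integer scaling. Hashable, so usable as a dict key.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                if n < 0:
                    raise FormulaError(f"negative count for {el}: {n}")
                if int(n) != n:
                    raise FormulaError(f"non-integer count for {el}: {n}")
                if n:
                    merged[el] = merged.get(el, 0) + int(n)
        self._counts = merged
        self._hash = hash(frozenset(merged.items()))

    # Mapping interface -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self):
        return len(self._counts)

    def __hash__(self):
        return self._hash

    def __eq__(self, other):
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    # Algebra -----------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction gives negative {el} count: "
                    f"{self} - {other}"
                )
            counts[el] = new
        return Formula(counts)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula can only be scaled by a non-negative int, got {k!r}")
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def contains(self, other: "Formula") -> bool:
        """True if ``other`` is a sub-formula (element-wise <=) of self."""
        return all(self[el] >= n for el, n in other.items())

    # Formatting --------------------------------------------------------
    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:
        return f"Formula({format_formula(self)!r})"

    def mass(self, table: AtomicMassTable | None = None) -> float:
        return monoisotopic_mass(self, table)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string such as ``"C43H88O3"``.

    An omitted count means 1. Raises :class:`FormulaError` on malformed
    strings or unknown element symbols.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"malformed formula string: {text!r}")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula string: {text!r}")
        if not m.group(0):
            break
        el, num = m.group(1), m.group(2)
        if el not in _DEFAULT_TABLE:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula string: {text!r}")
    return Formula(counts)


def format_formula(f: Mapping[str, int]) -> str:
    """Format in Hill order: C, H, then remaining elements alphabetically."""
    parts = []
    for el in ("C", "H"):
        n = f.get(el, 0) if hasattr(f, "get") else f[el]
        if n:
            parts.append(el + (str(n) if n != 1 else ""))
    for el in sorted(k for k in f if k not in ("C", "H")):
        n = f[el]
        if n:
            parts.append(el + (str(n) if n != 1 else ""))
    return "".join(parts)


def monoisotopic_mass(f: Mapping[str, int], table: AtomicMassTable | None = None) -> float:
    """Exact monoisotopic mass (Da) of a neutral formula."""
    table = table or _DEFAULT_TABLE
    return sum(table[el] * n for el, n in f.items())


@dataclass(frozen=True)
class Adduct:
    """A singly charged positive-mode adduct: m/z = M + delta."""

    name: str
    delta: float
    charge: int = 1


# Electron-corrected deltas: e.g. [M+H]+ adds a proton, not a hydrogen atom.
ADDUCTS: dict[str, Adduct] = {
    "+H": Adduct("+H", PROTON_MASS),
    "+NH4": Adduct("+NH4", 18.033823),
    "+Na": Adduct("+Na", 22.989218),
}


def _resolve_adduct(a: "Adduct | str") -> Adduct:
    if isinstance(a, Adduct):
        return a
    try:
        return ADDUCTS[a]
    except KeyError:
        raise FormulaError(f"unsupported adduct: {a!r}") from None


def mz(f: Mapping[str, int], adduct: "Adduct | str", table: AtomicMassTable | None = None) -> float:
    """m/z of the singly charged adduct ion of neutral species ``f``."""
    a = _resolve_adduct(adduct)
    return monoisotopic_mass(f, table) + a.delta


def cation_mz(f: Mapping[str, int], table: AtomicMassTable | None = None) -> float:
    """m/z of an even-electron cation whose atoms are exactly ``f``.

    Used for fragment ions that are intact cations (e.g. the quaternary
    ammonium headgroup fragments) rather than protonated neutrals: the atom
    sum minus one electron mass.
    """
    return monoisotopic_mass(f, table) - ELECTRON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error in parts per million."""
    return (observed - theoretical) / theoretical * 1e6


def formulas(texts: Iterable[str]) -> list[Formula]:
    return [parse_formula(t) for t in texts]
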