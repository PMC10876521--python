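"""Molecular formulas, exact monoisotopic masses, and adduct m/z arithmetic.

Deuterium (``D``) is modeled as a distinct element symbol rather than an
attribute of H, so that formula addition/subtraction for isotope-labeled
species remains integer-exact.  Ion m/z values include the electron mass:
for a neutral M,

    m/z([M-H]-) = mass(M) - m(1H) + m(e)
    m/z([M+H]+) = mass(M) + m(1H) - m(e)

Omitting the electron term shifts 4-decimal m/z values by ~0.0005 Th, which
is enough to miss high-resolution values quoted to 0.0001 Th.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, Mapping, Tuple

__all__ = [
    "ISOTOPE_MASS",
    "ELECTRON_MASS",
    "DELTA_D",
    "MolecularFormula",
    "Adduct",
    "ADDUCTS",
    "M_MINUS_H",
    "M_PLUS_H",
    "parse_formula",
    "monoisotopic_mass",
    "mz_for_adduct",
    "deuterium_shift",
    "ppm_window",
    "ppm_error",
]


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formulas."""


def _load_masses() -> Dict[str, float]:
    with resources.files("befa.data").joinpath("isotope_masses.json").open() as fh:
        raw = json.load(fh)
    return {k: float(v) for k, v in raw.items() if not k.startswith("_")}


_MASSES = _load_masses()

#: monoisotopic mass of each supported element symbol, Da
ISOTOPE_MASS: Mapping[str, float] = {k: v for k, v in _MASSES.items() if k != "e"}

#: electron rest mass, Da
ELECTRON_MASS: float = _MASSES["e"]

#: exact mass difference of one D-for-H substitution, Da (~1.0062768)
DELTA_D: float = ISOTOPE_MASS["D"] - ISOTOPE_MASS["H"]

# Hill convention: C first, H next (D kept adjacent to H), then alphabetical.
_HILL_ORDER = ("C", "H", "D", "N", "O", "P", "S")

_ELEMENTS = set(ISOTOPE_MASS)
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with exact-mass arithmetic.

    Counts are non-negative; a formula with zero atoms is invalid.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in _ELEMENTS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n:
                clean[el] = n
        if not clean:
            raise FormulaError("formula contains no atoms")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.counts.items())

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"subtraction yields negative {el} count ({merged[el]})"
                )
        return MolecularFormula(merged)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def hill(self) -> str:
        """Canonical Hill-order string; counts of 1 are left implicit."""
        parts = []
        for el in _HILL_ORDER:
            n = self.counts.get(el, 0)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse an element-count string such as ``"C11H20O2"`` or ``"C11H9D11O4"``.

    Repeated element tokens are summed.  Raises :class:`FormulaError` naming
    the offending token for unknown symbols or malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed token at {text[pos:]!r} in {text!r}")
        el, digits = m.groups()
        if el not in _ELEMENTS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Exact monoisotopic mass in Da: sum of count x isotope mass."""
    return sum(n * ISOTOPE_MASS[el] for el, n in f)


@dataclass(frozen=True)
class Adduct:
    """Singly charged ESI adduct: hydrogen and electron deltas vs the neutral."""

    name: str
    charge: int  # +1 or -1
    h_delta: int  # protons-as-hydrogens added to the neutral
    e_delta: int  # electrons added

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")


M_MINUS_H = Adduct("[M-H]-", charge=-1, h_delta=-1, e_delta=+1)
M_PLUS_H = Adduct("[M+H]+", charge=+1, h_delta=+1, e_delta=-1)

ADDUCTS: Mapping[str, Adduct] = {a.name: a for a in (M_MINUS_H, M_PLUS_H)}


def mz_for_adduct(f: MolecularFormula, adduct: Adduct) -> float:
    """m/z of the adduct ion of neutral formula ``f`` (full double precision).

    Display values in this field are conventionally rounded to 4 decimals;
    rounding is left to the caller.
    """
    if adduct.h_delta < 0 and f["H"] < -adduct.h_delta:
        raise FormulaError(
            f"cannot remove {-adduct.h_delta} H from {f.hill()} (has {f['H']})"
        )
    return (
        monoisotopic_mass(f)
        + adduct.h_delta * ISOTOPE_MASS["H"]
        + adduct.e_delta * ELECTRON_MASS
    )


def deuterium_shift(n: int) -> float:
    """Exact mass shift in Da of ``n`` D-for-H substitutions (n >= 0)."""
    if n < 0:
        raise ValueError("deuterium count must be non-negative")
    return n * DELTA_D


def ppm_window(mz: float, tol_ppm: float) -> Tuple[float, float]:
    """Closed interval [lo, hi] spanning ``tol_ppm`` parts-per-million around mz."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if tol_ppm < 0:
        raise ValueError("ppm tolerance must be non-negative")
    return mz * (1.0 - tol_ppm * 1e-6), mz * (1.0 + tol_ppm * 1e-6)


def ppm_error(observed: float, expected: float) -> float:
    """Signed relative mass error of ``observed`` vs ``expected`` in ppm."""
    return (observed - expected) / expected * 1e6
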