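"""Monoisotopic mass bookkeeping: molecular formulas, residue tables, m/z.

Everything downstream (peptide variants, cross-link assembly, EIC target
lists) is integer element arithmetic on top of a single table of IUPAC
monoisotopic element masses. Masses are stored to >=6 decimal places so
that two-decimal instrument-style m/z values round correctly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources as _resources
from typing import Iterator, Mapping

__all__ = [
    "ELEMENT_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "parse_formula",
    "monoisotopic_mass",
    "mz",
    "round_half_up",
    "WATER",
    "AMMONIA",
    "HEXOSE",
    "residue_table",
    "free_amino_acid",
]

#: IUPAC monoisotopic masses of the elements handled here (Da).
ELEMENT_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of a proton (Da); the only charge adduct modelled ([M+zH]z+).
PROTON_MASS = 1.007276466

_HILL_FIRST = ("C", "H")
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Immutable element-count vector with element-wise arithmetic.

    Counts are non-negative integers; subtraction that would drive any
    count negative raises ``ValueError`` (chemically meaningless here).
    """

    counts: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for element, n in dict(self.counts).items():
            if element not in ELEMENT_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {element} must be a non-negative int, got {n!r}")
            if n:
                cleaned[element] = n
        object.__setattr__(self, "counts", tuple(sorted(cleaned.items())))

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "MolecularFormula":
        return cls(tuple(counts.items()))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = self.as_dict()
        for element, n in other:
            out[element] = out.get(element, 0) + n
        return MolecularFormula.from_dict(out)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = self.as_dict()
        for element, n in other:
            new = out.get(element, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {element} count "
                    f"({self.to_string()} - {other.to_string()})"
                )
            out[element] = new
        return MolecularFormula.from_dict(out)

    def __mul__(self, k: int) -> "MolecularFormula":
        if not isinstance(k, int) or k < 0:
            raise ValueError("formula multiplier must be a non-negative int")
        return MolecularFormula.from_dict({e: n * k for e, n in self.counts})

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (linear in the counts)."""
        return sum(n * ELEMENT_MASS[e] for e, n in self.counts)

    def to_string(self) -> str:
        """Canonical Hill-order string: C, H, then other elements A-Z."""
        d = self.as_dict()
        parts = []
        for element in _HILL_FIRST:
            if element in d:
                parts.append(f"{element}{d[element] if d[element] != 1 else ''}")
        for element in sorted(e for e in d if e not in _HILL_FIRST):
            parts.append(f"{element}{d[element] if d[element] != 1 else ''}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MolecularFormula({self.to_string() or 'empty'})"


def parse_formula(text: str) -> MolecularFormula:
    """Parse ``"C24H43N7O8"``-style strings into a :class:`MolecularFormula`.

    The empty string is the empty formula (mass 0). Repeated element
    symbols accumulate. Unknown symbols or malformed counts raise
    ``ValueError``.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula at position {pos}: {text!r}")
        element, digits = match.groups()
        if element not in ELEMENT_MASS:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        if digits == "0":
            raise ValueError(f"malformed count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula at position {pos}: {text!r}")
    return MolecularFormula.from_dict(counts)


def monoisotopic_mass(f: MolecularFormula | str) -> float:
    """Monoisotopic mass in Da of a formula (or formula string)."""
    if isinstance(f, str):
        f = parse_formula(f)
    return f.mass


def mz(mass: float, charge: int) -> float:
    """m/z of the [M+zH]z+ ion of a neutral species of the given mass."""
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    return (mass + charge * PROTON_MASS) / charge


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Instrument-style printed values (e.g. 558.3246 -> 558.32) follow this
    convention rather than banker's rounding.
    """
    x = float(x)
    if x != x or x in (float("inf"), float("-inf")):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


WATER = parse_formula("H2O")
AMMONIA = parse_formula("NH3")
HEXOSE = parse_formula("C6H10O5")  # anhydro-hexose: one glycosylation step

_RESIDUES: dict[str, MolecularFormula] | None = None


def residue_table() -> dict[str, MolecularFormula]:
    """Residue code -> chain-form (no water) formula, from the CSV resource.

    Covers the 20 standard residues plus the collagen set: Hyp, Hyl,
    G-Hyl, GG-Hyl, allysine (``Lysald``), hydroxyallysine (``Hylald``)
    and N-terminal pyroglutamate (``pyroQ``). Returned dict is a copy;
    callers may extend it without affecting the shipped table.
    """
    global _RESIDUES
    if _RESIDUES is None:
        table: dict[str, MolecularFormula] = {}
        with _resources.files("collagen_ptm.resources").joinpath("residues.csv").open() as fh:
            for row in csv.DictReader(fh):
                table[row["code"]] = parse_formula(row["formula"])
        _RESIDUES = table
    return dict(_RESIDUES)


def free_amino_acid(code: str) -> MolecularFormula:
    """Free (hydrated) form of a residue: chain form + H2O.

    This is the currency of cross-link assembly, which condenses free
    amino acids rather than peptide-bound residues.
    """
    table = residue_table()
    if code not in table:
        raise KeyError(f"unknown residue code {code!r}")
    return table[code] + WATER
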