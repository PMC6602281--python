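"""Assembly, fragmentation and assignment of reducible collagen cross-links.

Lysyl-oxidase chemistry in soft tissue starts from telopeptidyl allysine
(Lys^ald). An allysine condenses with a helical Lys or Hyl to give the
bifunctional aldimines dehydro-LNL / dehydro-HLNL; two allysines first
form an aldol condensation product (ACP, one water loss) that condenses
with a helical His and a Lys or Hyl to give the tetrafunctional
dehydro-d-HHMD / dehydro-HHMD. Borohydride reduction (+H2 per reduced
bond) yields the stable species measured by MS:

    LNL     = Lys^ald + Lys       - H2O  + H2   (C12H25N3O4, [M+H]+ 276.19)
    HLNL    = Lys^ald + Hyl       - H2O  + H2   (C12H25N3O5, [M+H]+ 292.19)
    HHMD    = 2 Lys^ald + His + Hyl - 2 H2O + H2  (C24H43N7O9, [M+H]+ 574.32)
    d-HHMD  = 2 Lys^ald + His + Lys - 2 H2O + H2  (C24H43N7O8, [M+H]+ 558.32)

Components are free amino acids (chain form + H2O); all arithmetic is
exact integer element bookkeeping from :mod:`collagen_ptm.chem`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources as _resources
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

from .chem import (
    HEXOSE,
    WATER,
    MolecularFormula,
    free_amino_acid,
    mz,
    parse_formula,
)

__all__ = [
    "CrosslinkSpecies",
    "FragmentSet",
    "Fragment",
    "SpeciesAssignment",
    "assemble",
    "builtin_species",
    "enumerate_fragments",
    "assign_species",
    "DEFAULT_LOSS_GRAMMAR",
    "DEFAULT_MS2_TOLERANCE",
]

_H2 = parse_formula("H2")
_H = parse_formula("H")

#: Neutral losses seen in the MS/MS spectra of these species.
DEFAULT_LOSS_GRAMMAR: Mapping[str, MolecularFormula] = {
    "NH3": parse_formula("NH3"),
    "H2O": WATER,
    "HCOOH": parse_formula("CH2O2"),
}

DEFAULT_MS2_TOLERANCE = 0.02


@dataclass(frozen=True)
class CrosslinkSpecies:
    """An assembled cross-link with full provenance of its arithmetic."""

    name: str
    components: tuple[str, ...]  # free amino-acid codes, e.g. ("Lysald", "K")
    n_water: int
    n_h2: int
    n_hexose: int
    formula: MolecularFormula

    @property
    def mass(self) -> float:
        return self.formula.mass

    def mh(self, charge: int = 1) -> float:
        """[M+zH]z+ m/z."""
        return mz(self.mass, charge)


@dataclass(frozen=True)
class Fragment:
    label: str
    formula: MolecularFormula

    @property
    def mz(self) -> float:
        return mz(self.formula.mass, 1)


@dataclass(frozen=True)
class FragmentSet:
    precursor: CrosslinkSpecies
    fragments: tuple[Fragment, ...]
    grammar: tuple[str, ...]

    def mz_values(self) -> list[float]:
        return [f.mz for f in self.fragments]


@dataclass(frozen=True)
class SpeciesAssignment:
    observed_precursor: float
    decision: str  # "assigned" | "ambiguous" | "unassigned"
    species: CrosslinkSpecies | None
    matched_fragments: tuple[tuple[float, float, float], ...]  # (obs, theo, delta)
    n_matched: int


def assemble(
    name: str,
    components: Sequence[str] | None = None,
    n_water: int | None = None,
    n_h2: int | None = None,
    n_hexose: int = 0,
) -> CrosslinkSpecies:
    """Build a cross-link species from a built-in recipe name or an explicit one.

    formula = sum of component free amino acids - n_water*H2O + n_h2*H2
              + n_hexose*C6H10O5

    With only ``name`` given, the recipe is looked up in the shipped
    recipe table (LNL, HLNL, G-HLNL, GG-HLNL, HHMD, d-HHMD, ACP and the
    dehydro- precursors). Subtraction that exhausts an element raises.
    """
    if components is None:
        recipes = _load_recipes()
        if name not in recipes:
            raise KeyError(f"unknown cross-link recipe {name!r}")
        components, n_water, n_h2, n_hexose = recipes[name]
    if n_water is None or n_h2 is None:
        raise ValueError("explicit recipes need components, n_water and n_h2")
    total = MolecularFormula()
    for code in components:
        total = total + free_amino_acid(code)
    total = total - n_water * WATER + n_h2 * _H2 + n_hexose * HEXOSE
    return CrosslinkSpecies(
        name=name,
        components=tuple(components),
        n_water=n_water,
        n_h2=n_h2,
        n_hexose=n_hexose,
        formula=total,
    )


_RECIPES: dict[str, tuple[tuple[str, ...], int, int, int]] | None = None


def _load_recipes() -> dict[str, tuple[tuple[str, ...], int, int, int]]:
    global _RECIPES
    if _RECIPES is None:
        out = {}
        with _resources.files("collagen_ptm.resources").joinpath("xlink_recipes.csv").open() as fh:
            for row in csv.DictReader(fh):
                out[row["name"]] = (
                    tuple(row["components"].split(";")),
                    int(row["n_water"]),
                    int(row["n_h2"]),
                    int(row["n_hexose"]),
                )
        _RECIPES = out
    return dict(_RECIPES)


def builtin_species(names: Iterable[str] = ("LNL", "HLNL", "HHMD", "d-HHMD")) -> list[CrosslinkSpecies]:
    return [assemble(n) for n in names]


def enumerate_fragments(
    species: CrosslinkSpecies,
    grammar: Mapping[str, MolecularFormula] = DEFAULT_LOSS_GRAMMAR,
    max_losses: int = 3,
) -> FragmentSet:
    """Theoretical singly charged MS/MS fragments of a cross-link.

    Two mechanisms are modelled:

    * combined neutral losses from the precursor — every multiset of up
      to ``max_losses`` losses drawn from the grammar;
    * component release — heterolytic cleavage releasing one intact
      component amino acid with a single H transfer either way, giving
      both the released free amino acid (e.g. His from HHMD at m/z
      156.08) and its complement, each as the +/-H and no-transfer forms.

    Fragments are deduplicated by formula and sorted by m/z; every
    fragment m/z is <= the precursor [M+H]+.
    """
    candidates: dict[MolecularFormula, str] = {}

    def _add(formula: MolecularFormula, label: str) -> None:
        candidates.setdefault(formula, label)

    _add(species.formula, "[M+H]+")
    loss_names = sorted(grammar)
    for k in range(1, max_losses + 1):
        for combo in combinations_with_replacement(loss_names, k):
            f = species.formula
            try:
                for name in combo:
                    f = f - grammar[name]
            except ValueError:
                continue
            _add(f, "[M+H-" + "-".join(combo) + "]+")
    for code in set(species.components):
        released = free_amino_acid(code)
        try:
            complement = species.formula - released
        except ValueError:
            complement = None
        for shift, tag in ((MolecularFormula(), ""), (_H, "+H"), (None, "-H")):
            for base, label in ((released, f"{code}{tag}"), (complement, f"[M-{code}{tag}]")):
                if base is None:
                    continue
                try:
                    f = base + shift if shift is not None else base - _H
                except ValueError:
                    continue
                if f.mass <= species.mass:
                    _add(f, label)
    fragments = tuple(
        sorted((Fragment(label, f) for f, label in candidates.items()), key=lambda fr: fr.mz)
    )
    return FragmentSet(precursor=species, fragments=fragments, grammar=tuple(loss_names))


def assign_species(
    observed_precursor: float,
    observed_fragments: Sequence[float],
    candidates: Sequence[CrosslinkSpecies],
    tolerance: float = DEFAULT_MS2_TOLERANCE,
    grammar: Mapping[str, MolecularFormula] = DEFAULT_LOSS_GRAMMAR,
    max_losses: int = 3,
) -> SpeciesAssignment:
    """Assign an observed (precursor, fragments) spectrum to a candidate.

    A candidate is eligible when its [M+H]+ lies within ``tolerance`` of
    the observed precursor; among eligible candidates the one matching
    the most observed fragments (each within ``tolerance``) wins. A tie
    is reported as ``ambiguous``; no eligible precursor as ``unassigned``.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    scored: list[tuple[int, CrosslinkSpecies, tuple[tuple[float, float, float], ...]]] = []
    for cand in candidates:
        if abs(cand.mh(1) - observed_precursor) > tolerance:
            continue
        theo = enumerate_fragments(cand, grammar, max_losses).mz_values()
        matches = []
        for obs in observed_fragments:
            best = min(theo, key=lambda t: abs(t - obs), default=None)
            if best is not None and abs(best - obs) <= tolerance:
                matches.append((obs, best, obs - best))
        scored.append((len(matches), cand, tuple(matches)))
    if not scored:
        return SpeciesAssignment(observed_precursor, "unassigned", None, (), 0)
    scored.sort(key=lambda item: item[0], reverse=True)
    best_n = scored[0][0]
    if len(scored) > 1 and scored[1][0] == best_n:
        return SpeciesAssignment(observed_precursor, "ambiguous", None, (), best_n)
    n, species, matches = scored[0]
    return SpeciesAssignment(observed_precursor, "assigned", species, matches, n)
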