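"""Marker-peptide modification variants and EIC target lists.

A collagen molecular site (e.g. alpha1(I) Lys-87) is observed through one
marker peptide whose lysine(s) can carry a state from {Lys, Hyl, G-Hyl,
GG-Hyl} (helical sites) or {Lys, Lys^ald, Hyl} (telopeptidyl sites).
This module enumerates the mass-distinct occupancy classes of a site and
turns them into extracted-ion-chromatogram (EIC) queries at the desired
charge states.

Site numbering follows the collagen convention: helical residue number
from the start of the triple helix, telopeptide residues superscripted
N/C. Most shipped marker sequences are synthetic collagen-like stand-ins
(see ``sites.csv``, column ``synthetic``); quantification depends only on
the modification mass deltas, which are exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources as _resources
from itertools import product
from typing import Iterable, Mapping, Sequence

from .chem import AMMONIA, WATER, MolecularFormula, mz, residue_table

__all__ = [
    "SiteDefinition",
    "PeptideSpecies",
    "OccupancyClass",
    "EICQuery",
    "load_sites",
    "peptide_formula",
    "peptide_mass",
    "enumerate_variants",
    "build_eic_queries",
    "DEFAULT_TOLERANCE",
]

#: Absolute EIC m/z half-window (instrument mass precision), in m/z units.
DEFAULT_TOLERANCE = 0.02

#: Canonical ordering of modification states for class labels.
_STATE_ORDER = {"Lys": 0, "Lysald": 1, "Hyl": 2, "G-Hyl": 3, "GG-Hyl": 4}

#: Residue code substituted for the base Lys for each state.
_STATE_RESIDUE = {"Lys": "K", "Lysald": "Lysald", "Hyl": "Hyl", "G-Hyl": "G-Hyl", "GG-Hyl": "GG-Hyl"}


@dataclass(frozen=True)
class SiteDefinition:
    """One modifiable molecular site carried by one marker peptide."""

    chain: str
    label: str
    sequence: str
    pyro_glu: bool
    mod_positions: tuple[int, ...]  # 1-based, must be K in the base sequence
    allowed_states: tuple[tuple[str, ...], ...]  # per modifiable position
    hyp_positions: tuple[int, ...] = ()  # 1-based prolines fixed as 4-Hyp
    synthetic: bool = True

    def __post_init__(self) -> None:
        if len(self.mod_positions) != len(self.allowed_states):
            raise ValueError(f"{self.label}: one state set per modifiable position required")
        for pos in self.mod_positions:
            if not (1 <= pos <= len(self.sequence)) or self.sequence[pos - 1] != "K":
                raise ValueError(f"{self.label}: modifiable position {pos} is not Lys")
        for states in self.allowed_states:
            for s in states:
                if s not in _STATE_RESIDUE:
                    raise ValueError(f"{self.label}: unknown modification state {s!r}")
        for pos in self.hyp_positions:
            if self.sequence[pos - 1] != "P":
                raise ValueError(f"{self.label}: Hyp position {pos} is not Pro")

    @property
    def telopeptide(self) -> bool:
        return "^" in self.label


@dataclass(frozen=True)
class PeptideSpecies:
    """One mass-distinct modified form of a marker peptide."""

    site: SiteDefinition
    states: tuple[str, ...]
    formula: MolecularFormula
    charge: int = 0  # 0 = neutral

    @property
    def mass(self) -> float:
        return self.formula.mass

    @property
    def mz(self) -> float:
        if self.charge < 1:
            raise ValueError("neutral species has no m/z; set a charge >= 1")
        return mz(self.mass, self.charge)


@dataclass(frozen=True)
class OccupancyClass:
    """A mass-distinct occupancy class (isobaric positional isomers collapse)."""

    label: str
    species: PeptideSpecies
    n_isomers: int = 1

    @property
    def mass(self) -> float:
        return self.species.mass


@dataclass(frozen=True)
class EICQuery:
    """A single extracted-ion-chromatogram request."""

    target_mz: float
    tolerance: float = DEFAULT_TOLERANCE
    charge: int = 1
    class_label: str = ""
    rt_window: tuple[float, float] | None = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("EIC tolerance must be > 0")


def _auto_hyp_positions(sequence: str) -> tuple[int, ...]:
    """Prolines at the Y position of a G-X-Y triplet (i.e. two after a Gly)."""
    return tuple(
        p for p in range(3, len(sequence) + 1)
        if sequence[p - 1] == "P" and sequence[p - 3] == "G"
    )


def load_sites() -> dict[tuple[str, str], SiteDefinition]:
    """Load the shipped site table, keyed by (chain, label)."""
    sites: dict[tuple[str, str], SiteDefinition] = {}
    with _resources.files("collagen_ptm.resources").joinpath("sites.csv").open() as fh:
        for row in csv.DictReader(fh):
            seq = row["sequence"]
            mode = row["hyp_mode"].strip()
            if mode == "auto":
                hyp = _auto_hyp_positions(seq)
            elif mode == "none":
                hyp = ()
            else:
                hyp = tuple(int(p) for p in mode.split(";") if p)
            site = SiteDefinition(
                chain=row["chain"],
                label=row["label"],
                sequence=seq,
                pyro_glu=row["pyro_glu"].strip().lower() == "yes",
                mod_positions=tuple(int(p) for p in row["mod_positions"].split(";")),
                allowed_states=tuple(
                    tuple(group.split("|")) for group in row["allowed_states"].split(";")
                ),
                hyp_positions=hyp,
                synthetic=row["synthetic"].strip().lower() == "yes",
            )
            sites[(site.chain, site.label)] = site
    return sites


def peptide_formula(site: SiteDefinition, states: Sequence[str]) -> MolecularFormula:
    """Neutral formula of the peptide with the given per-position states.

    mass = sum of residue (chain-form) formulas + H2O, minus NH3 when the
    N-terminal Gln is cyclized to pyroglutamate.
    """
    if len(states) != len(site.mod_positions):
        raise ValueError("one state per modifiable position required")
    table = residue_table()
    subs = {pos: _STATE_RESIDUE[state] for pos, state in zip(site.mod_positions, states)}
    for pos in site.hyp_positions:
        subs[pos] = "Hyp"
    total = MolecularFormula()
    for i, aa in enumerate(site.sequence, start=1):
        code = subs.get(i, aa)
        if code not in table:
            raise KeyError(f"unknown residue code {code!r} at position {i} of {site.label}")
        total = total + table[code]
    total = total + WATER
    if site.pyro_glu:
        if site.sequence[0] != "Q":
            raise ValueError(f"{site.label}: pyro-Glu flag requires an N-terminal Gln")
        total = total - AMMONIA
    return total


def peptide_mass(species: PeptideSpecies) -> float:
    """Neutral monoisotopic mass of a peptide species in Da."""
    return species.formula.mass


def enumerate_variants(site: SiteDefinition) -> list[OccupancyClass]:
    """All mass-distinct occupancy classes of a site, ordered by mass.

    Combinations of per-position states whose masses coincide (positional
    isomers such as Lys+Hyl vs Hyl+Lys) collapse into one class, because
    EIC quantification cannot distinguish them. Class labels follow the
    reporting convention: single-site classes carry the state name, joint
    classes the states sorted canonically and joined with " + ".
    """
    by_mass: dict[float, tuple[tuple[str, ...], int]] = {}
    for combo in product(*site.allowed_states):
        f = peptide_formula(site, combo)
        key = round(f.mass, 6)
        if key in by_mass:
            states, n = by_mass[key]
            by_mass[key] = (states, n + 1)
        else:
            by_mass[key] = (combo, 1)
    classes = []
    for mass_key in sorted(by_mass):
        states, n = by_mass[mass_key]
        ordered = tuple(sorted(states, key=_STATE_ORDER.__getitem__))
        label = " + ".join(ordered) if len(ordered) > 1 else ordered[0]
        classes.append(
            OccupancyClass(
                label=label,
                species=PeptideSpecies(site=site, states=states, formula=peptide_formula(site, states)),
                n_isomers=n,
            )
        )
    return classes


def build_eic_queries(
    site: SiteDefinition,
    charges: Iterable[int] = (2,),
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[EICQuery]:
    """One EIC query per (occupancy class, charge).

    Queries whose targets at the same charge fall within twice the
    tolerance of each other are flagged ``ambiguous`` (their windows
    overlap, so their areas cannot be attributed to a single class).
    """
    charges = tuple(charges)
    if any((not isinstance(z, int)) or z < 1 for z in charges):
        raise ValueError("charges must be positive integers")
    queries = [
        EICQuery(
            target_mz=mz(cls.mass, z),
            tolerance=tolerance,
            charge=z,
            class_label=cls.label,
        )
        for cls in enumerate_variants(site)
        for z in charges
    ]
    flagged = list(queries)
    for i, a in enumerate(queries):
        for j, b in enumerate(queries):
            if i < j and a.charge == b.charge and abs(a.target_mz - b.target_mz) < 2 * tolerance:
                flagged[i] = replace(flagged[i], ambiguous=True)
                flagged[j] = replace(flagged[j], ambiguous=True)
    return flagged
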