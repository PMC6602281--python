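"""Cross-link quantification from HPLC radioactivity traces.

Reducible cross-links are measured after NaB(3H)4 reduction: every
reduced bond carries tritium, so integrated counts in a species' elution
window convert to moles via the label's specific activity. Levels are
expressed per mole of collagen (from 4-Hyp isotope dilution). Acid
hydrolysis measures total HLNL, LNL, HHMD and d-HHMD; base hydrolysis
preserves the O-glycosidic bond and resolves GG-, G- and free HLNL.

The bifunctional species (HLNL, LNL and the HLNL glycoforms) carry one
reduced bond; the tetrafunctional HHMD and d-HHMD carry two (the aldimine
and the remaining free aldehyde are both reduced), so their counts are
halved before mole conversion. This label multiplicity is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HplcTrace",
    "QuantCalibration",
    "CrosslinkLevels",
    "DEFAULT_WINDOWS",
    "DEFAULT_LABELS",
    "HYP_PER_COLLAGEN",
    "quantify_peaks",
    "total_aldehyde",
    "hlnl_glyco_fractions",
]

#: 4-Hyp residues per collagen triple helix used to convert a measured
#: 4-Hyp amount into moles of collagen molecules (denominator convention).
HYP_PER_COLLAGEN = 300

#: Tritium-labelled (reduced) bonds per cross-link molecule.
DEFAULT_LABELS: Mapping[str, int] = {
    "HLNL": 1,
    "LNL": 1,
    "HHMD": 2,
    "d-HHMD": 2,
    "GG-HLNL": 1,
    "G-HLNL": 1,
    "free-HLNL": 1,
}

#: Elution windows (fraction index, inclusive) per hydrolysis mode. The
#: chromatographic positions are method-relative; generator and
#: quantifier share this table.
DEFAULT_WINDOWS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "acid": {
        "HLNL": (15, 25),
        "LNL": (28, 38),
        "HHMD": (42, 52),
        "d-HHMD": (56, 66),
    },
    "base": {
        "GG-HLNL": (10, 20),
        "G-HLNL": (24, 34),
        "free-HLNL": (38, 48),
    },
}


@dataclass
class HplcTrace:
    """One cross-link HPLC run: (fraction, detector signal, cpm) records."""

    sample_id: str
    data: pd.DataFrame  # columns: fraction, signal, cpm
    mode: str = "acid"  # "acid" | "base"

    def __post_init__(self) -> None:
        for col in ("fraction", "cpm"):
            if col not in self.data.columns:
                raise ValueError(f"HPLC trace missing column {col!r}")
        if self.mode not in ("acid", "base"):
            raise ValueError(f"hydrolysis mode must be 'acid' or 'base', got {self.mode!r}")
        frac = self.data["fraction"].to_numpy(dtype=float)
        if len(frac) > 1 and not np.all(np.diff(frac) > 0):
            raise ValueError("fraction indices must be strictly increasing")
        if (self.data["cpm"].to_numpy(dtype=float) < 0).any():
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class QuantCalibration:
    """Counting calibration and the collagen denominator.

    specific_activity: counts per minute per mole of reduced bond.
    efficiency: counting efficiency (1.0 = counts already corrected).
    collagen_mol: moles of collagen in the hydrolysate, typically
        (4-Hyp moles) / HYP_PER_COLLAGEN.
    """

    specific_activity: float
    collagen_mol: float
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if min(self.specific_activity, self.collagen_mol, self.efficiency) <= 0:
            raise ValueError("calibration values must all be positive")

    @classmethod
    def from_hyp(cls, specific_activity: float, hyp_mol: float,
                 hyp_per_collagen: int = HYP_PER_COLLAGEN, efficiency: float = 1.0) -> "QuantCalibration":
        return cls(specific_activity, hyp_mol / hyp_per_collagen, efficiency)


@dataclass(frozen=True)
class CrosslinkLevels:
    """Cross-link levels in mol per mol collagen for one sample."""

    sample_id: str
    mode: str
    levels: Mapping[str, float]

    def __getitem__(self, species: str) -> float:
        return self.levels.get(species, 0.0)


def quantify_peaks(
    trace: HplcTrace,
    windows: Mapping[str, tuple[float, float]] | None = None,
    cal: QuantCalibration | None = None,
    labels: Mapping[str, int] = DEFAULT_LABELS,
) -> CrosslinkLevels:
    """Convert windowed counts into mol cross-link per mol collagen.

    species mol = (sum of cpm in window) / (labels * specific activity *
    efficiency); level = species mol / collagen mol. Windows default to
    the shared :data:`DEFAULT_WINDOWS` table for the trace's hydrolysis
    mode and must not overlap.
    """
    if cal is None:
        raise ValueError("a QuantCalibration is required")
    if windows is None:
        windows = DEFAULT_WINDOWS[trace.mode]
    spans = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (_, (lo_a, hi_a)), (name_b, (lo_b, _)) in zip(spans, spans[1:]):
        if lo_b <= hi_a:
            raise ValueError(f"elution window for {name_b!r} overlaps its neighbour")
    frac = trace.data["fraction"].to_numpy(dtype=float)
    cpm = trace.data["cpm"].to_numpy(dtype=float)
    levels: dict[str, float] = {}
    for species, (lo, hi) in windows.items():
        counts = float(cpm[(frac >= lo) & (frac <= hi)].sum())
        n_labels = labels.get(species, 1)
        mol = counts / (n_labels * cal.specific_activity * cal.efficiency)
        levels[species] = mol / cal.collagen_mol
    return CrosslinkLevels(sample_id=trace.sample_id, mode=trace.mode, levels=levels)


def total_aldehyde(levels: CrosslinkLevels | Mapping[str, float]) -> float:
    """Total aldehyde involvement: HLNL + LNL + 2*HHMD + 2*d-HHMD.

    The bifunctional species consume one telopeptidyl aldehyde each; the
    tetrafunctional (d-)HHMD consume two (the ACP).
    """
    get = levels.__getitem__ if isinstance(levels, CrosslinkLevels) else (
        lambda k: levels.get(k, 0.0)
    )
    return get("HLNL") + get("LNL") + 2.0 * get("HHMD") + 2.0 * get("d-HHMD")


def hlnl_glyco_fractions(levels: CrosslinkLevels | Mapping[str, float]) -> dict[str, float]:
    """GG-, G- and free HLNL as percentages of total HLNL (sums to 100)."""
    raw = levels.levels if isinstance(levels, CrosslinkLevels) else levels
    forms = {k: float(raw.get(k, 0.0)) for k in ("GG-HLNL", "G-HLNL", "free-HLNL")}
    total = sum(forms.values())
    if total <= 0:
        raise ValueError("all HLNL glycoform levels are zero")
    return {k: 100.0 * v / total for k, v in forms.items()}
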