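"""EIC-based quantification: site occupancy, glycoforms, collagen typing.

The measurement model is deliberately simple and mirrors routine targeted
MS1 quantification: a chromatogram is a long table of (retention time,
m/z, intensity) records; an EIC sums intensity within an absolute m/z
window (default +/-0.02) around the target at every time point; peak
areas are trapezoidal; relative quantities are ratios of areas.

Occupancy convention: Lys + Hyl + G-Hyl + GG-Hyl = 100% per site, with
Lys^ald areas pooled into the Lys class. Glycoform convention: Hyl +
G-Hyl + GG-Hyl = 100% among hydroxylated forms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peptides import DEFAULT_TOLERANCE, EICQuery, SiteDefinition, build_eic_queries

__all__ = [
    "Chromatogram",
    "EIC",
    "SiteOccupancy",
    "GlycoformProfile",
    "CollagenQuant",
    "extract_eic",
    "integrate_peak",
    "site_occupancy",
    "glycoform_profile",
    "class_areas",
    "occupancy_from_chromatogram",
    "collagen_type_ratio",
    "extractability",
]

_CHROM_COLUMNS = ("rt_s", "mz", "intensity")


@dataclass
class Chromatogram:
    """MS1 data for one sample: records of (rt_s, mz, intensity)."""

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CHROM_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"chromatogram missing columns: {missing}")
        vals = self.data["intensity"].to_numpy(dtype=float)
        if len(vals) and (not np.all(np.isfinite(vals)) or (vals < 0).any()):
            raise ValueError("intensities must be finite and >= 0")
        self.data = self.data.sort_values("rt_s", kind="stable").reset_index(drop=True)

    @classmethod
    def from_csv(cls, path, sample_id: str | None = None) -> "Chromatogram":
        """Read the long-format CSV (sample_id, rt_s, mz, intensity)."""
        df = pd.read_csv(path)
        if sample_id is None:
            ids = df["sample_id"].unique()
            if len(ids) != 1:
                raise ValueError("CSV holds multiple samples; pass sample_id")
            sample_id = str(ids[0])
        else:
            df = df[df["sample_id"] == sample_id]
        return cls(sample_id=str(sample_id), data=df[list(_CHROM_COLUMNS)].copy())


@dataclass
class EIC:
    """Extracted ion chromatogram: summed intensity vs retention time."""

    query: EICQuery
    rt_s: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if len(self.rt_s) < 1 or len(self.rt_s) != len(self.intensity):
            raise ValueError("EIC needs matched, non-empty rt/intensity arrays")


@dataclass(frozen=True)
class SiteOccupancy:
    """Per-sample fractional class abundances at one site, in percent."""

    sample_id: str
    site_label: str
    fractions: Mapping[str, float]  # class label -> percent; sums to 100
    detected: bool = True

    def __post_init__(self) -> None:
        if self.detected:
            total = sum(self.fractions.values())
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"occupancy must sum to 100, got {total!r}")


@dataclass(frozen=True)
class GlycoformProfile:
    """Hyl / G-Hyl / GG-Hyl percentages among hydroxylated forms only."""

    sample_id: str
    site_label: str
    fractions: Mapping[str, float]


@dataclass(frozen=True)
class CollagenQuant:
    """Type I/III amounts from light/heavy marker-peptide area ratios."""

    sample_id: str
    amounts: Mapping[str, float]  # collagen type -> amount (standard units)
    type_i_pct: float
    type_iii_pct: float


def extract_eic(chrom: Chromatogram, query: EICQuery) -> EIC:
    """Sum intensity within |m/z - target| <= tolerance at every time point.

    The EIC is laid out on the chromatogram's full retention-time grid so
    that all classes of one site share a common time base; empty windows
    give all-zero traces.
    """
    if chrom.data.empty:
        raise ValueError("chromatogram is empty")
    df = chrom.data
    rt_grid = np.unique(df["rt_s"].to_numpy(dtype=float))
    mask = (df["mz"] - query.target_mz).abs() <= query.tolerance
    inside = df[mask].groupby("rt_s")["intensity"].sum()
    intensity = np.zeros_like(rt_grid)
    if len(inside):
        idx = np.searchsorted(rt_grid, inside.index.to_numpy(dtype=float))
        intensity[idx] = inside.to_numpy(dtype=float)
    return EIC(query=query, rt_s=rt_grid, intensity=intensity)


def integrate_peak(eic: EIC, window: tuple[float, float] | None = None) -> float:
    """Trapezoidal area of the (largest) peak.

    With an explicit ``window`` (rt interval), integrates over it. In
    auto mode the apex is located and the bounds walk outward to the
    first points below 1% of the apex intensity; an all-zero trace has
    area 0.
    """
    rt, y = eic.rt_s, eic.intensity
    if window is not None:
        lo, hi = window
        sel = (rt >= lo) & (rt <= hi)
        if not sel.any():
            raise ValueError("integration window contains no points")
        return float(np.trapezoid(y[sel], rt[sel]))
    if not y.any():
        return 0.0
    apex = int(np.argmax(y))
    floor = 0.01 * y[apex]
    lo = apex
    while lo > 0 and y[lo - 1] >= floor:
        lo -= 1
    hi = apex
    while hi < len(y) - 1 and y[hi + 1] >= floor:
        hi += 1
    return float(np.trapezoid(y[lo : hi + 1], rt[lo : hi + 1]))


def site_occupancy(
    areas: Mapping[str, float],
    sample_id: str = "",
    site_label: str = "",
) -> SiteOccupancy:
    """Class percentages from per-class areas (Lys^ald pooled into Lys).

    ``areas`` maps occupancy-class labels to EIC peak areas. Percentages
    are 100 * area / total. All-zero areas yield a ``detected=False``
    result rather than a division by zero.
    """
    pooled: dict[str, float] = {}
    for label, area in areas.items():
        if area < 0:
            raise ValueError(f"negative area for class {label!r}")
        target = "Lys" if label == "Lysald" else label
        pooled[target] = pooled.get(target, 0.0) + float(area)
    total = sum(pooled.values())
    if total == 0:
        return SiteOccupancy(sample_id, site_label, {k: float("nan") for k in pooled}, detected=False)
    fractions = {k: 100.0 * v / total for k, v in pooled.items()}
    return SiteOccupancy(sample_id, site_label, fractions)


_GLYCO_CLASSES = ("Hyl", "G-Hyl", "GG-Hyl")


def glycoform_profile(occ: SiteOccupancy) -> GlycoformProfile:
    """Renormalize the hydroxylated classes to Hyl + G-Hyl + GG-Hyl = 100%."""
    if not occ.detected:
        raise ValueError(f"site {occ.site_label!r} not detected")
    hydrox = {k: occ.fractions.get(k, 0.0) for k in _GLYCO_CLASSES}
    total = sum(hydrox.values())
    if total <= 0:
        raise ValueError(f"site {occ.site_label!r} is fully unmodified; no glycoform profile")
    return GlycoformProfile(
        sample_id=occ.sample_id,
        site_label=occ.site_label,
        fractions={k: 100.0 * v / total for k, v in hydrox.items()},
    )


def class_areas(
    chrom: Chromatogram,
    site: SiteDefinition,
    charges: Iterable[int] = (2,),
    tolerance: float = DEFAULT_TOLERANCE,
    window: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Per-class peak areas for one site, summed over the queried charges."""
    out: dict[str, float] = {}
    for q in build_eic_queries(site, charges=charges, tolerance=tolerance):
        area = integrate_peak(extract_eic(chrom, q), window=window)
        out[q.class_label] = out.get(q.class_label, 0.0) + area
    return out


def occupancy_from_chromatogram(
    chrom: Chromatogram,
    site: SiteDefinition,
    charges: Iterable[int] = (2,),
    tolerance: float = DEFAULT_TOLERANCE,
) -> SiteOccupancy:
    """Full EIC pipeline for one (sample, site): extract, integrate, normalize."""
    areas = class_areas(chrom, site, charges=charges, tolerance=tolerance)
    return site_occupancy(areas, sample_id=chrom.sample_id, site_label=site.label)


def collagen_type_ratio(
    markers: pd.DataFrame,
    sample_id: str = "",
) -> CollagenQuant:
    """Type I / III percentages from stable-isotope dilution marker peptides.

    ``markers`` needs columns ``collagen_type`` ("I" | "III"),
    ``light_area``, ``heavy_area`` and ``standard_amount``. Each marker
    estimates an amount light/heavy * standard; the per-type amount is
    the mean over that type's markers. Markers with a missing or zero
    heavy channel are excluded; a type with no usable marker is an error.
    """
    required = {"collagen_type", "light_area", "heavy_area", "standard_amount"}
    missing = required - set(markers.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    usable = markers[markers["heavy_area"].fillna(0) > 0]
    amounts: dict[str, float] = {}
    for ctype, grp in usable.groupby("collagen_type"):
        amounts[str(ctype)] = float(
            (grp["light_area"] / grp["heavy_area"] * grp["standard_amount"]).mean()
        )
    for ctype in ("I", "III"):
        if ctype not in amounts:
            raise ValueError(f"no usable marker for type {ctype} collagen")
    total = amounts["I"] + amounts["III"]
    return CollagenQuant(
        sample_id=sample_id,
        amounts=amounts,
        type_i_pct=100.0 * amounts["I"] / total,
        type_iii_pct=100.0 * amounts["III"] / total,
    )


def extractability(amounts: Mapping[str, float]) -> dict[str, float]:
    """Percent of total collagen in each sequential-extraction fraction.

    ``amounts`` maps fraction names (e.g. acid-soluble, pepsin-soluble,
    residual) to collagen amounts from 4-Hyp isotope dilution; output
    percentages sum to 100.
    """
    if any(v < 0 for v in amounts.values()):
        raise ValueError("fraction amounts must be >= 0")
    total = sum(amounts.values())
    if total <= 0:
        raise ValueError("all fraction amounts are zero")
    return {k: 100.0 * v / total for k, v in amounts.items()}
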