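"""Seed-deterministic synthetic instrument data for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
Gaussian elution peaks at theoretical m/z with class areas proportional
to an occupancy vector, windowed HPLC count peaks whose integrals encode
mol/mol levels, and forward Dimitriadis-Hertz force curves — so each
stage can be tested end to end with known ground truth. Every generator
is a pure function of its arguments and the seed, and returns the ground
truth alongside the fixture (never re-derived from the fixture itself).

Noise model (all optional, off by default): truncated-normal per-class
occupancy draws renormalized to 100%, multiplicative log-normal
intensity noise, uniform m/z jitter bounded at +/-0.005, Poisson counts,
and per-sample modulus draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .chem import mz as _mz
from .peptides import SiteDefinition, enumerate_variants
from .quant import Chromatogram
from .xlink_quant import DEFAULT_LABELS, DEFAULT_WINDOWS, HplcTrace, QuantCalibration
from .afm import ForceCurve, hertz_force

__all__ = [
    "CohortSpec",
    "draw_occupancy",
    "simulate_chromatogram",
    "simulate_marker_chromatogram",
    "marker_table_from_chromatogram",
    "simulate_hplc_trace",
    "simulate_force_curves",
]

_MZ_JITTER = 0.005  # bound on simulated calibration jitter, m/z units


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: genotypes, group sizes, noise switches, seed.

    Defaults are the study conditions: WT/Het/KO groups with n = 3 for
    MS-based assays and AFM and n = 10 for cross-link analysis, set-point
    tables from :mod:`collagen_ptm.defaults`.
    """

    genotypes: tuple[str, ...] = defaults.GENOTYPES
    n_occupancy: int = defaults.N_OCCUPANCY
    n_crosslink: int = defaults.N_CROSSLINK
    n_afm: int = defaults.N_AFM
    noise: bool = True
    intensity_cv: float = 0.05  # log-normal multiplicative noise, sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_occupancy, self.n_crosslink, self.n_afm) < 1:
            raise ValueError("group sizes must be >= 1")


def draw_occupancy(
    means: Mapping[str, float],
    sds: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Truncated-normal draw per class, renormalized to sum to 100.

    Honours the per-class SDs of the set-point tables (a Dirichlet draw
    would not); clipping at zero keeps fractions physical.
    """
    draw = {
        cls: max(0.0, rng.normal(means[cls], sds.get(cls, 0.0)))
        for cls in means
    }
    total = sum(draw.values())
    if total <= 0:
        raise ValueError("degenerate occupancy draw: all classes zero")
    return {cls: 100.0 * v / total for cls, v in draw.items()}


def _gaussian_profile(rt: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    """Discrete peak whose *trapezoidal* integral over rt is exactly ``area``."""
    shape = np.exp(-0.5 * ((rt - center) / sigma) ** 2)
    norm = np.trapezoid(shape, rt)
    return area * shape / norm


def simulate_chromatogram(
    site: SiteDefinition,
    occupancies: Mapping[str, float],
    sample_id: str = "S1",
    charges: Sequence[int] = (2,),
    seed: int | None = None,
    noise: bool = False,
    intensity_cv: float = 0.05,
    base_area: float = 1.0e6,
    rt_center: float = 300.0,
    rt_sigma: float = 8.0,
    rt_step: float = 1.0,
) -> tuple[Chromatogram, dict]:
    """MS1 chromatogram of one marker peptide with set class abundances.

    Each occupancy class elutes as one Gaussian peak at its theoretical
    m/z for every queried charge (co-eluting, resolved in m/z); the
    class's total area across charges is proportional to its occupancy
    percentage. With ``noise`` enabled, intensities get multiplicative
    log-normal noise and m/z values a uniform jitter bounded at
    +/-0.005. Returns the chromatogram and a ground-truth sidecar dict.

    An empty occupancy mapping yields an empty chromatogram.
    """
    rng = np.random.default_rng(seed)
    classes = {c.label: c for c in enumerate_variants(site)}
    unknown = set(occupancies) - set(classes)
    if unknown:
        raise ValueError(f"classes not defined for site {site.label!r}: {sorted(unknown)}")
    rt = np.arange(rt_center - 5 * rt_sigma, rt_center + 5 * rt_sigma + rt_step / 2, rt_step)
    records: list[pd.DataFrame] = []
    for label, pct in occupancies.items():
        if pct < 0:
            raise ValueError(f"negative occupancy for class {label!r}")
        if pct == 0:
            continue
        area_per_charge = base_area * (pct / 100.0) / len(charges)
        for z in charges:
            target = _mz(classes[label].mass, z)
            intensity = _gaussian_profile(rt, rt_center, rt_sigma, area_per_charge)
            if noise:
                intensity = intensity * rng.lognormal(0.0, intensity_cv, size=len(rt))
                mz_col = target + rng.uniform(-_MZ_JITTER, _MZ_JITTER, size=len(rt))
            else:
                mz_col = np.full(len(rt), target)
            records.append(pd.DataFrame({"rt_s": rt, "mz": mz_col, "intensity": intensity}))
    data = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["rt_s", "mz", "intensity"])
    )
    truth = {
        "sample_id": sample_id,
        "site": site.label,
        "chain": site.chain,
        "occupancies": dict(occupancies),
        "charges": list(charges),
        "noise": noise,
        "seed": seed,
    }
    return Chromatogram(sample_id=sample_id, data=data), truth


def simulate_marker_chromatogram(
    type_amounts: Mapping[str, float],
    sample_id: str = "S1",
    markers: Sequence[tuple] = defaults.TYPE_MARKERS,
    standard_amount: float = 1.0,
    seed: int | None = None,
    noise: bool = False,
    intensity_cv: float = 0.05,
    base_area: float = 1.0e6,
    rt_sigma: float = 6.0,
    rt_step: float = 1.0,
) -> tuple[Chromatogram, dict]:
    """Light/heavy marker-peptide peak pairs for collagen typing.

    ``type_amounts`` gives the relative amount of each collagen type
    (e.g. {"I": 85.8, "III": 14.2}); every marker of a type elutes a
    light peak with area proportional to that amount and a co-eluting
    heavy (SI-collagen internal standard) peak with area proportional to
    ``standard_amount``.
    """
    rng = np.random.default_rng(seed)
    records: list[pd.DataFrame] = []
    for marker_id, ctype, weight, light_mz, heavy_mz, rt_center in markers:
        if ctype not in type_amounts:
            continue
        rt = np.arange(rt_center - 5 * rt_sigma, rt_center + 5 * rt_sigma + rt_step / 2, rt_step)
        pairs = (
            (light_mz, base_area * weight * type_amounts[ctype]),
            (heavy_mz, base_area * weight * standard_amount),
        )
        for target, area in pairs:
            intensity = _gaussian_profile(rt, rt_center, rt_sigma, area)
            if noise:
                intensity = intensity * rng.lognormal(0.0, intensity_cv, size=len(rt))
                mz_col = target + rng.uniform(-_MZ_JITTER, _MZ_JITTER, size=len(rt))
            else:
                mz_col = np.full(len(rt), target)
            records.append(pd.DataFrame({"rt_s": rt, "mz": mz_col, "intensity": intensity}))
    data = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["rt_s", "mz", "intensity"])
    )
    truth = {
        "sample_id": sample_id,
        "type_amounts": dict(type_amounts),
        "standard_amount": standard_amount,
        "noise": noise,
        "seed": seed,
    }
    return Chromatogram(sample_id=sample_id, data=data), truth


def marker_table_from_chromatogram(
    chrom: Chromatogram,
    markers: Sequence[tuple] = defaults.TYPE_MARKERS,
    standard_amount: float = 1.0,
    tolerance: float = 0.02,
) -> pd.DataFrame:
    """Extract light/heavy EIC areas for each typing marker.

    Returns the table :func:`collagen_ptm.quant.collagen_type_ratio`
    consumes (marker, collagen_type, light_area, heavy_area,
    standard_amount).
    """
    from .peptides import EICQuery
    from .quant import extract_eic, integrate_peak

    rows = []
    for marker_id, ctype, _w, light_mz, heavy_mz, _rt in markers:
        light = integrate_peak(extract_eic(chrom, EICQuery(light_mz, tolerance)))
        heavy = integrate_peak(extract_eic(chrom, EICQuery(heavy_mz, tolerance)))
        rows.append(
            {
                "marker": marker_id,
                "collagen_type": ctype,
                "light_area": light,
                "heavy_area": heavy,
                "standard_amount": standard_amount,
            }
        )
    return pd.DataFrame(rows)


def simulate_hplc_trace(
    levels: Mapping[str, float],
    cal: QuantCalibration,
    sample_id: str = "S1",
    mode: str = "acid",
    windows: Mapping[str, tuple[float, float]] | None = None,
    labels: Mapping[str, int] = DEFAULT_LABELS,
    seed: int | None = None,
    poisson_noise: bool = False,
    n_fractions: int = 80,
) -> tuple[HplcTrace, dict]:
    """HPLC radioactivity trace with species peaks of known mol/mol levels.

    Counts for a species are placed as a discrete Gaussian centred in its
    elution window and normalized so their *sum* equals
    level * collagen_mol * specific_activity * efficiency * labels —
    exactly what :func:`collagen_ptm.xlink_quant.quantify_peaks` inverts.
    Species at level 0 leave their window empty.
    """
    rng = np.random.default_rng(seed)
    if windows is None:
        windows = DEFAULT_WINDOWS[mode]
    unknown = set(levels) - set(windows)
    if unknown:
        raise ValueError(f"no elution window for species: {sorted(unknown)}")
    fractions = np.arange(1, n_fractions + 1, dtype=float)
    cpm = np.zeros(n_fractions)
    for species, level in levels.items():
        if level < 0:
            raise ValueError(f"negative level for {species!r}")
        if level == 0:
            continue
        lo, hi = windows[species]
        center, sigma = (lo + hi) / 2.0, (hi - lo) / 6.0
        sel = (fractions >= lo) & (fractions <= hi)
        shape = np.exp(-0.5 * ((fractions[sel] - center) / sigma) ** 2)
        total_counts = (
            level
            * cal.collagen_mol
            * cal.specific_activity
            * cal.efficiency
            * labels.get(species, 1)
        )
        cpm[sel] += total_counts * shape / shape.sum()
    if poisson_noise:
        cpm = rng.poisson(cpm).astype(float)
    data = pd.DataFrame({"fraction": fractions, "signal": cpm / max(cpm.max(), 1.0), "cpm": cpm})
    truth = {
        "sample_id": sample_id,
        "mode": mode,
        "levels": dict(levels),
        "poisson_noise": poisson_noise,
        "seed": seed,
    }
    return HplcTrace(sample_id=sample_id, data=data, mode=mode), truth


def simulate_force_curves(
    e_pa: float,
    n_curves: int = 1,
    tip_radius_m: float = defaults.AFM_TIP_RADIUS_M,
    thickness_m: float = defaults.AFM_THICKNESS_M,
    poisson: float = defaults.AFM_POISSON,
    bonded: bool = True,
    max_depth_m: float = 1.0e-6,
    n_points: int = 100,
    seed: int | None = None,
    force_noise_rel: float = 0.0,
) -> list[ForceCurve]:
    """Forward Dimitriadis-Hertz loading curves at a set modulus.

    Optional multiplicative Gaussian force noise (relative SD). Zero
    curves requested gives an empty list.
    """
    rng = np.random.default_rng(seed)
    depth = np.linspace(0.0, max_depth_m, n_points)
    curves = []
    for i in range(n_curves):
        force = np.asarray(
            hertz_force(e_pa, depth, tip_radius_m, thickness_m, poisson, bonded), dtype=float
        )
        if force_noise_rel > 0:
            force = force * (1.0 + force_noise_rel * rng.standard_normal(n_points))
        curves.append(
            ForceCurve(
                depth_m=depth.copy(),
                force_n=force,
                tip_radius_m=tip_radius_m,
                thickness_m=thickness_m,
                poisson=poisson,
                bonded=bonded,
                curve_id=f"curve{i + 1}",
            )
        )
    return curves
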