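"""Finite-thickness-corrected Hertz fitting of AFM nanoindentation curves.

A microspherical tip (radius R) indents a thin tissue section (thickness
h) bonded to a glass slide. The plain Hertz sphere model

    F = (4/3) * E/(1 - nu^2) * sqrt(R) * delta^(3/2)

underestimates stiffness once the contact length sqrt(R*delta) becomes
comparable to h; the Dimitriadis correction multiplies the Hertz force by
a polynomial in chi = sqrt(R*delta)/h. For a bonded layer:

    C(chi) = 1 + 1.133 chi + 1.283 chi^2 + 0.769 chi^3 + 0.0975 chi^4

with C(0) = 1 recovering plain Hertz as h -> infinity. The free-slip
coefficient set is selectable via ``bonded=False``.

The indentation modulus E_ind is the single free parameter; the model is
linear in E, so the least-squares fit is well conditioned. Curves are
assumed pre-zeroed (contact point at delta = 0); a constant force offset
can be co-fitted behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BONDED_COEFFS",
    "FREE_COEFFS",
    "ForceCurve",
    "IndentationResult",
    "hertz_force",
    "fit_modulus",
]

#: Dimitriadis polynomial coefficients (chi^1..chi^4), bonded layer.
BONDED_COEFFS = (1.133, 1.283, 0.769, 0.0975)
#: Free-slip (non-bonded) coefficient set.
FREE_COEFFS = (0.884, 0.781, 0.386, 0.0048)


@dataclass
class ForceCurve:
    """Loading portion of one force-indentation curve (SI units)."""

    depth_m: np.ndarray
    force_n: np.ndarray
    tip_radius_m: float
    thickness_m: float
    poisson: float = 0.45
    bonded: bool = True
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if self.depth_m.shape != self.force_n.shape:
            raise ValueError("depth and force arrays must match")
        if (self.depth_m < 0).any() or (np.diff(self.depth_m) < 0).any():
            raise ValueError("indentation depth must be >= 0 and non-decreasing")
        if not np.all(np.isfinite(self.force_n)):
            raise ValueError("forces must be finite")
        if self.tip_radius_m <= 0 or self.thickness_m <= 0:
            raise ValueError("tip radius and thickness must be positive")
        if not 0 <= self.poisson < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")


@dataclass(frozen=True)
class IndentationResult:
    """Fitted effective indentation modulus and fit diagnostics."""

    e_ind_pa: float
    residual: float  # RMS force residual, N
    n_points: int
    converged: bool

    @property
    def e_ind_kpa(self) -> float:
        return self.e_ind_pa / 1e3


def _correction(chi: np.ndarray, bonded: bool) -> np.ndarray:
    c1, c2, c3, c4 = BONDED_COEFFS if bonded else FREE_COEFFS
    return 1.0 + c1 * chi + c2 * chi**2 + c3 * chi**3 + c4 * chi**4


def hertz_force(
    e_pa: float,
    depth_m: np.ndarray | float,
    tip_radius_m: float,
    thickness_m: float,
    poisson: float = 0.45,
    bonded: bool = True,
) -> np.ndarray | float:
    """Forward model: force (N) at indentation depth(s) for modulus E (Pa)."""
    delta = np.asarray(depth_m, dtype=float)
    if (delta < 0).any():
        raise ValueError("indentation depth must be >= 0")
    if thickness_m <= 0 or tip_radius_m <= 0:
        raise ValueError("tip radius and thickness must be positive")
    chi = np.sqrt(tip_radius_m * delta) / thickness_m
    force = (
        (4.0 / 3.0)
        * (e_pa / (1.0 - poisson**2))
        * np.sqrt(tip_radius_m)
        * delta**1.5
        * _correction(chi, bonded)
    )
    return force if force.shape else float(force)


def fit_modulus(
    curve: ForceCurve,
    max_depth_fraction: float = 0.10,
    fit_offset: bool = False,
) -> IndentationResult:
    """Least-squares fit of E_ind to the corrected Hertz model.

    Only points with depth <= ``max_depth_fraction`` * thickness enter
    the fit (the correction's validity range). The initial guess inverts
    plain Hertz at the deepest retained point. Non-convergence is
    reported via ``converged=False`` rather than a silent fallback.
    """
    keep = curve.depth_m <= max_depth_fraction * curve.thickness_m
    delta = curve.depth_m[keep]
    force = curve.force_n[keep]
    positive = delta > 0
    if positive.sum() < 10:
        raise ValueError("need at least 10 loading points below the depth cut")

    def model(d, e_pa, *offset):
        f = hertz_force(e_pa, d, curve.tip_radius_m, curve.thickness_m, curve.poisson, curve.bonded)
        return f + (offset[0] if offset else 0.0)

    d_max = delta[positive][-1]
    f_max = max(force[positive][-1], 1e-30)
    e0 = f_max * (1.0 - curve.poisson**2) * 3.0 / (4.0 * np.sqrt(curve.tip_radius_m) * d_max**1.5)
    p0 = [e0, 0.0] if fit_offset else [e0]
    try:
        popt, _ = curve_fit(model, delta, force, p0=p0, maxfev=10000)
    except RuntimeError:
        return IndentationResult(float("nan"), float("nan"), int(len(delta)), False)
    resid = model(delta, *popt) - force
    rms = float(np.sqrt(np.mean(resid**2)))
    e_fit = float(popt[0])
    return IndentationResult(e_fit, rms, int(len(delta)), e_fit > 0)
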