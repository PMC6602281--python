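"""Group summaries and pairwise genotype comparisons.

Per-sample metrics are aggregated per genotype (mean with SD or SE,
matching the reporting convention of each table) and compared pairwise —
WT vs KO and Het vs KO by default — with Welch's two-sample t-test.
Significance tiers follow the usual star thresholds (0.05, 0.01, 0.001,
0.0001); no multiplicity correction is applied across the two
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _st

__all__ = ["GroupStats", "GroupSummary", "group_summary", "significance_tier", "TIER_THRESHOLDS"]

TIER_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class GroupStats:
    mean: float
    dispersion: float  # SD or SE, per `dispersion` mode
    n: int


@dataclass(frozen=True)
class GroupSummary:
    metric: str
    groups: Mapping[str, GroupStats]
    dispersion: str  # "sd" | "se"
    p_values: Mapping[tuple[str, str], float]
    tiers: Mapping[tuple[str, str], str]
    warnings: tuple[str, ...] = ()


def significance_tier(p: float, thresholds: Sequence[float] = TIER_THRESHOLDS) -> str:
    """Star tier for a p-value: 'ns', '*', '**', '***' or '****'."""
    if np.isnan(p):
        return "na"
    stars = sum(p < t for t in thresholds)
    return "*" * stars if stars else "ns"


def group_summary(
    values: Mapping[str, Sequence[float]],
    metric: str = "",
    dispersion: str = "sd",
    comparisons: Sequence[tuple[str, str]] = (("WT", "KO"), ("Het", "KO")),
) -> GroupSummary:
    """Mean, SD/SE and Welch-test comparisons for per-genotype samples.

    Identical groups give p = 1 ('ns'); a comparison involving a group
    with n < 2 is skipped with a warning rather than an error. Two
    groups with zero within-group variance and different means land in
    the smallest tier.
    """
    if dispersion not in ("sd", "se"):
        raise ValueError("dispersion must be 'sd' or 'se'")
    groups: dict[str, GroupStats] = {}
    for name, vals in values.items():
        arr = np.asarray(list(vals), dtype=float)
        n = len(arr)
        sd = float(arr.std(ddof=1)) if n > 1 else float("nan")
        disp = sd / np.sqrt(n) if (dispersion == "se" and n > 1) else sd
        groups[name] = GroupStats(mean=float(arr.mean()) if n else float("nan"), dispersion=disp, n=n)
    p_values: dict[tuple[str, str], float] = {}
    tiers: dict[tuple[str, str], str] = {}
    warn_msgs: list[str] = []
    for a, b in comparisons:
        if a not in values or b not in values:
            continue
        xa = np.asarray(list(values[a]), dtype=float)
        xb = np.asarray(list(values[b]), dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            warn_msgs.append(f"comparison {a} vs {b} skipped: group with n < 2")
            continue
        if np.array_equal(xa, xb):
            p = 1.0
        elif xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            # degenerate limit: distinct constants are maximally separated
            p = 0.0 if xa.mean() != xb.mean() else 1.0
        else:
            with warnings.catch_warnings():
                # near-identical draws trip scipy's precision-loss warning;
                # exact ties and zero-variance pairs are handled above
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(_st.ttest_ind(xa, xb, equal_var=False).pvalue)
        p_values[(a, b)] = p
        tiers[(a, b)] = significance_tier(p)
    return GroupSummary(
        metric=metric,
        groups=groups,
        dispersion=dispersion,
        p_values=p_values,
        tiers=tiers,
        warnings=tuple(warn_msgs),
    )
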