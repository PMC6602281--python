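"""HPLC cross-link quantification: counts -> mol per mol collagen."""

import numpy as np
import pandas as pd
import pytest

from collagen_ptm import defaults
from collagen_ptm.simulate import simulate_hplc_trace
from collagen_ptm.xlink_quant import (
    DEFAULT_WINDOWS,
    CrosslinkLevels,
    HplcTrace,
    QuantCalibration,
    hlnl_glyco_fractions,
    quantify_peaks,
    total_aldehyde,
)

WT_ACID = {sp: t["WT"][0] for sp, t in defaults.CROSSLINKS_ACID.items()}
KO_ACID = {sp: t["KO"][0] for sp, t in defaults.CROSSLINKS_ACID.items()}
WT_BASE = {sp: t["WT"][0] for sp, t in defaults.CROSSLINKS_BASE.items()}


def test_round_trip_at_wt_levels(calibration):
    trace, _ = simulate_hplc_trace(WT_ACID, calibration, mode="acid")
    got = quantify_peaks(trace, cal=calibration)
    for sp, level in WT_ACID.items():
        assert got[sp] == pytest.approx(level, abs=1e-9)
    assert got["HLNL"] == pytest.approx(0.53)


def test_all_zero_counts_give_zero_levels(calibration):
    data = pd.DataFrame({"fraction": np.arange(1.0, 81.0), "signal": 0.0, "cpm": 0.0})
    got = quantify_peaks(HplcTrace("S1", data, "acid"), cal=calibration)
    assert all(v == 0.0 for v in got.levels.values())


def test_ratio_invariance_counts_and_collagen(calibration):
    trace, _ = simulate_hplc_trace(WT_ACID, calibration, mode="acid")
    doubled = HplcTrace(
        "S1", trace.data.assign(cpm=trace.data["cpm"] * 2), "acid"
    )
    cal2 = QuantCalibration(
        calibration.specific_activity, calibration.collagen_mol * 2, calibration.efficiency
    )
    a = quantify_peaks(trace, cal=calibration)
    b = quantify_peaks(doubled, cal=cal2)
    for sp in WT_ACID:
        assert b[sp] == pytest.approx(a[sp], rel=1e-12)


def test_hhmd_counts_are_halved_for_two_labels(calibration):
    """(d-)HHMD carries two reduced bonds: same counts -> half the moles."""
    trace, _ = simulate_hplc_trace({"HHMD": 0.5}, calibration, mode="acid")
    naive = quantify_peaks(trace, cal=calibration, labels={"HHMD": 1})
    assert naive["HHMD"] == pytest.approx(1.0)
    correct = quantify_peaks(trace, cal=calibration)
    assert correct["HHMD"] == pytest.approx(0.5)


def test_overlapping_windows_rejected(calibration):
    trace, _ = simulate_hplc_trace(WT_ACID, calibration, mode="acid")
    with pytest.raises(ValueError):
        quantify_peaks(trace, windows={"A": (10, 30), "B": (25, 40)}, cal=calibration)


@pytest.mark.parametrize(
    "levels, expected",
    [
        ({"HLNL": 0.53, "LNL": 0.0, "HHMD": 0.72, "d-HHMD": 0.0}, 1.97),
        (KO_ACID, 0.89),
        ({}, 0.0),
    ],
)
def test_total_aldehyde_formula(levels, expected):
    assert total_aldehyde(levels) == pytest.approx(expected, abs=1e-9)


def test_total_aldehyde_close_to_printed_group_values():
    # printed group totals (1.99 WT, 0.88 KO) reflect per-sample averaging
    # before rounding; evaluating the formula on printed means agrees to 0.02
    assert abs(total_aldehyde(WT_ACID) - 1.99) <= 0.02 + 1e-12
    assert abs(total_aldehyde(KO_ACID) - 0.88) <= 0.02 + 1e-12


def test_total_aldehyde_linearity(calibration):
    rng = np.random.default_rng(7)
    cohort = [
        {sp: max(0.0, rng.normal(*defaults.CROSSLINKS_ACID[sp]["WT"])) for sp in WT_ACID}
        for _ in range(6)
    ]
    mean_of_totals = np.mean([total_aldehyde(c) for c in cohort])
    total_of_means = total_aldehyde(
        {sp: np.mean([c[sp] for c in cohort]) for sp in WT_ACID}
    )
    assert mean_of_totals == pytest.approx(total_of_means, rel=1e-12)


def test_hlnl_glyco_fractions():
    pct = hlnl_glyco_fractions({"GG-HLNL": 0.18, "G-HLNL": 0.10, "free-HLNL": 0.25})
    assert pct["GG-HLNL"] == pytest.approx(34.0, abs=0.05)
    assert pct["G-HLNL"] == pytest.approx(18.9, abs=0.05)
    assert pct["free-HLNL"] == pytest.approx(47.2, abs=0.05)
    assert sum(pct.values()) == pytest.approx(100.0)
    only = hlnl_glyco_fractions({"GG-HLNL": 0.3})
    assert only == pytest.approx({"GG-HLNL": 100.0, "G-HLNL": 0.0, "free-HLNL": 0.0})
    with pytest.raises(ValueError):
        hlnl_glyco_fractions({})


def test_acid_base_conservation(calibration):
    """Base-mode GG + G + free HLNL equals acid-mode total HLNL by construction."""
    trace_b, _ = simulate_hplc_trace(WT_BASE, calibration, mode="base")
    base_levels = quantify_peaks(trace_b, cal=calibration)
    assert sum(base_levels.levels.values()) == pytest.approx(WT_ACID["HLNL"], abs=1e-9)


def test_cohort_group_means_recover_setpoints(calibration):
    """n=10 noisy cohort: group means within 2 SE of the set levels."""
    rng = np.random.default_rng(11)
    n = 10
    recovered = {sp: [] for sp in WT_ACID}
    for k in range(n):
        levels = {
            sp: max(0.0, rng.normal(*defaults.CROSSLINKS_ACID[sp]["WT"])) for sp in WT_ACID
        }
        trace, _ = simulate_hplc_trace(
            levels, calibration, mode="acid", seed=k, poisson_noise=False
        )
        got = quantify_peaks(trace, cal=calibration)
        for sp in WT_ACID:
            recovered[sp].append(got[sp])
    for sp, (mean, sd) in ((s, defaults.CROSSLINKS_ACID[s]["WT"]) for s in WT_ACID):
        vals = np.array(recovered[sp])
        se = max(sd / np.sqrt(n), 1e-12)
        assert abs(vals.mean() - mean) <= 2 * se + 1e-9, sp
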