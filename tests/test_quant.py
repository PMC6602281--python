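"""EIC extraction, peak integration, occupancy and typing arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from collagen_ptm.peptides import EICQuery
from collagen_ptm.quant import (
    EIC,
    Chromatogram,
    collagen_type_ratio,
    extract_eic,
    extractability,
    glycoform_profile,
    integrate_peak,
    site_occupancy,
)


def _chrom(records):
    return Chromatogram("S1", pd.DataFrame(records, columns=["rt_s", "mz", "intensity"]))


def test_extract_eic_recovers_on_target_peak():
    chrom = _chrom([(t, 500.0, 10.0 * t) for t in range(5)])
    eic = extract_eic(chrom, EICQuery(500.0, 0.02))
    assert np.allclose(eic.intensity, [0, 10, 20, 30, 40])


def test_extract_eic_outside_window_is_zero():
    chrom = _chrom([(t, 500.03, 100.0) for t in range(5)])
    eic = extract_eic(chrom, EICQuery(500.0, 0.02))
    assert not eic.intensity.any()


def test_extract_eic_separates_two_analytes():
    rows = [(t, 500.0, 10.0) for t in range(5)] + [(t, 505.0, 20.0) for t in range(5)]
    chrom = _chrom(rows)
    a = extract_eic(chrom, EICQuery(500.0, 0.02))
    b = extract_eic(chrom, EICQuery(505.0, 0.02))
    assert np.allclose(a.intensity, 10.0)
    assert np.allclose(b.intensity, 20.0)


def test_integrate_rectangular_peak():
    rt = np.arange(0.0, 11.0)
    y = np.where((rt >= 2) & (rt <= 8), 5.0, 0.0)
    eic = EIC(EICQuery(500.0), rt, y)
    # trapezoid over the auto-detected peak: h*w with triangular shoulders
    assert integrate_peak(eic) == pytest.approx(5.0 * 6.0, rel=0.2)
    assert integrate_peak(eic, window=(2, 8)) == pytest.approx(30.0)


def test_integrate_zero_and_linearity():
    rt = np.arange(0.0, 10.0)
    zero = EIC(EICQuery(1.0), rt, np.zeros_like(rt))
    assert integrate_peak(zero) == 0.0
    y = np.exp(-0.5 * ((rt - 5) / 1.5) ** 2)
    one = integrate_peak(EIC(EICQuery(1.0), rt, y))
    two = integrate_peak(EIC(EICQuery(1.0), rt, 2 * y))
    assert two == pytest.approx(2 * one, rel=1e-12)


def test_integrate_empty_window_is_error():
    eic = EIC(EICQuery(1.0), np.arange(5.0), np.ones(5))
    with pytest.raises(ValueError):
        integrate_peak(eic, window=(10, 20))


@pytest.mark.parametrize("scale", [1.0, 0.25, 1e6])
def test_site_occupancy_percentages(scale):
    areas = {"Lys": 0.2 * scale, "Hyl": 1.8 * scale, "G-Hyl": 3.5 * scale, "GG-Hyl": 94.5 * scale}
    occ = site_occupancy(areas)
    assert occ.fractions == pytest.approx(
        {"Lys": 0.2, "Hyl": 1.8, "G-Hyl": 3.5, "GG-Hyl": 94.5}
    )
    assert sum(occ.fractions.values()) == pytest.approx(100.0, abs=1e-9)


def test_site_occupancy_pools_aldehyde_into_lys():
    occ = site_occupancy({"Lys": 30.0, "Lysald": 20.0, "Hyl": 50.0})
    assert occ.fractions == pytest.approx({"Lys": 50.0, "Hyl": 50.0})


def test_site_occupancy_single_class_and_not_detected():
    occ = site_occupancy({"Lys": 0.0, "Hyl": 0.0, "G-Hyl": 0.0, "GG-Hyl": 7.0})
    assert occ.fractions["GG-Hyl"] == 100.0
    nd = site_occupancy({"Lys": 0.0, "Hyl": 0.0})
    assert not nd.detected


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(st.floats(0.01, 1e6), min_size=2, max_size=5),
    st.floats(1e-3, 1e3),
)
def test_occupancy_scale_invariance(areas, k):
    labels = [f"c{i}" for i in range(len(areas))]
    base = site_occupancy(dict(zip(labels, areas)))
    scaled = site_occupancy({l: a * k for l, a in zip(labels, areas)})
    assert sum(base.fractions.values()) == pytest.approx(100.0, abs=1e-6)
    for l in labels:
        assert scaled.fractions[l] == pytest.approx(base.fractions[l], rel=1e-9)


@pytest.mark.parametrize(
    "areas, cls, expected",
    [
        ({"Lys": 0.2, "Hyl": 1.8, "G-Hyl": 3.5, "GG-Hyl": 94.5}, "GG-Hyl", 94.7),
        ({"Lys": 13.9, "Hyl": 84.7, "G-Hyl": 0.9, "GG-Hyl": 0.5}, "Hyl", 98.4),
        ({"Lys": 50.0, "Hyl": 50.0, "G-Hyl": 0.0, "GG-Hyl": 0.0}, "Hyl", 100.0),
    ],
)
def test_glycoform_renormalization(areas, cls, expected):
    prof = glycoform_profile(site_occupancy(areas))
    assert round(prof.fractions[cls], 1) == expected
    assert sum(prof.fractions.values()) == pytest.approx(100.0, abs=1e-9)


def test_glycoform_requires_hydroxylated_forms():
    with pytest.raises(ValueError):
        glycoform_profile(site_occupancy({"Lys": 100.0, "Hyl": 0.0}))


def _marker_table(ratios, standards=None):
    rows = []
    for i, (ctype, ratio) in enumerate(ratios):
        std = 1.0 if standards is None else standards[i]
        rows.append(
            {
                "marker": f"m{i}",
                "collagen_type": ctype,
                "light_area": ratio,
                "heavy_area": 1.0,
                "standard_amount": std,
            }
        )
    return pd.DataFrame(rows)


def test_collagen_type_ratio_unity_is_fifty_fifty():
    q = collagen_type_ratio(_marker_table([("I", 1.0), ("III", 1.0)]))
    assert q.type_i_pct == pytest.approx(50.0)
    assert q.type_iii_pct == pytest.approx(50.0)


def test_collagen_type_ratio_set_composition():
    q = collagen_type_ratio(_marker_table([("I", 85.8), ("I", 85.8), ("III", 14.2)]))
    assert q.type_iii_pct == pytest.approx(14.2)


def test_collagen_type_ratio_excludes_dead_heavy_channel():
    table = _marker_table([("I", 85.8), ("I", 999.0), ("III", 14.2)])
    table.loc[1, "heavy_area"] = 0.0  # outlier marker has no internal standard
    q = collagen_type_ratio(table)
    assert q.type_iii_pct == pytest.approx(14.2)
    table.loc[2, "heavy_area"] = 0.0
    with pytest.raises(ValueError):
        collagen_type_ratio(table)


@pytest.mark.parametrize("scale", [1.0, 3.7])
def test_extractability_normalization(scale):
    pct = extractability({"acid": 14.2 * scale, "pepsin": 70.8 * scale, "residual": 15.0 * scale})
    assert pct == pytest.approx({"acid": 14.2, "pepsin": 70.8, "residual": 15.0})
    assert sum(pct.values()) == pytest.approx(100.0)


def test_extractability_degenerate_cases():
    assert extractability({"a": 0.0, "b": 5.0, "c": 0.0}) == pytest.approx(
        {"a": 0.0, "b": 100.0, "c": 0.0}
    )
    with pytest.raises(ValueError):
        extractability({"a": 0.0, "b": 0.0})
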