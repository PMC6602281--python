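"""Synthetic-data generators: determinism, ground truth, recovery."""

import numpy as np
import pytest

from collagen_ptm import defaults
from collagen_ptm.quant import collagen_type_ratio, occupancy_from_chromatogram
from collagen_ptm.simulate import (
    CohortSpec,
    draw_occupancy,
    marker_table_from_chromatogram,
    simulate_chromatogram,
    simulate_force_curves,
    simulate_hplc_trace,
    simulate_marker_chromatogram,
)

KO_87 = defaults.occupancy_vector("alpha1(I)", "Lys-87", "KO")


def test_noiseless_occupancy_round_trip(site_a1_87):
    chrom, truth = simulate_chromatogram(site_a1_87, KO_87, noise=False)
    occ = occupancy_from_chromatogram(chrom, site_a1_87)
    for cls, pct in KO_87.items():
        assert occ.fractions[cls] == pytest.approx(pct, abs=1e-6)
    assert truth["occupancies"] == KO_87


def test_empty_occupancy_gives_empty_chromatogram(site_a1_87):
    chrom, _ = simulate_chromatogram(site_a1_87, {}, noise=False)
    assert chrom.data.empty


def test_unknown_class_rejected(site_a1_87):
    with pytest.raises(ValueError):
        simulate_chromatogram(site_a1_87, {"Phospho": 100.0})


def test_chromatogram_seed_determinism(site_a1_87):
    a, _ = simulate_chromatogram(site_a1_87, KO_87, seed=42, noise=True)
    b, _ = simulate_chromatogram(site_a1_87, KO_87, seed=42, noise=True)
    c, _ = simulate_chromatogram(site_a1_87, KO_87, seed=43, noise=True)
    assert a.data.equals(b.data)
    assert not a.data.equals(c.data)


def test_noisy_group_means_recover_occupancy(site_a1_87):
    """5% intensity noise, n=5: group mean within 2 SE per class (seeded)."""
    n = 5
    sds = defaults.occupancy_sds("alpha1(I)", "Lys-87", "KO")
    per_class = {cls: [] for cls in KO_87}
    for k in range(n):
        rng = np.random.default_rng(100 + k)
        vec = draw_occupancy(KO_87, sds, rng)
        chrom, _ = simulate_chromatogram(
            site_a1_87, vec, seed=100 + k, noise=True, intensity_cv=0.05
        )
        occ = occupancy_from_chromatogram(chrom, site_a1_87)
        for cls in KO_87:
            per_class[cls].append(occ.fractions[cls])
    for cls, vals in per_class.items():
        arr = np.array(vals)
        se = max(arr.std(ddof=1) / np.sqrt(n), sds[cls] / np.sqrt(n), 0.05)
        assert abs(arr.mean() - KO_87[cls]) <= 2 * se, cls


def test_occupancy_draw_sums_to_100():
    rng = np.random.default_rng(0)
    means = {"a": 70.0, "b": 25.0, "c": 5.0}
    sds = {"a": 5.0, "b": 3.0, "c": 1.0}
    for _ in range(20):
        draw = draw_occupancy(means, sds, rng)
        assert sum(draw.values()) == pytest.approx(100.0, abs=1e-9)
        assert all(v >= 0 for v in draw.values())


def test_hplc_trace_determinism_and_empty_window(calibration):
    levels = {"HLNL": 0.5, "LNL": 0.0, "HHMD": 0.7, "d-HHMD": 0.0}
    a, _ = simulate_hplc_trace(levels, calibration, seed=5, poisson_noise=True)
    b, _ = simulate_hplc_trace(levels, calibration, seed=5, poisson_noise=True)
    assert a.data.equals(b.data)
    frac = a.data["fraction"].to_numpy()
    from collagen_ptm.xlink_quant import DEFAULT_WINDOWS

    lo, hi = DEFAULT_WINDOWS["acid"]["LNL"]
    assert a.data["cpm"].to_numpy()[(frac >= lo) & (frac <= hi)].sum() == 0.0


def test_force_curve_generator_contracts():
    assert simulate_force_curves(10e3, n_curves=0) == []
    a = simulate_force_curves(10e3, n_curves=2, seed=1, force_noise_rel=0.05)
    b = simulate_force_curves(10e3, n_curves=2, seed=1, force_noise_rel=0.05)
    assert all(np.array_equal(x.force_n, y.force_n) for x, y in zip(a, b))


def test_marker_chromatogram_round_trip():
    chrom, truth = simulate_marker_chromatogram({"I": 85.8, "III": 14.2}, noise=False)
    table = marker_table_from_chromatogram(chrom)
    q = collagen_type_ratio(table)
    assert q.type_iii_pct == pytest.approx(14.2, abs=1e-6)
    assert truth["type_amounts"] == {"I": 85.8, "III": 14.2}


def test_cohort_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(n_occupancy=0)
    spec = CohortSpec()
    assert spec.genotypes == ("WT", "Het", "KO")
    assert (spec.n_occupancy, spec.n_crosslink, spec.n_afm) == (3, 10, 3)


def test_default_occupancy_vectors_sum_to_100():
    for (chain, label) in defaults.OCCUPANCY:
        for genotype in defaults.GENOTYPES:
            vec = defaults.occupancy_vector(chain, label, genotype)
            assert sum(vec.values()) == pytest.approx(100.0, abs=1e-9)
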