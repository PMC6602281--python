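"""Write example synthetic fixtures with their ground-truth sidecars.

One of each input the pipeline consumes, generated at documented
set-points with a fixed seed: an MS1 chromatogram of the alpha1(I)
Lys-87 marker peptide at the KO occupancy vector, acid- and
base-hydrolysate HPLC traces at WT cross-link levels, a light/heavy
typing chromatogram at the WT type I/III composition, and one
Dimitriadis-Hertz force curve at the WT epidermis modulus.

Files land in results/example_data/ (CSV + ground-truth JSON).
"""

import json
from pathlib import Path

import pandas as pd

from collagen_ptm import defaults
from collagen_ptm.peptides import load_sites
from collagen_ptm.simulate import (
    simulate_chromatogram,
    simulate_force_curves,
    simulate_hplc_trace,
    simulate_marker_chromatogram,
)
from collagen_ptm.xlink_quant import QuantCalibration

SEED = 20240601
OUT = Path(__file__).resolve().parents[1] / "results" / "example_data"
OUT.mkdir(parents=True, exist_ok=True)

truths = {}

site = load_sites()[("alpha1(I)", "Lys-87")]
vec = defaults.occupancy_vector("alpha1(I)", "Lys-87", "KO")
chrom, truth = simulate_chromatogram(site, vec, sample_id="KO1", seed=SEED, noise=True)
chrom.data.assign(sample_id="KO1").to_csv(OUT / "chromatogram_a1_87_KO1.csv", index=False)
truths["chromatogram_a1_87_KO1"] = truth

cal = QuantCalibration(specific_activity=1.0e9, collagen_mol=1.0e-6)
for mode, table in (("acid", defaults.CROSSLINKS_ACID), ("base", defaults.CROSSLINKS_BASE)):
    levels = {sp: t["WT"][0] for sp, t in table.items()}
    trace, truth = simulate_hplc_trace(
        levels, cal, sample_id="WT1", mode=mode, seed=SEED, poisson_noise=True
    )
    trace.data.assign(sample_id="WT1", mode=mode).to_csv(
        OUT / f"hplc_{mode}_WT1.csv", index=False
    )
    truths[f"hplc_{mode}_WT1"] = truth

t3 = defaults.TYPE_III_PCT["WT"][0]
mchrom, truth = simulate_marker_chromatogram(
    {"I": 100.0 - t3, "III": t3}, sample_id="WT1", seed=SEED, noise=True
)
mchrom.data.assign(sample_id="WT1").to_csv(OUT / "typing_markers_WT1.csv", index=False)
truths["typing_markers_WT1"] = truth

e_kpa = defaults.MODULUS_KPA["epidermis"]["WT"][0]
curve = simulate_force_curves(e_kpa * 1e3, n_curves=1, seed=SEED, force_noise_rel=0.05)[0]
pd.DataFrame(
    {
        "curve_id": curve.curve_id,
        "region": "epidermis",
        "depth_m": curve.depth_m,
        "force_N": curve.force_n,
    }
).to_csv(OUT / "force_curve_epidermis_WT1.csv", index=False)
truths["force_curve_epidermis_WT1"] = {
    "e_kpa": e_kpa,
    "tip_radius_m": curve.tip_radius_m,
    "thickness_m": curve.thickness_m,
    "poisson": curve.poisson,
    "bonded": curve.bonded,
    "seed": SEED,
}

(OUT / "ground_truth.json").write_text(json.dumps(truths, indent=2))
print(f"wrote {len(list(OUT.glob('*.csv')))} fixtures + ground_truth.json to {OUT}")
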