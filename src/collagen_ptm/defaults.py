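"""Default study conditions for the synthetic cohort generators.

Per-genotype set-points: site occupancy mean vectors with SDs, cross-link
levels (mol/mol collagen) with SDs for acid- and base-hydrolysis runs,
regional indentation moduli (kPa, with SE), type III collagen content and
sequential-extraction fractions. Group sizes follow the study design:
n = 3 per genotype for MS occupancy, typing, extraction and AFM samples,
n = 10 for cross-link analysis.

Printed occupancy vectors can sum to 100 +/- 0.1 because of per-class
rounding; :func:`occupancy_vector` renormalizes them to exactly 100 so
the generator honours the sum invariant.
"""

from __future__ import annotations

GENOTYPES = ("WT", "Het", "KO")

N_OCCUPANCY = 3
N_CROSSLINK = 10
N_AFM = 3

#: {(chain, site label): {class: {genotype: (mean %, SD)}}}
OCCUPANCY: dict[tuple[str, str], dict[str, dict[str, tuple[float, float]]]] = {
    ("alpha1(I)", "Lys-87"): {
        "Lys": {"WT": (0.2, 0.0), "Het": (0.2, 0.0), "KO": (80.8, 2.4)},
        "Hyl": {"WT": (1.8, 0.3), "Het": (1.7, 0.1), "KO": (3.7, 0.4)},
        "G-Hyl": {"WT": (3.5, 0.3), "Het": (3.6, 0.2), "KO": (0.8, 0.0)},
        "GG-Hyl": {"WT": (94.5, 0.5), "Het": (94.6, 0.3), "KO": (14.7, 2.0)},
    },
    ("alpha1(I)", "Lys-99"): {
        "Lys": {"WT": (82.5, 0.3), "Het": (83.3, 1.7), "KO": (90.7, 1.6)},
        "Hyl": {"WT": (13.2, 0.3), "Het": (12.6, 0.9), "KO": (3.8, 0.5)},
        "G-Hyl": {"WT": (3.6, 0.4), "Het": (3.4, 0.7), "KO": (2.8, 0.4)},
        "GG-Hyl": {"WT": (0.8, 0.2), "Het": (0.7, 0.1), "KO": (2.8, 0.8)},
    },
    ("alpha1(I)", "Lys-174"): {
        "Lys": {"WT": (65.2, 1.4), "Het": (66.7, 0.8), "KO": (73.9, 3.6)},
        "Hyl": {"WT": (32.7, 0.9), "Het": (31.6, 0.7), "KO": (18.6, 1.7)},
        "G-Hyl": {"WT": (1.5, 0.4), "Het": (1.3, 0.1), "KO": (2.4, 0.3)},
        "GG-Hyl": {"WT": (0.6, 0.2), "Het": (0.5, 0.1), "KO": (5.1, 1.6)},
    },
    ("alpha1(I)", "Lys-219"): {
        "Lys": {"WT": (88.6, 0.3), "Het": (89.0, 0.4), "KO": (89.5, 1.3)},
        "Hyl": {"WT": (11.4, 0.3), "Het": (11.0, 0.4), "KO": (10.5, 1.3)},
    },
    ("alpha1(I)", "Lys-564"): {
        "Lys": {"WT": (76.8, 0.9), "Het": (76.4, 1.2), "KO": (48.8, 5.7)},
        "Hyl": {"WT": (19.2, 0.3), "Het": (19.5, 1.1), "KO": (21.5, 0.4)},
        "G-Hyl": {"WT": (2.7, 0.4), "Het": (2.8, 0.1), "KO": (9.8, 0.7)},
        "GG-Hyl": {"WT": (1.3, 0.3), "Het": (1.4, 0.0), "KO": (19.9, 5.0)},
    },
    ("alpha1(I)", "Lys-603"): {
        "Lys": {"WT": (13.9, 0.2), "Het": (15.1, 0.8), "KO": (15.7, 0.2)},
        "Hyl": {"WT": (84.7, 0.2), "Het": (83.4, 0.9), "KO": (81.9, 0.4)},
        "G-Hyl": {"WT": (0.9, 0.0), "Het": (0.9, 0.1), "KO": (0.9, 0.0)},
        "GG-Hyl": {"WT": (0.5, 0.0), "Het": (0.6, 0.0), "KO": (1.5, 0.4)},
    },
    ("alpha2(I)", "Lys-87"): {
        "Lys": {"WT": (2.8, 0.4), "Het": (4.7, 1.0), "KO": (70.7, 4.2)},
        "Hyl": {"WT": (97.2, 0.4), "Het": (95.3, 1.0), "KO": (29.3, 4.2)},
    },
    ("alpha2(I)", "Lys-174"): {
        "Lys": {"WT": (38.9, 3.4), "Het": (37.4, 3.3), "KO": (91.8, 1.4)},
        "Hyl": {"WT": (7.1, 0.7), "Het": (6.1, 1.1), "KO": (0.5, 0.0)},
        "G-Hyl": {"WT": (45.2, 3.3), "Het": (48.3, 3.4), "KO": (4.7, 0.6)},
        "GG-Hyl": {"WT": (8.8, 0.8), "Het": (8.3, 0.9), "KO": (3.0, 0.9)},
    },
    ("alpha2(I)", "Lys-219"): {
        "Lys": {"WT": (63.8, 1.2), "Het": (65.5, 1.0), "KO": (62.2, 6.2)},
        "Hyl": {"WT": (32.4, 0.7), "Het": (30.0, 0.8), "KO": (24.0, 1.6)},
        "G-Hyl": {"WT": (1.7, 0.2), "Het": (2.1, 0.3), "KO": (2.0, 0.3)},
        "GG-Hyl": {"WT": (2.2, 0.3), "Het": (2.5, 0.2), "KO": (11.7, 4.3)},
    },
    ("alpha1(I)", "Lys-918/930"): {
        "Lys + Lys": {"WT": (0.0, 0.0), "Het": (0.0, 0.0), "KO": (66.4, 2.3)},
        "Lys + Hyl": {"WT": (4.1, 0.2), "Het": (4.1, 0.2), "KO": (26.6, 1.4)},
        "Hyl + Hyl": {"WT": (95.9, 0.2), "Het": (95.9, 0.2), "KO": (7.0, 1.0)},
    },
    ("alpha2(I)", "Lys-933"): {
        "Lys": {"WT": (0.0, 0.0), "Het": (0.0, 0.0), "KO": (69.6, 5.3)},
        "Hyl": {"WT": (90.6, 2.2), "Het": (93.0, 2.3), "KO": (28.1, 4.8)},
        "G-Hyl": {"WT": (9.4, 2.2), "Het": (7.0, 2.3), "KO": (2.3, 0.5)},
        "GG-Hyl": {"WT": (0.0, 0.0), "Het": (0.0, 0.0), "KO": (0.0, 0.0)},
    },
    ("alpha1(I)", "Lys-9^N"): {
        "Lys": {"WT": (100.0, 0.0), "Het": (100.0, 0.0), "KO": (100.0, 0.0)},
        "Hyl": {"WT": (0.0, 0.0), "Het": (0.0, 0.0), "KO": (0.0, 0.0)},
    },
    ("alpha1(I)", "Lys-16^C"): {
        "Lys": {"WT": (100.0, 0.0), "Het": (100.0, 0.0), "KO": (100.0, 0.0)},
        "Hyl": {"WT": (0.0, 0.0), "Het": (0.0, 0.0), "KO": (0.0, 0.0)},
    },
    ("alpha2(I)", "Lys-5^N"): {
        "Lys": {"WT": (100.0, 0.0), "Het": (100.0, 0.0), "KO": (100.0, 0.0)},
        "Hyl": {"WT": (0.0, 0.0), "Het": (0.0, 0.0), "KO": (0.0, 0.0)},
    },
}

#: Acid-hydrolysis cross-link levels, mol/mol collagen: {species: {genotype: (mean, SD)}}
CROSSLINKS_ACID: dict[str, dict[str, tuple[float, float]]] = {
    "HLNL": {"WT": (0.53, 0.10), "Het": (0.47, 0.07), "KO": (0.08, 0.01)},
    "LNL": {"WT": (0.0, 0.0), "Het": (0.0, 0.0), "KO": (0.09, 0.02)},
    "HHMD": {"WT": (0.72, 0.15), "Het": (0.75, 0.16), "KO": (0.08, 0.03)},
    "d-HHMD": {"WT": (0.0, 0.0), "Het": (0.0, 0.0), "KO": (0.28, 0.07)},
}

#: Base-hydrolysis HLNL glycoforms, mol/mol collagen.
CROSSLINKS_BASE: dict[str, dict[str, tuple[float, float]]] = {
    "GG-HLNL": {"WT": (0.18, 0.016), "Het": (0.14, 0.016), "KO": (0.04, 0.005)},
    "G-HLNL": {"WT": (0.10, 0.024), "Het": (0.10, 0.020), "KO": (0.01, 0.003)},
    "free-HLNL": {"WT": (0.25, 0.069), "Het": (0.23, 0.065), "KO": (0.03, 0.006)},
}

#: Regional indentation moduli in kPa: {region: {genotype: (mean, SE)}}
MODULUS_KPA: dict[str, dict[str, tuple[float, float]]] = {
    "epidermis": {"WT": (12.04, 1.16), "KO": (4.70, 0.36)},
    "upper": {"WT": (9.60, 0.99), "KO": (4.73, 0.47)},
    "middle": {"WT": (6.89, 0.46), "KO": (4.11, 0.30)},
    "lower": {"WT": (6.46, 0.51), "KO": (5.50, 0.58)},
}

#: AFM geometry: microspherical tip on 40 um cryo-sections, nu = 0.45.
AFM_TIP_RADIUS_M = 5e-6
AFM_THICKNESS_M = 40e-6
AFM_POISSON = 0.45

#: Type III collagen content (% of type I + III): {genotype: (mean, SD)}
TYPE_III_PCT: dict[str, tuple[float, float]] = {
    "WT": (14.2, 2.6),
    "Het": (15.0, 1.0),
    "KO": (13.9, 1.0),
}

#: Sequential extraction percentages {genotype: {fraction: %}}.
EXTRACTABILITY: dict[str, dict[str, float]] = {
    "WT": {"acid": 14.2, "pepsin": 78.4, "residual": 7.4},
    "Het": {"acid": 14.3, "pepsin": 78.7, "residual": 7.0},
    "KO": {"acid": 14.9, "pepsin": 70.8, "residual": 14.3},
}

#: Synthetic marker peptides for isotope-dilution collagen typing. Two
#: markers per chain; m/z values are placeholders for an instrument
#: method, chosen collision-free. heavy_mz is the co-eluting SI-collagen
#: channel of the same peptide.
TYPE_MARKERS = (
    # marker_id, collagen_type, chain_weight, mz, heavy_mz, rt_center_s
    ("a1I-m1", "I", 1.0, 612.31, 615.32, 240.0),
    ("a1I-m2", "I", 1.0, 728.86, 731.87, 300.0),
    ("a2I-m1", "I", 1.0, 654.83, 657.84, 360.0),
    ("a3III-m1", "III", 1.0, 688.34, 691.35, 270.0),
    ("a3III-m2", "III", 1.0, 745.37, 748.38, 330.0),
)


def occupancy_vector(chain: str, label: str, genotype: str) -> dict[str, float]:
    """Mean occupancy vector for a site/genotype, renormalized to 100%."""
    table = OCCUPANCY[(chain, label)]
    raw = {cls: table[cls][genotype][0] for cls in table}
    total = sum(raw.values())
    return {cls: 100.0 * v / total for cls, v in raw.items()}


def occupancy_sds(chain: str, label: str, genotype: str) -> dict[str, float]:
    table = OCCUPANCY[(chain, label)]
    return {cls: table[cls][genotype][1] for cls in table}
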