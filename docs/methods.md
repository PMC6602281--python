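# Methods

## Scope and data model

The package implements the computational chain behind a collagen lysine
post-translational-modification (PTM) phenotype study: (1) exact
monoisotopic mass chemistry of lysine modifications and lysyl-oxidase
cross-links, (2) site-occupancy and glycoform quantification from MS1
extracted-ion chromatograms (EICs), (3) isotope-dilution collagen typing
and extractability, (4) cross-link quantification from HPLC
radioactivity traces, and (5) indentation-modulus fitting from AFM force
curves. Raw instrument data are represented as plain long-format tables
(CSV-compatible pandas frames); all quantities of interest are ratios,
so absolute intensity scales cancel by construction.

## Mass chemistry

Element masses are the IUPAC monoisotopic values stored to >= 6
decimals; the only charge adduct is protonation ([M+zH]z+, proton
1.007276 Da). Formulas are non-negative integer element vectors with
element-wise arithmetic; subtraction through zero is an error, which
catches malformed condensation recipes early. Comparisons against
2-decimal instrument-style values use round-half-up at the printed
precision (`chem.round_half_up`), the convention under which 558.3246
prints as 558.32.

Residue chain-form compositions (20 standard residues plus 4-Hyp, Hyl,
G-Hyl, GG-Hyl, allysine, hydroxyallysine, pyroglutamate) ship as a CSV
resource users can extend. Key identities maintained by construction:
Hyl = Lys + O; G-Hyl = Hyl + C6H10O5; GG-Hyl = Hyl + C12H20O10;
allysine = Lys − NH3 + O (−1.03163 Da); pyroGlu = Gln − NH3 = Glu − H2O.

Cross-links assemble from *free* amino acids (chain form + H2O) minus
condensation waters plus H2 per borohydride-reduced bond:
LNL = allysine + Lys − H2O + H2; HLNL uses Hyl; HHMD = 2 allysine + His
+ Hyl − 2 H2O + H2 (the two allysines first form the aldol condensation
product, ACP, accounting for one of the waters); d-HHMD replaces Hyl
with Lys. G-/GG-HLNL add one/two anhydro-hexoses. These recipes
reproduce the four reference ions exactly (558.32 / 574.32 / 276.19 /
292.19 at z = 1).

### MS/MS fragments

The fragment grammar has two mechanisms: multisets of up to three
neutral losses from {NH3, H2O, HCOOH}, and component release —
heterolytic cleavage freeing one intact component amino acid with a
single hydrogen transferred either way (0/±1 H), emitting both the free
amino acid and its complement. This reproduces the His release at m/z
156.08 common to HHMD/d-HHMD while keeping the search bounded. Reported
marker fragments whose elemental compositions are not independently
known (159.12, 175.11, 245.16, 403.27, 419.26) are *not* hard-coded;
the spectrum matcher only scores within-tolerance agreement (default
0.02 m/z for MS2, same as MS1, since no separate MS2 tolerance is
documented). Assignment takes the eligible precursor with the most
matched fragments; ties are reported `ambiguous`, never broken silently.

## Site occupancy from EICs

Marker peptides carry one or two modifiable lysines; helical sites allow
{Lys, Hyl, G-Hyl, GG-Hyl}, telopeptidyl sites {Lys, Lys^ald, Hyl}.
Variant enumeration collapses isobaric positional isomers (Lys+Hyl vs
Hyl+Lys) into one occupancy class because EICs cannot distinguish them.
The EIC window is an **absolute** ±0.02 m/z (not ppm). Peak areas are
trapezoidal; auto-integration bounds walk outward from the apex to the
first points below 1% of apex (explicit windows are available). Areas
from multiple charge states of one class are summed by default
(configurable to single-charge), keeping area ratios well defined.
Occupancy = 100 × class area / total with Lys^ald pooled into Lys;
glycoform profiles renormalize Hyl + G-Hyl + GG-Hyl to 100%. Every
output row asserts the 100% sum before rounding (report tables round to
1 decimal, half-up).

Aggregation is per-sample-then-average throughout: occupancies,
glycoform profiles, total aldehyde and HLNL glycoform percentages are
computed per sample and group means/dispersions taken afterwards. (The
alternative — renormalizing group means — provably differs at the first
decimal for strongly shifted sites.)

**Known discrepancy.** For the α2(I) Lys-5^N peptide pQYSDKGVSSGPGPM the
computed z = 2 precursor is 696.8086 for the Lys form (696.2928 for
Lys^ald), whereas reference spectra of this peptide are commonly
annotated at 696.8019/696.2864 — a constant offset of ~0.0065 m/z
(~0.013 Da neutral), suggesting a slightly different assumed
composition. The package does not force agreement; the internally exact
Lys/Lys^ald spacing (1.03163 Da neutral) is what quantification relies
on, and both forms shift together so occupancy ratios are unaffected.

**Marker sequences.** Most shipped site sequences are synthetic
collagen-like stand-ins (G-X-Y repeats with a single internal Lys,
flagged `synthetic` in `sites.csv`); only the α1(I) Lys-918/930 and
α2(I) Lys-5^N sequences are literature peptides. All quantification
depends on modification mass *deltas*, which are exact regardless of the
backbone; users with validated method peptides should replace the
resource rows. Prolines at the Y position of a G-X-Y triplet are treated
as fully 4-hydroxylated by default (`hyp_mode=auto`), overridable per
site.

## Collagen typing and extractability

Type I/III content uses stable-isotope-labelled collagen (SI-collagen)
as internal standard: each marker peptide contributes
light/heavy × standard amount; per-type amounts are means over that
type's markers (markers with a dead heavy channel are excluded), and
percentages are over type I + III. Sequential-extraction fractions
(acid-soluble, pepsin-soluble, residual) are 4-Hyp isotope-dilution
amounts normalized to 100%.

## Cross-link levels

Moles of a species = windowed counts / (labels-per-molecule × specific
activity × counting efficiency); levels divide by moles of collagen
(4-Hyp moles / 300 Hyp residues per triple helix — only the denominator
convention, configurable). HHMD and d-HHMD carry **two** tritium labels
(reduced aldimine + reduced free aldehyde), so their counts are halved;
this is an interpretive assumption consistent with the factor 2 these
species carry in the total-aldehyde sum (HLNL + LNL + 2·HHMD +
2·d-HHMD), and the label count is configurable (1 or 2). Elution
windows are method-relative and ship as one table shared by generator
and quantifier; counting efficiency defaults to 1.0 (counts already
corrected). Base hydrolysis preserves O-glycosides, resolving GG-, G-
and free HLNL whose sum equals acid-mode total HLNL; the generator
enforces that conservation so the quantifier can be tested against it.

## AFM nanoindentation

Forward model: F = (4/3)·E/(1−ν²)·√R·δ^{3/2}·C(χ), χ = √(Rδ)/h, with
the bonded-layer polynomial C(χ) = 1 + 1.133χ + 1.283χ² + 0.769χ³ +
0.0975χ⁴ as default — cryo-sectioned tissue adheres to the slide — and
the free-slip set (0.884, 0.781, 0.386, 0.0048) selectable. Defaults:
ν = 0.45, R = 5 µm, h = 40 µm. The fit keeps loading points with
δ ≤ 10% of h (validity range of the correction; configurable), needs at
least 10 of them, seeds E from the closed-form Hertz inversion at the
deepest point and runs scipy least squares (the model is linear in E,
so this is well conditioned). Curves are assumed pre-zeroed; a constant
force offset can be co-fitted behind a flag. Non-convergence is flagged,
never silently replaced. Ignoring the correction on 40 µm sections
biases E upward by ~5% on average over 0.1–2 µm depths
(`analysis/04_afm_validation.py`).

## Synthetic data

Generators are pure functions of (arguments, seed) via
`numpy.random.default_rng`; identical inputs give identical frames, and
every generator returns a ground-truth sidecar so recovery tests never
re-derive truth from the fixture.

* **Chromatograms**: one Gaussian elution peak per occupancy class and
  charge at the theoretical m/z (σ_rt = 8 s on a 1 s grid); the discrete
  profile is normalized so its *trapezoidal* integral equals the target
  area, making noiseless recovery exact rather than approximate.
  Per-sample occupancy vectors are truncated-normal draws per class
  renormalized to 100% — chosen over a Dirichlet to honour the
  per-class SDs of the set-point tables. Noise: multiplicative
  log-normal intensity (σ = 5% default) and uniform m/z jitter bounded
  at ±0.005, safely inside the ±0.02 window.
* **HPLC traces**: discrete Gaussian count peaks centred in each
  species' window, normalized so the *sum* of counts equals
  level × collagen mol × specific activity × labels; optional Poisson
  counting noise.
* **Force curves**: the forward model exactly, with optional relative
  Gaussian force noise.
* **Typing markers**: co-eluting light/heavy peak pairs at placeholder
  m/z values (the heavy channel mimics uniform stable-isotope labelling
  by a fixed mass offset).

Set-point tables (occupancy vectors with SDs per genotype and site,
cross-link levels, regional moduli, type III percentages, extraction
fractions) live in `collagen_ptm.defaults`. Printed occupancy vectors
whose per-class rounding makes them sum to 100 ± 0.1 are renormalized to
exactly 100 at load. Group sizes default to the study design (n = 3 MS
and AFM samples, n = 10 cross-link samples per genotype).

What the generators do **not** emulate — retention-time drift and
misalignment across runs, isotope envelopes and co-eluting
interferences, detector saturation, baseline drift in HPLC traces,
contact-point error and adhesion in force curves. Passing recovery tests
therefore demonstrate correctness of the quantification arithmetic and
estimator implementations under the stated noise model, not robustness
to those instrument artefacts.

## Statistics

Group summaries report mean with SD or SE (per table convention, SE for
moduli). Pairwise comparisons (WT vs KO, Het vs KO) use Welch's
two-sample t-test without multiplicity correction, with star tiers at
0.05/0.01/0.001/0.0001 — an interpretive default, documented as such,
with exact ties short-circuited to p = 1 and distinct zero-variance
groups to the smallest tier. A seeded Monte-Carlo calibration (500 null
replicates at n = 5) checks the empirical type-I error lies in
[0.03, 0.07] at α = 0.05.

## Numerical choices and problem sizes

Tolerances: mass additivity asserted to 1e-9 Da; EIC ±0.02 m/z;
noiseless pipeline recovery to 1e-6 percentage points; AFM round trip to
0.1%. Test and analysis problem sizes (n = 5 noisy occupancy samples,
n = 10 cross-link cohort, 50 noisy force curves, 300–500 t-test
replicates) are the smallest at which the 2-SE recovery criteria are
meaningful; the full cohort report runs in a few seconds.

## Limitations

* No retention-time alignment, label-free normalization or MS2-based
  quantification; chromatograms are assumed pre-calibrated in m/z.
* Mature trivalent cross-links (pyridinolines, pyrroles) are out of
  scope — the chemistry here covers the immature reducible species of
  soft tissue.
* The shipped marker sequences for most helical sites are synthetic
  stand-ins (see above); absolute peptide m/z values are method
  placeholders, exact only in their modification deltas.
* Whether HHMD-family counts should be divided by one or two labels is
  an assumption exposed as a parameter, not settled by the package.
* Viscoelasticity, adhesion and cantilever calibration are outside the
  indentation model; E_ind is an effective elastic modulus.
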