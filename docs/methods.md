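# Methods

This note documents the models behind `leafstress`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions taken where the underlying methodology left
the design open.

## Experimental design being emulated

A factorial pot-drought experiment on two-year-old seedlings of a
deciduous, autumn-coloring tree: four soil-water treatments (CK = 100% of
field capacity; T1 = 75–80%; T2 = 50–55%; T3 = 35–40%) × four sampling
periods (S1–S4 at 20-day intervals across the leaf-color transition) × 3
replicates. Twenty-six traits flow through the pipeline: three CIELAB
color coordinates, eight anatomy measures, three pigment contents and
three pigment ratios, two antioxidant enzyme activities, two gas-exchange
rates, and five hydraulic parameters.

## Trait derivation

### Colorimetry

Leaves are the sampling unit (several leaves per replicate, each read
several times), so aggregation is *leaf-then-replicate*: per-leaf reading
means, then an unweighted mean over leaves, with the SE taken over
leaves. A pooled mean over all readings would silently reweight leaves by
their read counts.

### Pigments

The exact extinction-coefficient sets behind published pigment tables are
rarely printed, so coefficients are configuration with documented
defaults and every report records the set used:

- Chlorophyll (80% acetone, 645/663 nm, Arnon-style, mg/L):
  Chl a = 12.70·A663 − 2.69·A645, Chl b = 22.90·A645 − 4.68·A663.
  Total chlorophyll is defined as the **row sum** of the a and b
  equations (20.21·A645 + 8.02·A663) rather than an independently rounded
  total, keeping the split and total mutually consistent and making the
  synthetic inverse → forward round trip exact.
- Carotenoids, adapted to the 445 nm band:
  Car = (1000·A445 − 3.27·Chla − 104·Chlb)/229 mg/L. The k-coefficients
  are configurable; the defaults are a Lichtenthaler-style correction set.
- Anthocyanin: ΔA = A530 − 0.25·A657 (chlorophyll interference
  correction), floored at zero with a flag. Default output is in relative
  ΔA-based units per g fresh weight because the extinction convention for
  acidified-methanol extracts varies between labs; an optional molar mode
  uses the cyanidin-3-glucoside convention (ε = 29 600 L mol⁻¹ cm⁻¹,
  M = 449.2 g/mol).

Contents scale as volume × dilution / mass (homogeneous of degree 1, 1,
−1), which the property tests assert.

### Anatomical hydraulic conductivity

Each petiole vessel of equivalent circular radius r (from its measured
cross-section area, r = √(area/π)) contributes a Hagen–Poiseuille
volumetric conductivity K_i = π r⁴ / (8 η ℓ). A bare π r⁴ / 8η is not
dimensionally a conductivity, so the conduit (petiole) length ℓ is an
explicit parameter, default 0.02 m — a typical petiole length for
hand-cut sections. Because ℓ is a common factor, *relative* comparisons
between treatments are unaffected by its value; absolute magnitudes
inherit its uncertainty, which is why the package treats the published
K_max span as a plausibility band rather than a point target.

K_max = (N / (n·A)) Σ K_i over the n counted vessels (N total vessels,
A leaf area), with a warning when fewer than two-thirds of the vessels
were measured (the conventional sampling rule). Unit conversion to
mmol m⁻² s⁻¹ MPa⁻¹: divide the volumetric flux density (m s⁻¹ Pa⁻¹) by
the molar volume of water (1.8×10⁻⁵ m³ mol⁻¹), multiply by 10⁶ Pa MPa⁻¹
and 10³ mmol mol⁻¹.

Water viscosity comes from the Vogel correlation
η = exp(−3.7188 + 578.919/(T − 137.546)) mPa·s (T in kelvin), accurate to
about 1% over 0–60 °C; the default water temperature is 25 °C.

### Epidermal conductance

A detached saturated leaf drying in the dark loses weight in two roughly
linear phases: a steeper stomatal phase and, after stomatal closure, a
shallow tail governed by the epidermis. Phase detection fits every
two-segment split of the time series (each segment ≥ 3 points) with
independent least-squares lines and keeps the split with minimal total
SSE, returning the later segment's slope; ties resolve to the longest
tail. Conductance follows g_e = 2.31×10⁶ · |slope| / (A · Δe) with the
2.31×10⁶ factor treated as a given unit-conversion constant (its exact
derivation, like the "mm m⁻³" humidity unit, is not standard; Δe is
consumed as a number in those units, and a separate helper is *not*
provided to avoid implying a unit interpretation the formula does not
license).

### Pressure–volume curves

Model: water potential Ψ(R) = Ψ_π(R) + Ψ_p(R) with the osmotic component
Ψ_π = Ψ_sat (1 − a_f)/(R − a_f) (van't Hoff dilution of symplastic
water; a_f = apoplastic fraction) and, above the turgor loss point, a
turgor component linear in R from −Ψ_sat at full hydration to zero at
RWC_tlp. The linear turgor term is the simplest model consistent with the
classical framework and is sufficient for recovery testing; real
pressure–volume curves have curvilinear turgor driven by elasticity.

Fitting transforms observations to (x = 1 − RWC, y = −1/P). The osmotic
line is seeded with the driest third of the observations — air-drying
protocols deliberately run well past turgor loss, so the driest third is
safely osmotic — and grown toward wetter points while each candidate's
residual stays within 2.5× the current RMSE. Two numerical choices
matter:

- residuals are evaluated on the **pressure scale**, not the transformed
  scale: chamber noise is approximately homoscedastic in P, while the
  −1/P transform inflates it at wet (low-pressure) points and would stall
  the region growth there;
- R² (default threshold 0.99) is a **final validation** of the accepted
  region rather than a growth criterion, because over a short dry-end
  span the statistic is noise-dominated even on perfectly osmotic points.

Outputs: Ψ_sat = 1/intercept, a_f = 1 − x₀ (x-intercept), RWC_tlp = RWC
of the wettest accepted point (the discrete-departure convention of
classical PV analysis; a flag midpoints toward the first rejected
observation instead), Ψ_tlp = osmotic line evaluated at RWC_tlp. Every
successful fit satisfies Ψ_tlp < Ψ_sat < 0 and a_f < RWC_tlp; violations
raise with diagnostics rather than returning nonsense.

Recovery performance under the simulated protocol (24 points from
RWC 0.98 to 0.58, 0.02 MPa pressure noise, 100 seeds): median absolute
errors ≈ 0.007 MPa (Ψ_sat), 0.007 (RWC_tlp), 0.021 MPa (Ψ_tlp), with
≈ 1% of curves rejected by the R² validation.

## Statistics

Two independent one-way ANOVA families annotate the factorial table
exactly as drought-trait tables are conventionally lettered: lowercase
letters compare treatments within each period, uppercase letters compare
periods within each treatment. No two-way model, no repeated-measures
correction, and no cross-trait multiplicity adjustment are applied; the
report layer states this.

`anova_from_summary` recovers each group's variance as n·SE², making it
*exactly* equivalent to raw-data ANOVA on any data sharing those
sufficient statistics (asserted to 10 decimals on random instances).
Zero within-group variance with unequal means is reported explicitly as
F = ∞, p = 0.

Duncan's multiple range test computes critical ranges from the
studentized-range distribution at Duncan's protection levels
α_p = 1 − (1−α)^(p−1) for a span of p ranked means — reproducing the
classical tables without shipping them — with the standard step-down
constraint that pairs inside a non-significant span stay non-significant.
Unequal group sizes fall back to the harmonic-mean n with a warning.
Compact letter displays use the insert-and-absorb algorithm with letters
assigned in descending-mean order. Property tests assert the sandwich
relation Tukey ⊆ Duncan ⊆ LSD on random instances.

## Random-forest importance

The tree learner is scikit-learn's `DecisionTreeRegressor`; the bagging,
OOB bookkeeping, %IncMSE permutation loop, both permutation tests, and
backward selection are implemented in this package because they are the
analysis being specified. Defaults: 500 trees, mtry = ⌈p/3⌉ (the
regression-forest one-third convention, rounded up so small predictor
sets are not reduced to single-feature splits).

%IncMSE: for each tree, each predictor's values are permuted within that
tree's OOB samples and the OOB MSE recomputed; the importance is the mean
MSE increase over trees as a percentage of the mean per-tree OOB MSE.
Per-predictor significance refits the forest on response-permuted data
(default 100 permutations) and reports p = (1 + #{null ≥ observed}) /
(n_perm + 1), never exactly zero. Whole-model significance applies the
same construction to the OOB R² with 99 permutations (minimum attainable
p = 0.01). Backward selection repeatedly drops the lowest-%IncMSE
predictor and refits until the target count (default 14 of 23) remains;
the drop criterion is this package's concrete choice, as the named
procedure does not fix one.

With n = 48 observations and 14 retained predictors the rankings are
seed-sensitive; reports carry that caveat, and the qualitative
pattern checks are therefore framed as seed-majority properties, not
point reproductions. Published model R² values for the original raw data
are not reproducible without that data and are deliberately not targets.

## Synthetic data: what it does and does not emulate

The generator draws every replicate as mean + Gaussian(0, SE·√n_SE)
around per-cell means, where n_SE = 3 is the replicate count behind the
configured SEs — so sample SEs match the configured ones in expectation
regardless of how many replicates are drawn. Within-cell Gaussianity is
an assumption of the emulation; the study's raw distributions are
unpublished.

Cell means come from two sources, kept explicitly distinct in
`leafstress.config`:

- the eight anatomy traits carry published per-cell means ± SE verbatim;
- all figure-only traits (color, pigments, enzymes, gas exchange,
  hydraulics) are **plausible calibrations**: anchored to the values and
  percent changes quoted in the running text (e.g. the a\* anchors 29.6 /
  3.7 / 43.4; the fourth-period hydraulic declines of 5.1/24.3/45.2%
  for K_max and their analogues; the enzyme and gas-exchange percent
  differences), and otherwise chosen once to follow the described
  treatment/period profiles. They are flagged via
  `leafstress.config.CALIBRATED_TRAITS` and are not printed data.

Pigment ratios are computed per replicate from the drawn pigment values,
preserving their sampling correlation.

All randomness flows from one master seed through named substreams
(CRC32 of the stage name mixed into a `SeedSequence`), so stages can be
regenerated independently and a fixed seed is bit-reproducible.

Zero-noise round trips through the corresponding analysis operations are
identities (color aggregation, pigment inversion, drydown slope, PV
parameters, K_max), which is the backbone of the test suite.

What the generator does **not** emulate: soil-water dynamics and the
weighing-method irrigation control, seedling growth, non-Gaussian or
heteroscedastic replicate error, instrument drift, elastic (curvilinear)
turgor in PV curves, within-leaf spatial color variation beyond iid
reading noise, and any causal coupling between traits beyond the shared
cell-mean structure — passing tests therefore demonstrate correctness of
the estimators and statistics under the stated noise model, not fidelity
to every property of real measurements.

## Problem sizes

Simulation-based checks use desk-scale sizes chosen to make the test
suite quick while keeping Monte-Carlo error far from the decision
thresholds: 100 seeds for PV and drydown recovery; 100 seeds × 20
response permutations × 50-tree forests for the permutation-test
calibration (the plus-one estimator's attainable p-values at 20
permutations still straddle α = 0.05 cleanly); 20 seeds × 500-tree
forests for the importance-pattern check. The pipeline defaults keep the
published analysis sizes (500 trees, 100/99 permutations).

## Known limitations

- Absolute K_max magnitudes inherit the petiole-length and viscosity
  conventions discussed above.
- The PV region-selection thresholds (residual factor 2.5, R² ≥ 0.99,
  minimum 3 points, driest-third seed) are this package's choices; other
  PV software draws the osmotic region differently and can shift RWC_tlp
  by roughly one observation spacing.
- Duncan's test is implemented for the balanced one-way layouts used
  here; the harmonic-mean fallback for unbalanced data is approximate.
- The anthocyanin default is a relative (ΔA-based) unit; cross-study
  comparisons require agreeing on an extinction convention.
- `importance_significance` refits the full forest per permutation; at
  published sizes (500 trees, 100 permutations) this is minutes, not
  seconds, per response.
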