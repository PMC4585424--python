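# Methods

This note documents the models implemented in `phenopipe`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## Imaging geometry

Side-view distances convert to mm with a single camera constant,
`side_coeff` (default 0.5156 mm px⁻¹ for the calibrated cabinet).
Because the top camera looks down on the plant, its effective pixel size
depends on plant height; the y-coordinate of the shoot's centre of mass
in the side view (`cm_pix`, y increasing downward) proxies height, and
`top_coeff = top_slope·cm_pix + top_offset` (defaults 0.0001097 mm px⁻²,
0.2899 mm px⁻¹). Areas scale with the squared pixel size. The two side
views (90° apart) are averaged into one `side_area_px` upstream; the
record stores the average. All three constants live in the `camera:`
config block, not in code.

## Area-to-trait calibration

For each of dry biomass, fresh plant weight and leaf area, ordinary
least squares is fitted for every subset of the five predictors
{side, top, side², top², side:top} (intercept always included; 32
candidates) on the destructive-harvest table, and the lowest-BIC model
is selected. BIC is the Gaussian form `n·ln(RSS/n) + k·ln(n)` with
`k = |terms| + 2` counting the intercept and the residual variance; only
BIC differences matter and the convention is uniform. An exact fit
(RSS = 0) maps to a −∞ sentinel that is logged, never silently compared.
Rank-deficient candidates are skipped with a warning; BIC ties break
toward fewer terms, then enumeration order.

Both watering treatments are pooled when fitting, and the selected model
is applied with identical coefficients to both — this keeps the two
regimes comparable and makes responses to soil water potential
meaningful. Per-treatment fitting exists behind
`per_treatment_calibration` but is off by default. Negative predictions,
which can occur for very small plants, are flagged in an `issues` column
and **not** clipped: clipping would bias the subsequent growth-curve
fits.

A caution on interpreting the selected terms: side and top areas of real
plants are driven by one dominant latent size, so the five predictors
are strongly collinear (pairwise correlations 0.94–0.999 on harvest
data). Under such collinearity several term subsets fit near-identically
and the BIC winner is a parsimonious representative, not a unique
"true" structure; what is stable is the fitted response surface. The
test suite therefore checks subset recovery on well-conditioned designs
(independently varying areas) and predictive equivalence on realistic
harvest designs.

## Thermal time

The temperature response of development is
`F(T) = A·T·exp(−ΔH_A/(R·T)) / (1 + exp(−ΔH_d/(R·T))^{α(1−T/T0)})`,
T in Kelvin. `ΔH_A` (J mol⁻¹) sets the low-temperature curvature, `α`
(dimensionless, fixed at 3.5 for developmental processes) the sharpness
of the high-temperature decline, and `T0` (K) the optimum region. By
default `ΔH_d = ΔH_A` — the single-enthalpy form — with a `dHd` config
hook for the two-enthalpy formulation. Note that in the single-enthalpy
form the argmax of F sits a few degrees below T0; T0 marks the onset of
the decline. A rate at temperature T becomes an equivalent rate at 20 °C
through `J₂₀ = J·F(20)/F(T)`; a duration becomes equivalent days at
20 °C (d₂₀) by integrating `F(T)/F(20)` piecewise-constant over the
logger intervals (matching the data cadence; no interpolation
assumptions). The scaling coefficient A cancels in every ratio.
Evaluation is in log space (`logaddexp`) because the power term
overflows above the optimum.

Default parameters `ΔH_A = 73 kJ mol⁻¹`, `T0 = 305 K` are implementer
choices for a cool-season cereal, suitable for tests; production runs
should set species-specific values explicitly (instantiating the
defaults emits a warning).

## Growth curves

Each plant × trait series (trait value versus d₂₀) is fitted with the
candidate families listed in `growth.MODELS`. The formulas for the
richer sigmoids (4-parameter logistic, Richards with and without a lower
asymptote, Gompertz, Weibull) are the standard parameterizations,
documented in code; on platform-like data only linear, exponential and
the 3-parameter logistic converge reliably, and the logistic wins the
BIC comparison, so those three are the default candidate set.

The logistic self-start takes `V_final⁰ = 1.05·max(v)`, `t0⁰` at the
value closest to half of that, and `K⁰` from the slope of
`logit(v/V_final⁰)` against t. Optimization is trust-region-reflective
least squares from the self-start plus three jittered restarts (10%
relative jitter, seeded); the best residual is kept, restarts are
skipped once a numerically exact fit is found. Failures set an honest
`converged=False` with a diagnostic message rather than raising; a
logistic fit whose inflexion lands more than 50 d₂₀ outside the data is
likewise flagged. Fits use ordinary (unweighted) least squares on the
raw calibrated values, including any negative early predictions.

Derived quantities use closed forms: growth rate `K·V·(1−V/V_final)`,
relative rate `K·(1−V/V_final)` (monotone decreasing, supremum K — hence
K is the maximum relative growth/expansion rate), `Growth_AVE =
(V(50)−V(35))/15` over the 35–50 d₂₀ analysis window, and the window
RGR as the trapezoid mean of the relative rate on a 0.1 d₂₀ grid
(`rgr_mode="midpoint"` gives the mid-window value instead). The window
is interpreted in thermal days — the derived traits carry d₂₀ units —
and is configurable. `Tx` is identified with the fitted `t0`, `K_RGR` /
`K_RER` with the fitted `K`.

## Water use

Pot bookkeeping: `total weight = tare + dry soil + water + plant fresh
weight`. At each weighing, water mass is the pot weight minus tare, dry
soil and the *modelled* fresh plant weight; gravimetric content θ is
water per unit dry soil. The plant-weight correction defaults to the
treatment-population mean modelled weight at that time
(`plant_weight_correction="population_mean"`), which is what a mean-based
correction implies when individual destructive weights are unavailable;
`"per_plant"` uses each plant's own fitted curve and makes the water
balance exact per plant (the noise-free identity tests use it — the
population-mean mode deliberately accepts a small per-plant bias, up to
~2% of window transpiration for plants far from their treatment mean).

Water loss over an interval is the post-watering water store minus the
next pre-watering store; evaporation is the mean loss of the
artificial-plant pots of the same treatment and interval (carried
forward with a flag if an interval is missing); transpiration is the
difference, floored at zero with a QC flag when the evaporation estimate
exceeds the loss. The closure `loss = transpiration + evaporation` is
exact by construction whenever nothing is floored.

The water-release curve is Van Genuchten,
`θ(Ψ) = θ_r + (θ_s−θ_r)·[1+(a·|Ψ|)^n]^(−m)`, `m = 1−1/n`, fitted by
least squares to the drying-pot observations and inverted in closed
form. Contents outside `(θ_r, θ_s]` within 1% of the span (measurement
noise) are clamped with a flag; beyond that, an error. Ψ per interval is
the mean of the post-watering and next pre-watering potentials, and the
window Ψ is the time-weighted mean over the interval overlaps.

Window traits allocate each watering interval's transpiration pro rata
to the thermal window so totals are conserved: `TR = total/window
length` (g d₂₀⁻¹; a calendar-day variant `TR_cal` is also emitted,
flagged, because transpiration tables sometimes print per calendar day),
`TR_area = TR / mean modelled leaf area`, `WUE = (Biomass(50) −
Biomass(35)) / total transpiration`. The identity `WUE × TR =
Growth_AVE` holds exactly by construction and is asserted for every
plant. Relative responses pair the two treatments of the same line ×
replicate (grown next to each other) as `(Value_D − Value_WW)/(Ψ_D −
Ψ_WW)`, undefined (flagged) when the potentials differ by under
0.005 MPa.

## Genetics

Variance components come from one-way random-effects ANOVA by method of
moments (unbalanced designs use the effective replicate number n₀);
σ²_G is floored at zero. Broad-sense heritability is on a line-mean
basis, `h² = 100·σ²_G/(σ²_G + σ²_e/r)` — the replicate-mean convention,
chosen because line means are what enter the marker scan.

The scan regresses each line-mean trait on each marker (coded +1/−1 for
the two parental alleles, missing calls mean-imputed per marker) after
removing optional covariates such as phenology-gene genotypes; the
statistic is the marker F test, and the additive effect is half the
difference between allele-class means, positive when the "A" (first
parent) allele increases the trait — label flips flip every sign.
Monomorphic markers are skipped with a flag. The genome-wide threshold
is the 95th percentile of the max-over-markers statistic under joint
permutation of the phenotypes across lines (default 1000 permutations,
seeded, vectorized as one matrix product, bit-reproducible).
Composite interval mapping is out of scope; the scan is the standard
first-pass single-marker analysis.

Allele-group curves resample lines with replacement within each allele
class (no refitting), average the fitted logistic curves on a common
grid, and report the bootstrap mean and SD envelope per class.

## The synthetic experiment

The generator emulates the platform study design: 150 RILs × 2
replicates × 2 watering regimes (watered back every second day to
−0.02 / −0.05 MPa), imaging and weighing every second day from day 21
to day 61 after sowing, two artificial-plant evaporation pots per
treatment, a 17–25 °C daily temperature sinusoid logged hourly, a
parental destructive harvest twice a week, and five drying pots for the
water-release curve (drying from retention capacity to −1.6 MPa).

Per plant, a latent logistic development curve S(t) on the thermal axis
drives the side (`c1·S`) and top (`c2·S^0.9`) areas; the three trait
truths are fixed second-order polynomials of the two areas (the same
family the calibration stage searches). Latent parameters are population
base + treatment effect + line effect + planted QTL effects + replicate
residual; the replicate component dominates the line component so that
heritabilities land in the low-to-moderate band (roughly 0–55%)
characteristic of image-derived traits. Treatment bases (K 0.143/0.130
d₂₀⁻¹, t0 56/51 d₂₀, drought size factor 0.32, transpiration
coefficients 5.3/3.2 mg mm⁻² d⁻¹) were chosen once so the population
means of Growth_AVE, LER_AVE, TR and WUE sit at the scale typical of
wheat platform experiments (≈0.3 g d₂₀⁻¹ well-watered Growth_AVE,
≈0.003–0.004 g g⁻¹ WUE, and so on).

Transpiration over a watering interval is `tr_coef · LA/(1+LA/LA_sat) ·
demand · Δt` — the saturation expresses canopy self-shading, demand
fluctuates sinusoidally between intervals (amplitude 0.10, period 10 d)
to mimic evaporative-demand weather, and an interval's transpiration is
capped so the pot never dries past θ_r + 0.03 (stomatal closure).
Evaporation depends on the post-watering water content (so the drier
regime evaporates less), which also makes the artificial-pot estimate
exact within a treatment. Biomass truth is the biomass polynomial of the
areas; WUE truth is its window gain divided by window transpiration.

Planted QTLs (defaults: a size locus, a K locus, a transpiration locus,
and two phenology loci acting on t0) shift the latent parameters
additively; genotypes follow RIL linkage (Haldane map function with the
2r/(1+2r) selfing correction) over 7 chromosomes × 20 markers with 2%
missing calls. Ground truth is written under `truth/` and never read by
the pipeline.

What the generator does **not** emulate: image segmentation errors that
correlate over time, diurnal transpiration dynamics and VPD coupling,
soil heterogeneity between pots, genotype × environment interaction
beyond the treatment main effect, flowering-time censoring of the
imaging window, and field/polytunnel agronomy. Passing tests therefore
validate the pipeline's arithmetic, statistical calibration and
recovery power under a faithful but idealized generative model — not the
segmentation quality or biological assumptions of any particular real
platform.

## Numerical choices and edge cases

- Temperature response in log space; reference exactly 293.15 K.
- Thermal-axis values at arbitrary days interpolate a 0.25-day grid of
  exact integrals.
- Logistic BIC uses k = params + 1 (residual variance), consistent with
  the calibration convention.
- Degenerate growth series (constant values, too few points) yield a
  non-fittable flag, not an exception; a whole-plant failure is recorded
  per plant and never aborts a run.
- The Van Genuchten inversion is closed-form; the 1% clamp tolerance is
  interpreted as 1% of (θ_s − θ_r).
- θ_r is weakly identified when drying stops far above residual content;
  with the five-pot design and a sharp retention curve (n ≈ 2, typical
  of coarse potting mixes) all four parameters are recovered within 5%
  under 1% content noise.
- Permutation thresholds and bootstraps take explicit seeds; identical
  seeds give bit-identical results.
- Problem sizes in the test suite (20–40 lines for identity checks, the
  full 150 × 2 × 2 for parameter-recovery and statistical-calibration
  checks, 200 null scans at 200 permutations) were chosen as the
  smallest designs at which the checked properties are stable.

## Known limitations

- The single-marker scan ignores linkage when declaring hits; adjacent
  markers of one QTL all exceed the threshold and are reported
  individually (no peak collapsing or confidence intervals).
- The population-mean plant-weight correction biases per-plant
  transpiration slightly toward the treatment mean (see above).
- Heritability uses the line-mean convention; plot-basis values would be
  lower.
- The calibration's selected term subset is design-dependent under
  collinearity; downstream traits depend only on the fitted surface.
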