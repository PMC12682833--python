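# Methods

This note documents the models, numerical choices and open design decisions
behind rhizotrace, and what the synthetic-trial tests do and do not show about
real field data.

## Depth registration and observation area

A minirhizotron tube runs obliquely from the edge of a bed (shallow) to its
centre (deep). Depth registration is **linear between two anchors**: the soil
depth of the first imaged position (default 0.6 m at tube distance 0 mm) and
the depth at the end of the tube (default 3.0 m at 5500 mm). A trigonometric
registration from the nominal 24° slope is *not* used: a 5.5-m tube at exactly
24° drops 5.5·sin 24° ≈ 2.24 m, which is inconsistent with the stated
0.6→3.0 m span, so the anchors take precedence and the angle is kept as
metadata. Facility descriptions also quote 2.7 m as the depth at the bed
centre; the deepest-anchor default of 3.0 m follows the imaging protocol and
both anchors are configurable.

Images are taken every 35 mm along the tube (158 positions for the default
geometry, ≈ 1.53 cm of soil depth between images). The observation area of a
half-open depth interval [lo, hi) is (images in the interval) × step × image
width. The across-tube image width has no single authoritative value; the
default (240/11 ≈ 21.82 mm) is derived by inverting, in the continuous limit,
the calibration that a 0.25-m depth interval exposes 0.0125 m² of observation
area. Because image positions are discrete, any specific 0.25-m interval
realises this to within one image's area (≈ ±3 %). Depth intervals are
half-open everywhere so that binning is an exact partition.

## DeepRoot₄₀

With C(d) = Σ root length at image depths ≥ d, DeepRoot₄₀ is the greatest
depth d\* with C(d\*) ≥ 40 cm — "the depth below which 40 cm of cumulative
root length is observed", so deeper-rooting tubes score *higher*. The
bottom-up cumulative curve is a step function on the image grid; reporting the
crossing image's depth would quantise the trait at the 1.5-cm image spacing,
so the crossing is linearly interpolated between the crossing image and its
deeper neighbour, in proportion to the root length needed from the crossing
image. The test oracle is an independent 1-mm grid scan of the linearly
interpolated cumulative curve; the two agree to within the 0.1-cm grid
resolution (tolerance 0.5 cm). Profiles holding less than the target length
return a missing value (with a logged shortfall), which propagates through
genotype means and correlations by pairwise deletion — shallow-profile tubes
are never silently assigned a depth.

DeepRoot₄₀ is monotone under the addition of root length below the current
threshold, and never decreases under uniform up-scaling of a profile; both are
enforced as property tests.

## Sigmoid inflection

Root length per image is fitted with a decreasing logistic
y(d) = A / (1 + e^{k(d−m)}), A > 0, k > 0, m within the observed depth range,
by bounded least squares (analytic Jacobian). Initialisation: A₀ = 95th
percentile of y, m₀ = length-weighted median depth, k₀ = 4 / depth span. The
exact parameterisation used by earlier SI implementations is not fully
specified in the literature; this logistic form is the package's documented
choice. Profiles with coefficient of variation < 0.05 have no depth
transition and return a missing value, as do non-convergent fits and fits
with m pinned at a depth bound — never a silent boundary value. On exact
logistic data the fit recovers m to better than 0.1 cm; under multiplicative
noise with CV 0.3 on the full image grid the median absolute error is < 10 cm
(Monte Carlo, 50 seeds).

## Isotope mass balance

Delta values convert to atom fractions via R = (δ/1000 + 1)·R_std,
AF = R/(1+R), with literature standard ratios (¹⁵N/¹⁴N air = 0.0036765,
¹³C/¹²C VPDB = 0.011180, ²H/¹H VSMOW = 0.00015576) held as configurable
metadata. Excess ¹⁵N per tissue sample is N mass × (AF(δ) − AF(baseline));
the unlabelled baseline defaults to δ¹⁵N = 0 ‰ vs air (no control-plot
measurement is assumed) and is configurable. Negative excess values, possible
within measurement noise, are flagged but not clamped, preserving unbiased
averages.

The tracer mixture totals 1.51725 g ¹⁵N (8.925 g Ca nitrate in 54.6 L of
water) and 1 L of ²H-labelled water per line application. Dividing by 200 row
sides reproduces the documented per-row-side amounts (0.00759 g and 5 mL);
the physical basis of that divisor (rather than 300 rows × 2 sides) is not
documented, so it is an explicit configuration field. Percent recovery per
crop row divides the row's total excess by the per-row applied dose,
total × n_injections / n_rows; n_injections defaults to
2·n_rows/n_row_sides = 3, the unique value making the per-row dose equal two
row-side doses. Grain-only and grain+straw recoveries are reported
separately, since straw is sampled in a subset of rows. δ¹³C is analysed as
raw per-mil values (no discrimination-Δ conversion), and ²H is reported as δ
only, without a mass balance. Model transforms are ln(δ¹⁵N) and ln(δ²H + 90),
with domain violations reported by row.

## Genotype statistics

The reference analysis for this kind of trial is a generalized least squares
fit with a spatial correlation structure over row/bed/year. That requires the
facility's exact layout and is deliberately **not** reproduced; the package
uses OLS with genotype and year fixed effects, bed effects and a quadratic
along-bed position covariate, and records this divergence in the output
metadata. Marginal genotype means average the fitted surface over years and
beds at the mean position. Pairwise genotype differences use the studentized
range (Tukey) when replication is balanced and Holm-adjusted t-tests
otherwise; letters come from insert-and-absorb, and the letter display is
validated as an exact encoding of the non-significance graph (two genotypes
share a letter iff their adjusted p ≥ α). Rank-deficient designs (a genotype
confounded with a bed) raise an error naming the aliased terms.

Cultivar-mean correlations are Pearson, two-sided p from the t-distribution
with n − 2 df, pairwise deletion, α = 0.05; zero-variance inputs are flagged
rather than propagated as NaN. Depth-interval screening correlates cultivar
means of interval root length with cultivar means of an isotope value across
a grid of intervals.

## Synthetic trial generator

The generator's defaults define the simulated study conditions and are fixed;
they were chosen from the magnitudes typical of this kind of facility, not
fitted to any particular dataset.

- **Design**: 9 core genotypes × 10 rows + 39 genotypes × 4 rows = 246 rows
  per year, randomised over 2 beds, three years. One June imaging session per
  year is generated (the session used for trait–isotope correlation);
  per-year midpoint offsets (+5, −17, 0 cm) make one year shallow-rooted.
- **Profiles**: expected root length per image is logistic in depth with
  A = 2 cm, midpoint m₀ = 120 cm, k = 0.05 cm⁻¹ (expected DeepRoot₄₀
  ≈ 94–99 cm). Genotype midpoint shifts b_g ~ N(0, 10 cm) persist across
  years (plus N(0, 4 cm) genotype × year jitter); row-level shifts are
  N(0, 6 cm) with a ±3 cm linear along-bed trend. Because a midpoint shift
  translates the whole profile, planted DeepRoot₄₀ differences equal the
  planted shift differences exactly — used to plant a 25-cm extreme-genotype
  gap in the power check.
- **Observation noise**: multiplicative LogNormal(0, 0.3) per image (CV
  ≈ 0.3), plus an additive half-normal detection floor of SD 0.02 cm per
  image representing spurious/missed detections, which dominates where roots
  are sparse and is why very deep, near-empty intervals carry little signal.
- **Isotope coupling**: grain δ¹⁵N = 20 + 3·L + ε(4 ‰) and grain
  δ²H = −60 + 4·L + ε(6 ‰), where L is the genotype's expected root length
  (cm) in the 1.6–1.8 m injection interval; straw δ¹⁵N is lower
  (8 + 2·L + ε(3)). Grain δ¹³C = year intercept − 0.012·severity·DeepRoot₄₀ᵉˣᵖ
  + ε(0.3 ‰), with severities (1.0, 0.6, 1.8) for the three years so the
  water-stress coupling is strongest in the dry year and weakest in the wet
  one. Couplings act at the genotype level; row noise is independent.
- **Tracer bookkeeping**: per-row uptake fractions are back-computed from the
  drawn δ¹⁵N values with inline atom-fraction arithmetic (independent of the
  isotopes module) and stored in the row-level truth table; aggregate
  recovery computed by the isotopes module must equal the planted aggregate
  within 1e-6. Whole-row dry masses (grain ≈ 1400 g at 2.2 %N, straw
  ≈ 1800 g at 0.5 %N; straw sampled in 60 rows/year) put per-row recoveries
  around 10–30 %.

**What the generator does not emulate**: soil-water dynamics and weather,
spatially correlated residuals (the generator's spatial trend is smooth and
low-order, which is exactly what the simplified OLS surrogate can absorb),
root diameter/branching, session-to-session root growth within a year, and
measurement artefacts such as tube-surface condensation. Passing tests
therefore demonstrate that the estimators recover the structure they assume,
at realistic noise levels — not that a real facility's spatial correlation or
year effects are handled optimally.

## Problem sizes used in the checks

The acceptance suite uses 200 random profiles for the oracle comparison, 500
cases for the monotonicity property, 50 seeds for the sigmoid Monte Carlo, 50
coupled + 200 null single-year trials for the correlation effect-recovery and
calibration checks, and 500 balanced 9 × 10 trials for the letters power
check (200 in the acceptance script). These sizes give stable pass/fail
margins for the stated thresholds while keeping a full run within a few
minutes on one CPU.

## Known limitations

- The OLS surrogate understates standard errors relative to a GLS with
  spatial correlation when residuals are strongly autocorrelated along a bed.
- DeepRoot₄₀ underestimates true rooting depth by construction (it is a
  cumulative-length threshold, not a root-front estimate) and is undefined
  for tubes with < 40 cm of observed root.
- The sigmoid fit assumes a single shallow-to-deep transition; bimodal
  profiles return a fit whose inflection is not meaningful (mitigated only by
  the CV floor and bound checks).
- The 0.6→2.7 m vs 0.6→3.0 m imaged-span ambiguity is exposed as
  configuration; results in the deepest half-metre depend on that choice.
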