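# Methods

## The measurement and its model

`iapflow` quantifies regional cerebral blood flow (rCBF) from a
terminal ¹⁴C-iodoantipyrine (IAP) autoradiography experiment.  IAP is a
freely diffusible tracer: during a ~1-minute intravenous infusion,
timed arterial blood samples record the input function `C_A(t)` while
each brain region accumulates tracer according to the Kety
tissue-equilibration (indicator-fractionation) model,

    Ci(T) = λ·K·∫₀ᵀ C_A(t)·e^{−K(T−t)} dt,      K = m·f/λ,

where `Ci(T)` is the tissue concentration at decapitation (nCi/g), `λ`
the tissue:blood partition coefficient, `f = F/W` the blood flow per
unit tissue mass (ml·g⁻¹·min⁻¹) and `m` a proportionality constant.
Flow is the unknown; it is recovered by inverting the forward model
against the measured `Ci(T)`.

Model assumptions: a single well-mixed tissue compartment, flow-limited
(not diffusion-limited) exchange, constant flow over the measurement
minute, negligible isotope decay (¹⁴C half-life ≫ 60 s), and tissue
density ≈ 1 g/ml so nCi/g and nCi/ml are numerically commensurate.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `λ` | tissue:blood partition coefficient (dimensionless) | 0.80 | standard value for IAP in rat brain, applied uniformly across regions |
| `m` | proportionality constant in `K = m·f/λ` | 1.0 | the classical indicator-fractionation convention; exposed so a non-unity instrument constant can be configured |
| `T` | decapitation time (s) | 60 | the head is frozen immediately after the final arterial sample of the 60-s series |
| calibration mode | OD → activity map | interpolating | passes exactly through every standard; an OLS `linear` mode (with R²) is available |
| extrapolation | out-of-range OD policy | error | the eight standards (40–1069 nCi/g) define the trusted range; `clamp` must be requested explicitly |
| min readings | densitometric readings per region | 8 | the protocol's floor of eight average density measurements |
| quench | counting efficiency, or linear curve `a + b·quench_index` | efficiency 1.0, warned | no quench-curve details are available; a direct efficiency column takes precedence |
| `α` | significance level | 0.05 | the study's criterion |

## Numerical scheme

**Integration.**  The arterial curve is linearly interpolated between
samples, with `(0, 0)` prepended when the series does not start at the
infusion onset.  The convolution integral is evaluated by *product
integration*: on each sampling interval the linear interpolant is
integrated against the exponential kernel in closed form, with a series
expansion of the interval weights where `K·Δt < 10⁻³` (the closed form
cancels catastrophically there; series truncation error is below
1e-13).  This is the exact limit of trapezoidal integration under grid
refinement, is independent of any auxiliary grid, and achieves
round-off-level agreement with the constant-input closed form
`λ·C_A·(1−e^{−KT})` — a plain composite trapezoid at fixed step `h`
carries a relative error of order `(K·h)²/12`, which would dominate the
tolerances the round-trip and limit checks require.

**Inversion.**  `K` is found by Brent's method inside the bracket
`[10⁻⁸, 10] s⁻¹` (absolute tolerance 1e-10 on `K`), widened ×10 up to
twice before declaring non-identifiability.  A vectorized geometric
scan of the bracket locates the first sign change before Brent runs.
The forward value is strictly increasing in `f` whenever `C_A` is
non-decreasing on `[0, T]`, which guarantees a unique root; for inputs
that decay well before `T` the map can lose monotonicity at very large
`K` (the forward value tends to `λ·C_A(T)` as `K → ∞`), and taking the
*first* crossing returns the physically meaningful branch.  A tissue
concentration above the ceiling attainable for the given curve raises a
non-identifiability error naming that ceiling; flagged rows do not stop
the batch pipeline.

**Degenerate inputs.**  Zero tissue concentration inverts to zero flow;
an identically zero arterial curve with positive uptake is an error; a
decapitation time more than one sampling interval past the last
arterial sample is rejected (within one interval the last concentration
is held constant).

## Statistics

Group summaries are mean ± SEM with SEM = sample SD (n−1 denominator)
over √n.  Hemodynamic-style comparisons use classical one-way ANOVA
(`scipy.stats.f_oneway`).  The primary flow analysis is a per-region
2×2 strain × treatment ANOVA (statsmodels OLS, type-II sums of squares —
identical to type I/III when balanced, the documented choice otherwise)
followed by Tukey HSD over the four cell means.  Tukey p-values use the
exact studentized-range distribution with Tukey–Kramer standard errors;
the expensive critical-value quantile is cached per (k, df, α).  A
statsmodels-free cross-check against `scipy.stats.tukey_hsd` is part of
the test suite.  No additional multiple-testing correction is applied
across the four regions, matching the original analysis; a secondary
group × region two-way layout is available behind the
`stats.layout: group_by_region` config flag.  Western-blot densitometry
is normalized per animal as phospho/total before the same 2×2 analysis
(one result per marker).

With all-zero within-group variance the one-way ANOVA reports the
`p → 0` limit (unequal means) or `p = 1` (identical data) with an
explicit degenerate-data warning instead of NaN.

## The synthetic generator

The generator emulates the study's design: 2 strains × 2 treatments ×
8 animals, four regions, arterial sampling every 3 s for 60 s, eight
standards log-spaced over 40–1069 nCi/g, eight density readings per
region.  Per animal, true regional flows are drawn from
`Normal(group mean, cv·mean)` truncated at zero; the tissue
concentration is computed by the forward model from the *recorded*
(noisy) arterial curve, exactly as a real measured input function
enters the real analysis — so with all noise off the full pipeline
recovers truth to numerical tolerance, and the noiseless identity test
isolates kinetic/calibration defects from sampling noise.

Choices where the experiment is silent, fixed once and documented:

* **Absolute flows.**  Only the relative group structure is
  reported by the study (cortex +32%, hippocampus +15% in
  vehicle-treated mutants; treatment restores mutants toward control,
  with no significant effect in controls).  Control-vehicle means are
  set to plausible isoflurane-anesthetized young-rat values — cortex
  1.10, hippocampus 0.95, cerebellum 1.00, pons 0.85 ml·g⁻¹·min⁻¹ —
  and the other groups are defined by ratios: mutant-vehicle
  1.32/1.15/1.00/1.00, mutant-inhibitor restored to 1.00 (0.97 in
  cerebellum/pons), control-inhibitor 0.95 everywhere.
* **Arterial shape.**  A gamma-variate
  `C_A(t) = peak·(t/rise)·e^{1−t/rise}` with peak 600 nCi/ml and rise
  time 60 s: the tracer is infused throughout the sampling minute, so
  the arterial concentration is still rising at decapitation.  A
  non-decreasing input also guarantees the monotone forward map on
  which unique inversion rests; an input peaking mid-scan can make two
  flows produce the same tissue concentration, which is a genuine
  physical non-identifiability, not a solver artifact.
* **Noise.**  Between-animal flow cv 0.10 (the study shows only SEM
  bars, so this is an assumption, not an estimate), multiplicative
  log-normal arterial sampling noise cv 0.05, additive Gaussian OD
  noise sd 0.002 OD units (~2 nCi/g at the synthetic film response of
  0.001 OD per nCi/g).  The linear film response keeps the
  interpolating calibration exact so that calibration error never
  masks kinetic error in recovery tests.
* **Seeding.**  Each animal's stream is keyed by
  (study seed, group index, animal index), so enlarging a group never
  perturbs previously generated animals, and identical seeds give
  byte-identical output files.

What the generator does **not** emulate: film-exposure physics and
nonlinear film response, anatomical images or ROI segmentation,
within-region heterogeneity beyond i.i.d. reading noise, physiological
drift of flow during the minute, inter-animal differences in the input
function shape, and any pharmacokinetics of the inhibitor (treatment is
purely a group label).  Passing recovery tests therefore demonstrate
the correctness of the kinetic inversion, calibration plumbing and
statistics under the stated noise model — not robustness to the
unmodelled features of real autoradiograms.

## Problem sizes

The recovery checks run the full 32-animal pipeline over 200 seeded
replicates (≈26k flow inversions), the statistical calibration checks
use 2000 null replicates each, and the blot power check 500 replicates;
these sizes put Monte-Carlo error well inside the asserted bands while
keeping the whole suite a few minutes long on one core.

## Known limitations

* A single λ = 0.80 is applied to all regions; regional λ variation
  would bias flows proportionally.
* `m` is a pure convention here; if the original microdensitometer
  software used a non-unity constant, absolute (not relative) flows
  would scale accordingly.
* The OD→activity interpolation is piecewise linear; a curved film
  response between standards is not modelled.
* Very high flows on inputs that decay before decapitation are
  intrinsically weakly identified (the forward map flattens); the
  inversion reports the first-crossing branch and its residual.
* Unbalanced designs are handled with type-II sums of squares; heavily
  unbalanced or heteroscedastic data would warrant methods out of scope
  here (no mixed-effects modelling of region within animal).
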