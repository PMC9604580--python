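# Methods

## The measurement problem

Wave-intensity analysis (WIA) quantifies the waves travelling through an
artery from simultaneous signals measured at one location. The classical
formulation needs invasive pressure; the area-based variant used here
replaces pressure with the vessel cross-sectional area, so the whole
analysis can run on non-invasive CMR phase-contrast data: a cross-sectional
area trace A(t) and a mean velocity trace U(t) for one cardiac cycle in the
ascending aorta.

The net area-based wave intensity is the per-sample product

    dI[i] = dU[i] · dlnA[i],        dU[i] = U[i+1] − U[i],
                                    dlnA[i] = ln A[i+1] − ln A[i].

Its sign gives the net travel direction (positive = forward, away from the
heart); the sign of dlnA at the wave's peak classifies it as compression
(dlnA > 0) or expansion (dlnA < 0). Two forward waves carry the clinical
information targeted here: the **forward compression wave (FCW)** of early
systole (ventricular ejection; its peak tracks contractility) and the
**forward expansion wave (FEW)** of late systole (ventricular relaxation).

Per-sample *differences* — not time derivatives — are used throughout, so
dI magnitudes depend on the sampling interval; every result therefore
records the analysis `dt` as a mandatory provenance field, and the output
tables use the conventional scales (FCW/FEW peaks ×10⁻⁵ m/s, wave areas
×10⁻³ m, distensibility ×10⁻³ 1/mmHg).

## Wave speed and distensibility

During early systole, before reflected waves arrive, only forward waves
are present and the water-hammer relation makes U linear in lnA with slope
equal to the local wave speed c. `wave_speed_loop` fits that slope by
ordinary least squares over an early-systolic window; the window runs from
the first upward crossing of 5% of peak U to the first crossing of 50%
(defaults chosen so that, on synthetic beats, the window ends before
plausible reflection arrival). A negative slope is returned but flagged,
never silently dropped. At 30 ms sampling the 5–50% upstroke can contain
fewer than the 4 samples a slope fit needs; the beat model then extends
the window toward the velocity peak and flags `loop_window_extended`.

The Bramwell–Hill relation converts wave speed to aortic distensibility

    D = 1 / (ρ c²)

with blood density ρ = 1060 kg/m³ by default (configurable). D is stored
in 1/Pa and reported in 1/mmHg (1 mmHg = 133.322 Pa).

Given c, the net intensity separates exactly into forward/backward parts,

    dI± = ±(dU ± c·dlnA)² / (4c),

which sum to dI at machine precision; this identity is enforced by tests.
Cohort-level wave features are measured on the *net* curve; the separated
series are carried for audit and the conservation check.

## Beat pipeline

`WaveIntensityModel(signal, config).fit()` composes:
resample (piecewise-linear, uniform grid of nominal spacing `dt`) →
Savitzky–Golay smoothing → per-sample differences → ejection window →
loop wave speed → Bramwell–Hill → net intensity → separation → FCW/FEW
features. All intermediates stay on the results object.

Key parameters (defaults):

| parameter | default | why |
|---|---|---|
| analysis `dt` | 0.030 s | typical Cartesian CMR temporal resolution |
| smoothing window/order | 5 / 3 | gentle local-polynomial denoising that is exact on cubics; window 1 disables |
| loop window | 5%–50% of peak U | early systole, ahead of reflections |
| ρ | 1060 kg/m³ | standard blood density |
| wrap tolerance | 5% of baseline area | beats violating it are flagged (`cycle_wrap`), never silently fixed |

Feature extraction: wave regions are contiguous runs of dI > 0 delimited
by zero crossings, with one extra boundary inserted at the systolic
velocity peak — on an ideal forward-only beat dI = dU²/c never touches
zero, yet ejection and relaxation waves are distinct by definition on
either side of peak U; on noisy or reflected beats the inserted boundary
coincides with a near-zero sample and changes nothing material. The FCW is
the region whose maximum has dlnA > 0 and lies before peak U, the FEW the
one with dlnA < 0 after peak U; among multiple candidates the
largest-energy region wins (ties to the earliest), and regions carrying
< 1% of the cycle's total |dI| energy are treated as noise. Peaks are
region maxima; energies are trapezoidal integrals of dI·dt. A feature with
no qualifying region is *absent* (None), never zero.

Subjects whose velocity trace was computationally rectified (conduction
abnormality distorting the CMR velocity signal) keep their wave-intensity
features but are excluded from cohort wave-speed statistics — the
`adjusted` flag propagates from file header to result flag to the group
tests. The rectification procedure itself is out of scope; only the flag
and its exclusion rule are implemented.

## Synthetic data

No public dataset accompanies this analysis, so the generator builds beats
from the water-hammer characteristics themselves: a forward characteristic
velocity U_f(t) and a backward one U_b(t), each a sum of Gaussian bumps
(per-sample increments are then Gaussian-derivative pulses, which
integrate to zero and close the cycle), combined as

    U = U_f + U_b,        lnA = ln A0 + (U_f − U_b)/c_true.

Forward-only content therefore satisfies dU = c_true·dlnA *exactly* at any
sampling, making wave-speed recovery a sharp test. Construction runs on a
1 ms grid and is observed at the analysis `dt` (default 30 ms); exact
cycle closure is enforced by linearly detrending each characteristic to
zero endpoints, and a specification whose wavelets would need more than a
5%-of-peak endpoint correction is rejected. Measurement noise, when
requested, is added per observed sample (sd in mm² for A, m/s for U) —
i.e. at acquisition resolution, which is where CMR noise lives — rather
than on the fine physiological grid. Ground truth (c, D, FCW/FEW peak and
energy at the analysis dt) is computed from the noiseless construction.

The canonical ejection shape is a fast upstroke bump plus a wider delayed
decay bump (amplitude ratio 0.55), giving a steep acceleration (large FCW)
and a gentler deceleration; the resulting FEW/FCW peak ratio (~0.45) is a
property of this fixed shape and is larger than typically observed
clinically — the generator's FEW tracks its FCW rather than being an
independently distributed quantity. Recovery experiments use this shape at
a physiological velocity amplitude (peak U ≈ 1 m/s).

Cohorts emulate a four-group pulmonary-regurgitation severity structure
(none / mild 1–19% / moderate 20–39% / severe ≥ 40%). Per-group defaults
copy the published summary statistics of the repaired-ToF cohort this
analysis was designed around: group sizes 17/38/90/56; wave speed
3.9±0.7 / 4.7±1.1 / 4.9±1.6 / 5.8±1.5 m/s; FCW peak 10.5±9.7 / 4.7±4.4 /
4.3±3.4 / 4.0±4.1 ×10⁻⁵ m/s; demographics, ventricular volumes and the
per-group fractions of rectified-velocity subjects (9/17, 16/38, 52/90,
33/56). Draws are truncated normals (clip bounds in the code); because
wave intensity is quadratic in the wavelet amplitude, the per-subject
amplitude is solved in closed form so the analytic FCW peak equals the
drawn target at that subject's heart rate and wave speed. Everything is
reproducible from the cohort seed.

What the generator does **not** emulate: reflected-wave inventories of
real aortas (cohort beats are forward-only by default), beat-to-beat
variability and ensemble averaging, out-of-plane motion or segmentation
error, independently varying FEW magnitudes, and any physiological
coupling between PR fraction and aortic stiffness beyond the imposed
group means. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated group structure, not a claim about
ToF physiology.

## Cohort statistics

Group differences use the Kruskal–Wallis test (tie-corrected H,
chi-squared approximation) with Dunn's post hoc pairwise z-tests on mean
ranks; the post hoc family (6 pairs for 4 groups) is Bonferroni-adjusted,
and raw p-values are reported alongside since the appropriate adjustment
is a matter of convention. Categorical variables use Pearson's chi-squared
without continuity correction. Regression (univariate and multivariable
share one OLS code path) reports coefficients, two-sided p-values and R²;
collinear predictors raise an error naming the offending columns. The
canonical regression set mirrors the study: FCW peak on PR%, age, sex and
distensibility, each alone and jointly.

Power for the two-sided pooled-variance two-sample t-test uses the
noncentral t distribution with noncentrality δ = (μ₁−μ₂)/(σ_p·√(2/n)),
σ_p² = (s₁²+s₂²)/2, df = 2n−2; `required_n` inverts it by scanning n.
The published pilot comparisons (FCW 6.3 vs 2.1, sds 2.2/1.5, n = 7;
FEW 0.8 vs 0.3, sds 0.5/0.2, n = 18) both give ≈ 0.97 ≥ 0.90 at α = 0.05.

Derived indices are computed per subject and then averaged:
SV = (EDVi − ESVi)·BSA, EF = 100·(EDVi − ESVi)/EDVi,
CI = SV·HR/(1000·BSA). Group-mean identities on published tables are
approximate (means do not commute through products/ratios) and are checked
only where they hold under rounding. The same caveat applies to
distensibility: group-mean D is the mean of per-subject 1/(ρc²), which is
not 1/(ρc̄²).

PR bin edges: the verbal definitions of the moderate (20–39%) and severe
(>40%) bins leave [39, 40) unassigned; this package uses moderate = [20, 40)
and severe = ≥ 40.

## Numerical and scale choices

* Resampling uses `ceil(T/dt)+1` equally spaced points spanning the beat
  exactly, so endpoints are preserved and the effective spacing
  (recorded on the result) is `T/ceil(T/dt) ≤ dt`.
* Problem sizes in the test-suite and acceptance script — 50 recovery
  beats, 1000 conservation series, 2000 null calibration replicates,
  100,000 Monte-Carlo power replicates, 100 replicate cohorts of 201
  subjects — were chosen so each estimate's Monte-Carlo error is well
  inside the tolerance it is checked against.
* The end-to-end direction check is reported as three fractions over 100
  replicate cohorts (monotone group means; significant Kruskal–Wallis;
  both). Under the default group parameters the mild and moderate wave
  speed distributions (4.7±1.1 vs 4.9±1.6 m/s) overlap enough that strict
  monotonicity of estimated group means holds in only ~3 of 4 replicates,
  and the rectified-velocity exclusion (which roughly halves the eligible
  n in every group) puts Kruskal–Wallis power near 0.9 rather than 1.
  These are properties of the emulated study conditions, not estimator
  defects; the monotone ordering of the *underlying* group means is exact
  by construction.

## Known limitations

* Single-beat analysis only: no ensemble averaging or arrhythmia
  rejection.
* The loop estimator assumes a reflection-free early systole; a backward
  wave arriving inside the window biases c (demonstrated and bounded in
  the tests), and the only defence is window placement.
* Per-sample intensities are dt-dependent; comparisons across datasets
  require a common analysis dt.
* Pressure-based WIA, pulmonary-artery analysis and reservoir-wave
  decomposition are out of scope.
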