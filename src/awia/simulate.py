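"""Synthetic aortic beats and cohorts with known wave-intensity truth.

No public dataset accompanies the analysis this package implements, so
every pipeline stage is exercised on simulated data built from the
water-hammer characteristics themselves. A beat is constructed from a
forward and a backward characteristic velocity, each a sum of Gaussian
bumps (whose per-sample increments are Gaussian-derivative pulses that
integrate to zero, closing the cycle):

    U(t)    = U_f(t) + U_b(t)
    lnA(t)  = ln A0 + (U_f(t) − U_b(t)) / c_true

so forward-only content satisfies dU = c_true·dlnA exactly, by
construction, at any sampling. Physiology is generated on a fine grid
(1 ms) and then observed on the coarse analysis grid (default 30 ms,
typical Cartesian CMR temporal resolution), optionally with additive
Gaussian measurement noise on the observed samples.

Ground truth (wave speed, distensibility, FCW/FEW peak and energy at the
analysis dt) is computed from the noiseless construction, so recovery of
these quantities by the estimation pipeline is a meaningful test.

Cohorts mimic a four-group pulmonary-regurgitation severity structure:
group sizes, regurgitant fractions, wave speeds, FCW-peak magnitudes,
demographics and ventricular volumes are drawn from truncated normal
distributions whose defaults copy the printed summary statistics of the
clinical cohort the analysis was designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpecError
from .signal import AorticSignal, increments, resample_uniform
from .wia import bramwell_hill, extract_features, net_wave_intensity

#: maximum allowed endpoint correction (fraction of the velocity peak)
#: before a wavelet inventory is declared not to close the cycle
CLOSURE_TOLERANCE = 0.05


@dataclass(frozen=True)
class Wavelet:
    """One Gaussian velocity bump on a characteristic."""

    center: float   # s
    width: float    # s (Gaussian sigma)
    amplitude: float  # m/s (peak velocity contribution)


@dataclass(frozen=True)
class BeatSpec:
    """Parameters of one synthetic beat.

    Areas are specified in mm² (file/interface convention); the generated
    signal is SI internally. ``dt_gen`` is the fine construction step,
    ``dt_out`` the observed (analysis) sampling interval.
    """

    c_true: float                       # m/s
    A0: float = 600.0                   # baseline area, mm²
    period: float = 0.78                # s
    dt_gen: float = 0.001               # s
    dt_out: float = 0.030               # s
    forward_wavelets: tuple[Wavelet, ...] = ()
    backward_wavelets: tuple[Wavelet, ...] = ()
    noise_sd_A: float = 0.0             # mm², per observed sample
    noise_sd_U: float = 0.0             # m/s, per observed sample
    seed: int = 0
    subject_id: str = "synthetic"
    adjusted: bool = False

    def __post_init__(self):
        if self.c_true <= 0:
            raise SpecError("c_true must be positive")
        if self.A0 <= 0:
            raise SpecError("baseline area must be positive")
        if self.period <= 0:
            raise SpecError("period must be positive")
        if self.dt_gen > self.period / 100:
            raise SpecError("dt_gen must be <= period/100")
        for w in (*self.forward_wavelets, *self.backward_wavelets):
            if w.width <= 0:
                raise SpecError("wavelet widths must be positive")
        if self.noise_sd_A < 0 or self.noise_sd_U < 0:
            raise SpecError("noise sds must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What the pipeline should recover from a noiseless beat."""

    c_true: float               # m/s
    D_true_mmhg: float          # 1/mmHg
    fcw_peak: float | None      # m/s at the analysis dt
    fcw_energy: float | None    # m
    few_peak: float | None
    few_energy: float | None
    dt: float                   # analysis dt the peaks refer to
    forward_wavelets: tuple[Wavelet, ...] = ()
    backward_wavelets: tuple[Wavelet, ...] = ()


def default_forward_shape(period: float, amplitude: float) -> tuple[Wavelet, ...]:
    """Canonical systolic ejection shape: a fast upstroke bump plus a
    wider, delayed decay bump, giving a steep acceleration (large FCW)
    and a gentler late-systolic deceleration (smaller FEW)."""
    return (
        Wavelet(center=0.26 * period, width=0.085 * period, amplitude=amplitude),
        Wavelet(center=0.40 * period, width=0.16 * period,
                amplitude=0.55 * amplitude),
    )


def _characteristic(t: np.ndarray, wavelets: tuple[Wavelet, ...]) -> np.ndarray:
    """Sum of Gaussian bumps, linearly detrended to exact zero endpoints.

    The detrend enforces cycle closure (U and lnA return to baseline
    exactly); if the required correction is large the wavelets sit too
    close to the cycle edges and the spec is rejected.
    """
    u = np.zeros_like(t)
    for w in wavelets:
        u += w.amplitude * np.exp(-0.5 * ((t - w.center) / w.width) ** 2)
    if not wavelets:
        return u
    T = t[-1] - t[0]
    trend = u[0] + (u[-1] - u[0]) * (t - t[0]) / T
    peak = np.max(np.abs(u))
    if peak > 0 and np.max(np.abs([u[0], u[-1]])) > CLOSURE_TOLERANCE * peak:
        raise SpecError(
            "wavelet inventory does not close the cycle: endpoint level "
            f"{np.max(np.abs([u[0], u[-1]])) / peak:.3f} of peak exceeds "
            f"{CLOSURE_TOLERANCE}"
        )
    return u - trend


def simulate_beat(spec: BeatSpec) -> tuple[AorticSignal, GroundTruth]:
    """Generate one observed beat and its noiseless ground truth.

    Deterministic in ``spec`` (including its seed): the same spec always
    yields bitwise-identical output.
    """
    n_fine = int(round(spec.period / spec.dt_gen))
    t = np.linspace(0.0, spec.period, n_fine + 1)
    u_f = _characteristic(t, spec.forward_wavelets)
    u_b = _characteristic(t, spec.backward_wavelets)
    U = u_f + u_b
    lnA = np.log(spec.A0 * 1e-6) + (u_f - u_b) / spec.c_true
    fine = AorticSignal(
        subject_id=spec.subject_id,
        t=t,
        A=np.exp(lnA),
        U=U,
        dt_native=spec.dt_gen,
        adjusted=spec.adjusted,
    )
    observed = resample_uniform(fine, spec.dt_out)

    truth = _ground_truth(spec, observed)

    if spec.noise_sd_A > 0 or spec.noise_sd_U > 0:
        rng = np.random.default_rng(spec.seed)
        A = observed.A + rng.normal(0, spec.noise_sd_A * 1e-6, observed.n)
        U_obs = observed.U + rng.normal(0, spec.noise_sd_U, observed.n)
        A = np.maximum(A, 1e-8)  # keep lnA defined under extreme noise
        observed = replace(observed, A=A, U=U_obs)
    return observed, truth


def _ground_truth(spec: BeatSpec, noiseless: AorticSignal) -> GroundTruth:
    """FCW/FEW truth from per-sample differences of the exact construction
    observed at the analysis dt."""
    inc = increments(noiseless)
    dI = net_wave_intensity(inc)
    if np.max(noiseless.U) > 0:
        feats = extract_features(dI, inc, noiseless)
        fcw_peak, fcw_energy = feats.fcw_peak, feats.fcw_energy
        few_peak, few_energy = feats.few_peak, feats.few_energy
    else:
        fcw_peak = fcw_energy = few_peak = few_energy = None
    _, d_mmhg = bramwell_hill(spec.c_true)
    return GroundTruth(
        c_true=spec.c_true,
        D_true_mmhg=d_mmhg,
        fcw_peak=fcw_peak,
        fcw_energy=fcw_energy,
        few_peak=few_peak,
        few_energy=few_energy,
        dt=inc.dt,
        forward_wavelets=spec.forward_wavelets,
        backward_wavelets=spec.backward_wavelets,
    )


def amplitude_for_fcw_peak(
    target_peak: float,
    c_true: float,
    period: float = 0.78,
    dt_out: float = 0.030,
    A0: float = 600.0,
) -> float:
    """Forward-shape amplitude whose analytic FCW peak equals ``target_peak``.

    Wave intensity is quadratic in the wavelet amplitude (U and lnA are
    both linear in it), so one reference evaluation inverts exactly.
    """
    if target_peak <= 0:
        raise SpecError("target FCW peak must be positive")
    ref = BeatSpec(
        c_true=c_true,
        A0=A0,
        period=period,
        dt_out=dt_out,
        forward_wavelets=default_forward_shape(period, 1.0),
    )
    _, truth = simulate_beat(ref)
    if truth.fcw_peak is None or truth.fcw_peak <= 0:
        raise SpecError("reference beat has no forward compression wave")
    return float(np.sqrt(target_peak / truth.fcw_peak))


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class GroupSpec:
    """Distributional parameters of one PR-severity group.

    Means/sds mirror the summary-table convention: PR in %, wave speed in
    m/s, FCW peak on the ×10⁻⁵ m/s table scale, volumes indexed to BSA.
    """

    n: int
    pr_mean: float
    pr_sd: float
    pr_range: tuple[float, float]
    c_mean: float
    c_sd: float
    fcw_peak_mean_e5: float
    fcw_peak_sd_e5: float
    age_mean: float
    age_sd: float
    male_frac: float
    bsa_mean: float
    bsa_sd: float
    hr_mean: float
    hr_sd: float
    lv_edvi_mean: float
    lv_edvi_sd: float
    lv_esvi_mean: float
    lv_esvi_sd: float
    rv_edvi_mean: float
    rv_edvi_sd: float
    rv_esvi_mean: float
    rv_esvi_sd: float
    adjusted_frac: float

    def __post_init__(self):
        if self.n < 2:
            raise SpecError("need n >= 2 per group")
        for name in ("pr_sd", "c_sd", "fcw_peak_sd_e5", "age_sd", "bsa_sd",
                     "hr_sd", "lv_edvi_sd", "lv_esvi_sd", "rv_edvi_sd",
                     "rv_esvi_sd"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be non-negative")
        lo, hi = self.pr_range
        if not (lo <= hi):
            raise SpecError("invalid PR range")
        # a mean far outside its bin makes the truncated draw degenerate
        if self.pr_sd > 0 and not (
            lo - 4 * self.pr_sd <= self.pr_mean <= hi + 4 * self.pr_sd
        ):
            raise SpecError(
                f"PR mean {self.pr_mean} impossible to truncate into "
                f"[{lo}, {hi}]"
            )


@dataclass(frozen=True)
class CohortSpec:
    """A four-group severity-structured cohort specification."""

    groups: dict  # severity name -> GroupSpec, ordered none..severe
    seed: int = 0
    dt_out: float = 0.030
    noise_sd_A: float = 0.0   # mm²
    noise_sd_U: float = 0.0   # m/s

    def __post_init__(self):
        if not self.groups:
            raise SpecError("cohort needs at least one group")


SEVERITY_ORDER = ("none", "mild", "moderate", "severe")


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Cohort defaults copying the printed four-group summary statistics
    (demographics, volumes, wave speed, FCW peak) of the repaired-ToF
    cohort, including the per-group counts of rectified-velocity subjects."""
    groups = {
        "none": GroupSpec(
            n=17, pr_mean=0.0, pr_sd=0.0, pr_range=(0.0, 0.0),
            c_mean=3.9, c_sd=0.7, fcw_peak_mean_e5=10.5, fcw_peak_sd_e5=9.7,
            age_mean=17, age_sd=5, male_frac=7 / 17,
            bsa_mean=1.7, bsa_sd=0.3, hr_mean=75, hr_sd=10,
            lv_edvi_mean=73, lv_edvi_sd=12, lv_esvi_mean=25, lv_esvi_sd=8,
            rv_edvi_mean=88, rv_edvi_sd=17, rv_esvi_mean=38, rv_esvi_sd=14,
            adjusted_frac=9 / 17,
        ),
        "mild": GroupSpec(
            n=38, pr_mean=9, pr_sd=6, pr_range=(0.5, 19.9),
            c_mean=4.7, c_sd=1.1, fcw_peak_mean_e5=4.7, fcw_peak_sd_e5=4.4,
            age_mean=16, age_sd=10, male_frac=24 / 38,
            bsa_mean=1.5, bsa_sd=0.5, hr_mean=78, hr_sd=5,
            lv_edvi_mean=75, lv_edvi_sd=11, lv_esvi_mean=28, lv_esvi_sd=10,
            rv_edvi_mean=98, rv_edvi_sd=26, rv_esvi_mean=43, rv_esvi_sd=15,
            adjusted_frac=16 / 38,
        ),
        "moderate": GroupSpec(
            n=90, pr_mean=30, pr_sd=5, pr_range=(20.0, 39.9),
            c_mean=4.9, c_sd=1.6, fcw_peak_mean_e5=4.3, fcw_peak_sd_e5=3.4,
            age_mean=15, age_sd=9, male_frac=55 / 90,
            bsa_mean=1.5, bsa_sd=0.4, hr_mean=80, hr_sd=13,
            lv_edvi_mean=72, lv_edvi_sd=12, lv_esvi_mean=26, lv_esvi_sd=7,
            rv_edvi_mean=112, rv_edvi_sd=35, rv_esvi_mean=49, rv_esvi_sd=24,
            adjusted_frac=52 / 90,
        ),
        "severe": GroupSpec(
            n=56, pr_mean=49, pr_sd=6, pr_range=(40.0, 100.0),
            c_mean=5.8, c_sd=1.5, fcw_peak_mean_e5=4.0, fcw_peak_sd_e5=4.1,
            age_mean=14, age_sd=6, male_frac=43 / 56,
            bsa_mean=1.4, bsa_sd=0.4, hr_mean=79, hr_sd=3,
            lv_edvi_mean=73, lv_edvi_sd=17, lv_esvi_mean=30, lv_esvi_sd=9,
            rv_edvi_mean=154, rv_edvi_sd=35, rv_esvi_mean=73, rv_esvi_sd=27,
            adjusted_frac=33 / 56,
        ),
    }
    return CohortSpec(groups=groups, seed=seed, **overrides)


def _tnorm(rng, mean, sd, lo, hi, size=None):
    """Truncated-normal draw; degenerates to the clipped mean when sd=0."""
    if sd == 0:
        val = np.clip(mean, lo, hi)
        return np.full(size, val) if size is not None else float(val)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                               size=size, random_state=rng)


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated cohort: subject table, per-subject beats, ground truth."""

    table: pd.DataFrame
    signals: dict = field(default_factory=dict)     # subject_id -> AorticSignal
    truths: dict = field(default_factory=dict)      # subject_id -> GroundTruth
    spec: CohortSpec | None = None


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw per-subject parameters and generate each subject's beat.

    Group-level wave speed and FCW-peak targets are drawn from truncated
    normals; forward-wavelet amplitudes are solved per subject so the
    analytic FCW peak equals the drawn target at that subject's heart rate
    and wave speed. Fully reproducible from ``spec.seed``.
    """
    from .cohort import derived_indices, pr_group  # local: avoid cycle

    rng = np.random.default_rng(spec.seed)
    rows = []
    signals: dict[str, AorticSignal] = {}
    truths: dict[str, GroundTruth] = {}
    sid = 0
    for severity in [g for g in SEVERITY_ORDER if g in spec.groups] + [
        g for g in spec.groups if g not in SEVERITY_ORDER
    ]:
        g = spec.groups[severity]
        pr = _tnorm(rng, g.pr_mean, g.pr_sd, *g.pr_range, size=g.n)
        c = _tnorm(rng, g.c_mean, g.c_sd, 1.5, 12.0, size=g.n)
        fcw_target = _tnorm(rng, g.fcw_peak_mean_e5, g.fcw_peak_sd_e5,
                            0.3, 80.0, size=g.n) * 1e-5
        age = _tnorm(rng, g.age_mean, g.age_sd, 1.0, 70.0, size=g.n)
        bsa = _tnorm(rng, g.bsa_mean, g.bsa_sd, 0.5, 2.6, size=g.n)
        hr = _tnorm(rng, g.hr_mean, g.hr_sd, 40.0, 140.0, size=g.n)
        lv_edvi = _tnorm(rng, g.lv_edvi_mean, g.lv_edvi_sd, 20, 250, size=g.n)
        lv_esvi = np.minimum(
            _tnorm(rng, g.lv_esvi_mean, g.lv_esvi_sd, 5, 200, size=g.n),
            0.95 * lv_edvi,
        )
        rv_edvi = _tnorm(rng, g.rv_edvi_mean, g.rv_edvi_sd, 20, 350, size=g.n)
        rv_esvi = np.minimum(
            _tnorm(rng, g.rv_esvi_mean, g.rv_esvi_sd, 5, 300, size=g.n),
            0.95 * rv_edvi,
        )
        male = rng.random(g.n) < g.male_frac
        adjusted = rng.random(g.n) < g.adjusted_frac
        beat_seeds = rng.integers(0, 2**31 - 1, size=g.n)

        for k in range(g.n):
            subject_id = f"S{sid:04d}"
            sid += 1
            period = 60.0 / hr[k]
            amp = amplitude_for_fcw_peak(
                fcw_target[k], c[k], period=period, dt_out=spec.dt_out
            )
            bspec = BeatSpec(
                c_true=float(c[k]),
                period=period,
                dt_out=spec.dt_out,
                forward_wavelets=default_forward_shape(period, amp),
                noise_sd_A=spec.noise_sd_A,
                noise_sd_U=spec.noise_sd_U,
                seed=int(beat_seeds[k]),
                subject_id=subject_id,
                adjusted=bool(adjusted[k]),
            )
            sig, truth = simulate_beat(bspec)
            signals[subject_id] = sig
            truths[subject_id] = truth
            sv, ef, ci = derived_indices(
                float(lv_edvi[k]), float(lv_esvi[k]), float(bsa[k]), float(hr[k])
            )
            rows.append(
                {
                    "subject_id": subject_id,
                    "severity": pr_group(float(pr[k])),
                    "age": float(age[k]),
                    "sex": "M" if male[k] else "F",
                    "BSA": float(bsa[k]),
                    "HR": float(hr[k]),
                    "PR_pct": float(pr[k]),
                    "lv_edvi": float(lv_edvi[k]),
                    "lv_esvi": float(lv_esvi[k]),
                    "rv_edvi": float(rv_edvi[k]),
                    "rv_esvi": float(rv_esvi[k]),
                    "lv_sv": sv,
                    "lv_ef": ef,
                    "lv_ci": ci,
                    "adjusted": bool(adjusted[k]),
                    "c_true": float(c[k]),
                    "fcw_peak_true_e5": (
                        truth.fcw_peak * 1e5 if truth.fcw_peak else np.nan
                    ),
                }
            )
    table = pd.DataFrame(rows)
    return SimulatedCohort(table=table, signals=signals, truths=truths, spec=spec)
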