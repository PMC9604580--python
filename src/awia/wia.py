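"""Area-based wave-intensity analysis of a single aortic beat.

The net wave intensity at one location is the per-sample product
``dI[i] = dU[i]·dlnA[i]`` of the velocity increment and the fractional
(log) area increment. Its sign gives the net travel direction (positive =
forward, away from the heart); the sign of dlnA classifies the wave as
compression (dlnA > 0) or expansion (dlnA < 0). Because only area and
velocity enter, the analysis is fully non-invasive and suited to CMR data.

Wave speed c is estimated from the lnA–U loop: during early systole, before
reflections arrive, only forward waves are present and U is linear in lnA
with slope c (water-hammer relation dU = ±c·dlnA). The Bramwell–Hill
equation D = 1/(ρc²) then converts c into aortic distensibility.

Given c, the net intensity separates exactly into forward and backward
components::

    dI_fwd = +(dU + c·dlnA)² / (4c)      (≥ 0)
    dI_bwd = −(dU − c·dlnA)² / (4c)      (≤ 0)

with dI_fwd + dI_bwd = dI_net identically.

The module follows a statsmodels-like shape: :class:`WaveIntensityModel`
is built from an :class:`~awia.signal.AorticSignal` plus configuration and
``fit()`` returns a :class:`WaveIntensityResults` carrying the estimates,
diagnostics, all intermediates and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DomainError,
    InsufficientDataError,
    PipelineError,
    SignalQualityError,
)
from .signal import (
    AorticSignal,
    IncrementSeries,
    ejection_window,
    increments,
    resample_uniform,
    smooth,
)

#: pascals per mmHg
MMHG_PA = 133.322

#: default blood density, kg/m³
RHO_BLOOD = 1060.0

#: wave regions carrying less than this fraction of the cycle's total
#: |dI| energy are discarded as noise
MIN_REGION_ENERGY_FRAC = 0.01


@dataclass(frozen=True)
class LoopFit:
    """lnA–U loop regression: wave speed estimate and fit quality."""

    c: float                # slope = wave speed, m/s
    r_squared: float
    n: int                  # samples in the window
    window: range
    negative: bool          # slope came out non-positive (quality flag)


def wave_speed_loop(lnA: np.ndarray, U: np.ndarray, window: range) -> LoopFit:
    """Wave speed as the least-squares slope of U against lnA over an
    early-systolic window.

    Returns the slope even when non-positive, with the ``negative`` quality
    flag set, so callers can report rather than silently drop the beat.
    """
    idx = np.asarray(list(window), dtype=int)
    if len(idx) < 4:
        raise InsufficientDataError(
            f"loop fit needs >= 4 samples, window has {len(idx)}"
        )
    x = np.asarray(lnA, dtype=float)[idx]
    y = np.asarray(U, dtype=float)[idx]
    if np.ptp(x) <= 1e-15:
        raise DomainError("lnA is constant over the window; slope undefined")
    res = stats.linregress(x, y)
    c = float(res.slope)
    return LoopFit(
        c=c,
        r_squared=float(res.rvalue**2),
        n=len(idx),
        window=window,
        negative=c <= 0,
    )


def bramwell_hill(c: float, rho: float = RHO_BLOOD) -> tuple[float, float]:
    """Distensibility from wave speed: D = 1/(ρc²).

    Returns ``(D_per_Pa, D_per_mmHg)``.
    """
    if c <= 0:
        raise DomainError("wave speed must be positive")
    if rho <= 0:
        raise DomainError("blood density must be positive")
    d_pa = 1.0 / (rho * c * c)
    return d_pa, d_pa * MMHG_PA


def wave_speed_from_distensibility(d_pa: float, rho: float = RHO_BLOOD) -> float:
    """Inverse Bramwell–Hill: c = 1/sqrt(ρD)."""
    if d_pa <= 0 or rho <= 0:
        raise DomainError("distensibility and density must be positive")
    return 1.0 / np.sqrt(rho * d_pa)


def net_wave_intensity(inc: IncrementSeries) -> np.ndarray:
    """Net area-based wave intensity dI[i] = dU[i]·dlnA[i], units m/s."""
    return inc.dU * inc.dlnA


def separate_waves(
    inc: IncrementSeries, c: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split the net intensity into forward (≥0) and backward (≤0) parts.

    Uses the water-hammer characteristics at wave speed ``c``; the parts
    sum to the net intensity at machine precision.
    """
    if c <= 0:
        raise DomainError("wave speed must be positive for separation")
    fwd = (inc.dU + c * inc.dlnA) ** 2 / (4.0 * c)
    bwd = -((inc.dU - c * inc.dlnA) ** 2) / (4.0 * c)
    return fwd, bwd


@dataclass(frozen=True)
class WaveLabel:
    """One identified wave: direction, type, extent and magnitude."""

    direction: str          # "forward" | "backward"
    wave_type: str          # "compression" | "expansion"
    span: tuple[int, int]   # [start, stop) indices into the increment series
    peak: float             # max |dI_net| within the span, m/s
    energy: float           # trapezoidal ∫ dI_net dt over the span, m


@dataclass(frozen=True)
class WaveFeatures:
    """FCW/FEW features measured from the net wave-intensity curve."""

    fcw: WaveLabel | None
    few: WaveLabel | None

    @property
    def fcw_peak(self) -> float | None:
        return self.fcw.peak if self.fcw else None

    @property
    def fcw_energy(self) -> float | None:
        return self.fcw.energy if self.fcw else None

    @property
    def few_peak(self) -> float | None:
        return self.few.peak if self.few else None

    @property
    def few_energy(self) -> float | None:
        return self.few.energy if self.few else None


def _positive_regions(
    dI: np.ndarray, split_at: int | None = None
) -> list[tuple[int, int]]:
    """Contiguous runs of dI > 0 as [start, stop) index pairs.

    ``split_at`` inserts an extra boundary (used at the systolic velocity
    peak: on an ideal forward-only beat dI = dU²/c never crosses zero, yet
    the ejection and relaxation waves are distinct by definition on either
    side of peak U)."""
    pos = dI > 0
    if not np.any(pos):
        return []
    edges = np.diff(pos.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if pos[0]:
        starts.insert(0, 0)
    if pos[-1]:
        stops.append(len(dI))
    regions = []
    for start, stop in zip(starts, stops):
        if split_at is not None and start < split_at < stop:
            regions.append((start, split_at))
            regions.append((split_at, stop))
        else:
            regions.append((start, stop))
    return regions


def extract_features(
    dI_net: np.ndarray,
    inc: IncrementSeries,
    signal: AorticSignal,
) -> WaveFeatures:
    """Measure FCW and FEW peaks and energies from the net dI curve.

    The forward compression wave (FCW, ventricular ejection) is the
    contiguous dI > 0 region whose maximum has dlnA > 0 and lies before the
    systolic velocity peak; the forward expansion wave (FEW, ventricular
    relaxation) is the dI > 0 region whose maximum has dlnA < 0 and lies
    after it. Region boundaries are the zero crossings of dI. Peaks are the
    region maxima; energies are trapezoidal integrals of dI·dt over the
    region. Regions carrying < 1% of the cycle's total |dI| energy are
    treated as noise. A feature with no qualifying region is reported as
    absent (None), never as zero. Among multiple candidates the
    largest-energy region wins; ties go to the earliest.
    """
    ipeak = int(np.argmax(signal.U))
    t_peak = float(signal.t[ipeak])
    regions = _positive_regions(dI_net, split_at=ipeak)
    total = float(np.trapezoid(np.abs(dI_net), dx=inc.dt))

    candidates: list[WaveLabel] = []
    for start, stop in regions:
        seg = dI_net[start:stop]
        imax = start + int(np.argmax(seg))
        energy = float(np.trapezoid(seg, dx=inc.dt))
        if total > 0 and energy < MIN_REGION_ENERGY_FRAC * total:
            continue
        wave_type = "compression" if inc.dlnA[imax] > 0 else "expansion"
        candidates.append(
            WaveLabel(
                direction="forward",
                wave_type=wave_type,
                span=(start, stop),
                peak=float(dI_net[imax]),
                energy=energy,
            )
        )

    def best(cands: list[WaveLabel]) -> WaveLabel | None:
        if not cands:
            return None
        # largest energy; earliest span breaks ties
        return min(cands, key=lambda w: (-w.energy, w.span[0]))

    fcw = best(
        [
            w
            for w in candidates
            if w.wave_type == "compression"
            and inc.t_mid[w.span[0] + int(np.argmax(dI_net[slice(*w.span)]))]
            < t_peak
        ]
    )
    few = best(
        [
            w
            for w in candidates
            if w.wave_type == "expansion"
            and inc.t_mid[w.span[0] + int(np.argmax(dI_net[slice(*w.span)]))]
            > t_peak
        ]
    )
    return WaveFeatures(fcw=fcw, few=few)


# ---------------------------------------------------------------------------
# Model / Results


@dataclass(frozen=True)
class WiaConfig:
    """Configuration of the beat-analysis pipeline.

    dt is the analysis sampling interval (default 30 ms, typical Cartesian
    CMR temporal resolution); per-sample wave-intensity magnitudes depend
    on it, so every result records the dt used. Smoothing is a
    Savitzky–Golay filter applied before differencing (window=1 disables).
    """

    dt: float = 0.030                  # s
    smooth_window: int = 5             # odd sample count; 1 = off
    smooth_order: int = 3
    onset_frac: float = 0.05           # loop window start, fraction of peak U
    end_frac: float = 0.50             # loop window end
    rho: float = RHO_BLOOD             # kg/m³
    min_loop_samples: int = 4


class WaveIntensityModel:
    """Beat-level wave-intensity model: signal in, estimates out.

    Composes the pipeline resample → smooth → increments → ejection window
    → loop wave speed → Bramwell–Hill → net intensity → separation →
    FCW/FEW features. All intermediates are retained on the results object
    for audit.
    """

    def __init__(self, signal: AorticSignal, config: WiaConfig | None = None):
        self.signal = signal
        self.config = config or WiaConfig()

    def fit(self) -> "WaveIntensityResults":
        cfg = self.config
        flags: list[str] = []

        def stage(name, fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:  # annotate failures with the stage name
                raise PipelineError(name, str(exc)) from exc

        if not self.signal.cycle_closed:
            flags.append("cycle_wrap")

        resampled = stage("resample", resample_uniform, self.signal, cfg.dt)
        smoothed = stage(
            "smooth", smooth, resampled, cfg.smooth_window, cfg.smooth_order
        )
        inc = stage("increments", increments, smoothed)
        try:
            window = ejection_window(smoothed, cfg.onset_frac, cfg.end_frac)
        except SignalQualityError:
            # flat or inverted velocity: no wave speed, but wave-intensity
            # features (here: their absence) are still reportable
            window = None
            flags.append("no_systolic_upstroke")

        loop = None
        if window is not None:
            # At ~30 ms sampling the 5–50% upstroke can span fewer samples
            # than a slope fit needs; extend toward the velocity peak and
            # flag it.
            if len(window) < cfg.min_loop_samples:
                ipeak = int(np.argmax(smoothed.U))
                stop = min(
                    max(window.start + cfg.min_loop_samples, window.stop),
                    max(ipeak + 1, window.start + cfg.min_loop_samples),
                )
                window = range(window.start, stop)
                flags.append("loop_window_extended")
            loop = stage(
                "wave_speed", wave_speed_loop, smoothed.lnA, smoothed.U, window
            )
        else:
            loop = LoopFit(
                c=float("nan"),
                r_squared=float("nan"),
                n=0,
                window=range(0, 0),
                negative=True,
            )
        if window is not None and loop.negative:
            flags.append("negative_wave_speed")
        if loop.negative:
            d_pa = d_mmhg = np.nan
        else:
            d_pa, d_mmhg = stage("bramwell_hill", bramwell_hill, loop.c, cfg.rho)

        dI_net = stage("net_intensity", net_wave_intensity, inc)
        if loop.negative:
            dI_fwd = np.full_like(dI_net, np.nan)
            dI_bwd = np.full_like(dI_net, np.nan)
        else:
            dI_fwd, dI_bwd = stage("separation", separate_waves, inc, loop.c)
        features = stage("features", extract_features, dI_net, inc, smoothed)

        if self.signal.adjusted:
            # rectified velocity traces: keep wave-intensity features but
            # exclude c and D from cohort wave-speed statistics
            flags.append("wave_speed_excluded_adjusted")

        return WaveIntensityResults(
            model=self,
            resampled=resampled,
            smoothed=smoothed,
            increments=inc,
            loop=loop,
            dI_net=dI_net,
            dI_fwd=dI_fwd,
            dI_bwd=dI_bwd,
            D_pa=float(d_pa),
            D_mmhg=float(d_mmhg),
            features=features,
            flags=tuple(flags),
        )


def analyse_beat(
    signal: AorticSignal, config: WiaConfig | None = None
) -> "WaveIntensityResults":
    """Convenience wrapper: ``WaveIntensityModel(signal, config).fit()``."""
    return WaveIntensityModel(signal, config).fit()


@dataclass(frozen=True)
class WaveIntensityResults:
    """Fitted beat: wave speed, distensibility, wave features, audit trail."""

    model: WaveIntensityModel
    resampled: AorticSignal
    smoothed: AorticSignal
    increments: IncrementSeries
    loop: LoopFit
    dI_net: np.ndarray
    dI_fwd: np.ndarray
    dI_bwd: np.ndarray
    D_pa: float
    D_mmhg: float
    features: WaveFeatures
    flags: tuple[str, ...] = field(default_factory=tuple)

    # -- headline quantities ---------------------------------------------

    @property
    def c(self) -> float:
        """Wave speed, m/s (loop slope)."""
        return self.loop.c

    @property
    def dt(self) -> float:
        """Analysis sampling interval actually used, s."""
        return self.increments.dt

    @property
    def wave_speed_eligible(self) -> bool:
        """Whether c/D may enter cohort wave-speed statistics."""
        return (
            "wave_speed_excluded_adjusted" not in self.flags
            and "negative_wave_speed" not in self.flags
            and "no_systolic_upstroke" not in self.flags
            and np.isfinite(self.loop.c)
        )

    def to_row(self) -> dict:
        """Flat record on the conventional table scales
        (D ×10⁻³ 1/mmHg, peaks ×10⁻⁵ m/s, areas ×10⁻³ m)."""
        f = self.features

        def scaled(x, k):
            return None if x is None else x * k

        return {
            "subject_id": self.model.signal.subject_id,
            "dt": self.dt,
            "c_m_per_s": self.c,
            "D_e-3_per_mmHg": self.D_mmhg * 1e3,
            "fcw_peak_e-5_m_per_s": scaled(f.fcw_peak, 1e5),
            "fcw_area_e-3_m": scaled(f.fcw_energy, 1e3),
            "few_peak_e-5_m_per_s": scaled(f.few_peak, 1e5),
            "few_area_e-3_m": scaled(f.few_energy, 1e3),
            "flags": ";".join(self.flags),
        }

    def summary(self) -> str:
        f = self.features
        lines = [
            "Wave-Intensity Analysis Results",
            "=" * 46,
            f"subject:            {self.model.signal.subject_id}",
            f"analysis dt:        {self.dt * 1e3:.1f} ms",
            f"wave speed c:       {self.c:.3f} m/s  (R²={self.loop.r_squared:.4f},"
            f" n={self.loop.n})",
            f"distensibility D:   {self.D_mmhg * 1e3:.3f} ×10⁻³ 1/mmHg",
            f"FCW peak:           "
            + (f"{f.fcw_peak * 1e5:.3f} ×10⁻⁵ m/s" if f.fcw else "absent"),
            f"FCW energy:         "
            + (f"{f.fcw_energy * 1e3:.3f} ×10⁻³ m" if f.fcw else "absent"),
            f"FEW peak:           "
            + (f"{f.few_peak * 1e5:.3f} ×10⁻⁵ m/s" if f.few else "absent"),
            f"FEW energy:         "
            + (f"{f.few_energy * 1e3:.3f} ×10⁻³ m" if f.few else "absent"),
            f"flags:              {', '.join(self.flags) or 'none'}",
        ]
        return "\n".join(lines)
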