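"""Aortic waveform containers and pre-processing.

One :class:`AorticSignal` holds a single cardiac cycle of ascending-aortic
cross-sectional area A(t) and mean velocity U(t), as extracted from
phase-contrast CMR flow data. Internally everything is SI (m², m/s, s);
file readers convert mm² on load. The pre-processing chain —
uniform resampling, Savitzky–Golay smoothing, per-sample differencing,
early-systolic window delimitation — prepares a beat for area-based
wave-intensity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    ConfigError,
    DomainError,
    ResolutionError,
    SignalQualityError,
)

#: fractional area mismatch between first and last sample above which a
#: beat is flagged as not closing the cardiac cycle
WRAP_TOLERANCE = 0.05


@dataclass(frozen=True)
class AorticSignal:
    """A single sampled beat of aortic area and velocity.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    t : ndarray
        Sample times in seconds from cycle onset, strictly increasing.
    A : ndarray
        Cross-sectional area in m², strictly positive (lnA must exist).
    U : ndarray
        Mean velocity in m/s.
    dt_native : float or None
        Native sampling interval in seconds (None if irregular/unknown).
    adjusted : bool
        True when the velocity trace was computationally rectified during
        post-processing (conduction-abnormality cases). Such beats are
        excluded from cohort wave-speed statistics but kept for
        wave-intensity statistics.
    """

    subject_id: str
    t: np.ndarray
    A: np.ndarray
    U: np.ndarray
    dt_native: float | None = None
    adjusted: bool = False

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        A = np.asarray(self.A, dtype=float)
        U = np.asarray(self.U, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "U", U)
        if not (len(t) == len(A) == len(U)):
            raise DomainError("t, A, U must have equal length")
        if len(t) < 8:
            raise DomainError(f"need at least 8 samples per beat, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise DomainError("time grid must be strictly increasing")
        if not np.all(A > 0):
            raise DomainError("area must be strictly positive (lnA undefined)")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(U))):
            raise DomainError("non-finite sample values")

    # -- derived geometry -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def period(self) -> float:
        """Cycle duration covered by the samples, seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def lnA(self) -> np.ndarray:
        return np.log(self.A)

    @property
    def cycle_closed(self) -> bool:
        """True when the beat returns to its baseline area within the
        wrap tolerance (|A_end − A_start|/A_start ≤ 5%)."""
        return bool(abs(self.A[-1] - self.A[0]) / self.A[0] <= WRAP_TOLERANCE)

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.t)
        return bool(np.max(d) - np.min(d) <= rtol * np.mean(d))


@dataclass(frozen=True)
class IncrementSeries:
    """Per-sample forward differences of a uniformly sampled beat.

    ``dU[i] = U[i+1] − U[i]`` (m/s) and ``dlnA[i] = ln A[i+1] − ln A[i]``
    (dimensionless), located at midpoint times ``t_mid``. Per-sample
    differences — not time-derivatives — are the convention throughout;
    wave-intensity magnitudes therefore depend on the sampling interval
    ``dt``, which every downstream result records.
    """

    t_mid: np.ndarray
    dU: np.ndarray
    dlnA: np.ndarray
    dt: float

    def __post_init__(self):
        if not (len(self.t_mid) == len(self.dU) == len(self.dlnA)):
            raise DomainError("increment arrays must have equal length")
        if self.dt <= 0:
            raise DomainError("dt must be positive")

    @property
    def n(self) -> int:
        return len(self.dU)


def resample_uniform(signal: AorticSignal, dt: float) -> AorticSignal:
    """Resample a beat onto a uniform grid of nominal spacing ``dt``.

    The grid has ``ceil(T/dt) + 1`` points spanning exactly
    ``[t0, t_end]`` (endpoints preserved), so the effective spacing is
    ``T / ceil(T/dt) ≤ dt``. A and U are interpolated piecewise-linearly.
    When the signal is already uniform at the requested spacing the grid
    coincides with the input and values are unchanged.
    """
    if dt <= 0:
        raise ConfigError("dt must be positive")
    T = signal.period
    if dt > T / 2:
        raise ResolutionError(
            f"dt={dt} s exceeds half the cycle length ({T} s)"
        )
    n_int = int(np.ceil(T / dt - 1e-9))
    grid = np.linspace(signal.t[0], signal.t[-1], n_int + 1)
    A = np.interp(grid, signal.t, signal.A)
    U = np.interp(grid, signal.t, signal.U)
    return replace(signal, t=grid, A=A, U=U, dt_native=T / n_int)


def smooth(signal: AorticSignal, window: int = 5, order: int = 3) -> AorticSignal:
    """Savitzky–Golay smoothing of A and U.

    Local least-squares polynomial fit of the given window/order; exact on
    polynomials up to ``order``. Endpoints use the polynomial fitted to the
    terminal window evaluated at the edge samples. ``window=1`` disables
    smoothing (identity).
    """
    if window % 2 == 0:
        raise ConfigError("smoothing window must be odd")
    if window == 1:
        return signal
    if order >= window:
        raise ConfigError("polynomial order must be < window")
    if window >= signal.n:
        raise ConfigError(
            f"window {window} must be smaller than series length {signal.n}"
        )
    A = savgol_filter(signal.A, window, order, mode="interp")
    U = savgol_filter(signal.U, window, order, mode="interp")
    A = np.maximum(A, 1e-12)  # smoothing must not produce non-physical area
    return replace(signal, A=A, U=U)


def increments(signal: AorticSignal) -> IncrementSeries:
    """Per-sample forward differences dU and dlnA on a uniform beat."""
    if not signal.is_uniform():
        raise ConfigError("increments require uniform sampling; resample first")
    dt = signal.period / (signal.n - 1)
    dU = np.diff(signal.U)
    dlnA = np.diff(signal.lnA)
    t_mid = 0.5 * (signal.t[:-1] + signal.t[1:])
    return IncrementSeries(t_mid=t_mid, dU=dU, dlnA=dlnA, dt=dt)


def ejection_window(
    signal: AorticSignal,
    onset_frac: float = 0.05,
    end_frac: float = 0.50,
) -> range:
    """Indices of the early-systolic upstroke used for the lnA–U loop fit.

    Runs from the first sample at or above ``onset_frac·max(U)`` to the
    first sample at or above ``end_frac·max(U)`` on the upstroke. The
    defaults (5%–50% of peak velocity) keep the window ahead of plausible
    reflected-wave arrival, where the forward-only assumption underlying
    loop-slope wave-speed estimation holds.
    """
    if not (0 < onset_frac < end_frac <= 1):
        raise ConfigError("require 0 < onset_frac < end_frac <= 1")
    U = signal.U
    umax = float(np.max(U))
    if umax <= 0:
        raise SignalQualityError("no positive systolic velocity peak")
    ipeak = int(np.argmax(U))
    onset_lvl = onset_frac * umax
    end_lvl = end_frac * umax
    above = np.nonzero(U[: ipeak + 1] >= onset_lvl)[0]
    if len(above) == 0:
        raise SignalQualityError("no upward crossing of the onset threshold")
    i0 = int(above[0])
    reach = np.nonzero(U[i0 : ipeak + 1] >= end_lvl)[0]
    if len(reach) == 0:
        raise SignalQualityError("upstroke never reaches the end threshold")
    i1 = i0 + int(reach[0])
    return range(i0, i1 + 1)
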