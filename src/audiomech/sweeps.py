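"""Frequency-sweep trial processing.

Detrending (single-pole DC removal), trial averaging, best-frequency
extraction through the linear time-to-frequency map of the sweep stimulus,
and displacement-gain estimation from mechanical sensitivity curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, lfilter

__all__ = [
    "SweepStimulus",
    "TuningPeak",
    "TuningResult",
    "SensitivityCurve",
    "DisplacementGainFit",
    "dc_remove",
    "average_trials",
    "best_frequency_from_sweep",
    "analyze_sweep_trial",
    "displacement_gain_from_sensitivities",
]


@dataclass(frozen=True)
class SweepStimulus:
    """Linear frequency sweep: ``f(t) = f_start + (f_end - f_start) * t / duration``.

    Forward sweeps run 1 -> 1000 Hz over 1 s; backward sweeps reverse the
    endpoints over the same duration.
    """

    f_start_hz: float = 1.0
    f_end_hz: float = 1000.0
    duration_s: float = 1.0
    amplitude: float = 1.0
    intensity_index: int = 1

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("sweep duration must be positive")
        if self.f_start_hz == self.f_end_hz:
            raise ValueError("sweep must change frequency (f_start != f_end)")
        if self.f_start_hz <= 0 or self.f_end_hz <= 0:
            raise ValueError("sweep frequencies must be positive")

    @property
    def direction(self) -> str:
        return "forward" if self.f_start_hz < self.f_end_hz else "backward"

    def frequency_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous stimulus frequency at time ``t`` (s)."""
        return self.f_start_hz + (self.f_end_hz - self.f_start_hz) * t / self.duration_s

    def phase_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Accumulated phase (rad) of the chirp at time ``t``."""
        rate = (self.f_end_hz - self.f_start_hz) / self.duration_s
        return 2.0 * math.pi * (self.f_start_hz * t + 0.5 * rate * t**2)

    def reversed(self) -> "SweepStimulus":
        return SweepStimulus(
            f_start_hz=self.f_end_hz,
            f_end_hz=self.f_start_hz,
            duration_s=self.duration_s,
            amplitude=self.amplitude,
            intensity_index=self.intensity_index,
        )


@dataclass(frozen=True)
class TuningPeak:
    """Envelope maximum of one sweep response mapped to stimulus frequency."""

    bf_hz: float
    t_peak_s: float
    no_peak: bool = False


@dataclass(frozen=True)
class TuningResult:
    """Per-trial mechanical and electrical best frequencies."""

    mechanical_bf_hz: float
    electrical_bf_hz: float
    intensity_index: int
    mechanical_peak_t_s: float
    electrical_peak_t_s: float


@dataclass(frozen=True)
class SensitivityCurve:
    """Mechanical sensitivity (peak displacement / stimulus magnitude) per intensity."""

    intensities: np.ndarray
    sensitivities: np.ndarray

    def __post_init__(self) -> None:
        intensities = np.asarray(self.intensities, dtype=float)
        sensitivities = np.asarray(self.sensitivities, dtype=float)
        object.__setattr__(self, "intensities", intensities)
        object.__setattr__(self, "sensitivities", sensitivities)
        if intensities.shape != sensitivities.shape:
            raise ValueError("intensities and sensitivities must align")
        if np.any(np.diff(intensities) <= 0):
            raise ValueError("intensities must be strictly increasing")
        if np.any(sensitivities <= 0) or not np.all(np.isfinite(sensitivities)):
            raise ValueError("sensitivities must be positive and finite")


@dataclass(frozen=True)
class DisplacementGainFit:
    """Three-parameter sigmoid fit to sensitivity vs log10(intensity).

    ``gain`` is the ratio of the fitted curve's maximal to minimal value over
    the tested intensity range. Fits with ``r_squared`` below the configured
    floor carry ``below_floor=True`` and should be excluded from summaries.
    """

    asymptote: float
    midpoint: float
    slope: float
    r_squared: float
    gain: float
    below_floor: bool
    r2_floor: float = 0.9


def dc_remove(signal: np.ndarray, dt: float, tau: float = 0.015) -> np.ndarray:
    """Single-pole high-pass: subtract an exponential moving average.

    The EMA pole is placed at ``exp(-dt / tau)`` so a unit-step input leaves a
    residual that decays as ``exp(-t / tau)`` exactly.
    """
    signal = np.asarray(signal, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tau <= dt:
        raise ValueError(f"tau ({tau}) must exceed the sample interval ({dt})")
    alpha = 1.0 - math.exp(-dt / tau)
    # EMA as an IIR filter starting from rest: a step input leaves a residual
    # decaying exactly as exp(-t / tau)
    ema = lfilter([alpha], [1.0, -(1.0 - alpha)], signal)
    return signal - ema


def average_trials(trials: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Point-wise mean of same-length trial traces (averaging precedes envelope work)."""
    stacked = np.asarray(trials, dtype=float)
    if stacked.ndim != 2:
        raise ValueError("expected a list of equal-length 1-D traces")
    return stacked.mean(axis=0)


def _envelope(response: np.ndarray, dt: float, smooth_s: float) -> np.ndarray:
    """Rectify, interpolate between local maxima, and smooth with a boxcar."""
    rect = np.abs(response)
    peaks, _ = find_peaks(rect)
    t = np.arange(rect.size) * dt
    if peaks.size >= 2:
        env = np.interp(t, t[peaks], rect[peaks])
    else:
        env = rect
    win = max(1, int(round(smooth_s / dt)))
    if win % 2 == 0:
        win += 1  # odd window keeps the smoother symmetric
    if win > 1:
        kernel = np.ones(win) / win
        env = np.convolve(env, kernel, mode="same")
    return env


def best_frequency_from_sweep(
    response: np.ndarray,
    dt: float,
    stimulus: SweepStimulus,
    smooth_s: float = 0.02,
) -> TuningPeak:
    """Locate the response-envelope maximum and map its time to stimulus frequency.

    The envelope is built from local maxima of the rectified trace with linear
    interpolation, then smoothed over ``smooth_s`` seconds. The envelope peak
    time ``t*`` maps to ``f(t*)`` through the sweep's linear frequency ramp.
    """
    response = np.asarray(response, dtype=float)
    if response.ndim != 1 or response.size < 3:
        raise ValueError("response must be a 1-D trace with at least 3 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    span = (response.size - 1) * dt
    if not math.isclose(span, stimulus.duration_s, rel_tol=0.05):
        raise ValueError(
            f"response span {span:.4f} s does not match stimulus duration "
            f"{stimulus.duration_s:.4f} s"
        )
    env = _envelope(response, dt, smooth_s)
    if not np.any(env > 0) or np.ptp(env) == 0:
        return TuningPeak(bf_hz=math.nan, t_peak_s=math.nan, no_peak=True)
    t_peak = float(np.argmax(env)) * dt
    bf = stimulus.f_start_hz + (
        stimulus.f_end_hz - stimulus.f_start_hz
    ) * t_peak / stimulus.duration_s
    return TuningPeak(bf_hz=float(bf), t_peak_s=t_peak, no_peak=False)


def analyze_sweep_trial(
    displacement: np.ndarray,
    cap: np.ndarray,
    dt: float,
    stimulus: SweepStimulus,
    tau: float = 0.015,
    smooth_s: float = 0.02,
) -> TuningResult:
    """DC-remove both traces, then extract mechanical and electrical best frequencies."""
    disp = dc_remove(displacement, dt, tau=tau)
    nerve = dc_remove(cap, dt, tau=tau)
    mech = best_frequency_from_sweep(disp, dt, stimulus, smooth_s=smooth_s)
    elec = best_frequency_from_sweep(nerve, dt, stimulus, smooth_s=smooth_s)
    return TuningResult(
        mechanical_bf_hz=mech.bf_hz,
        electrical_bf_hz=elec.bf_hz,
        intensity_index=stimulus.intensity_index,
        mechanical_peak_t_s=mech.t_peak_s,
        electrical_peak_t_s=elec.t_peak_s,
    )


def mechanical_sensitivity(displacement: np.ndarray, stimulus: SweepStimulus) -> float:
    """Ratio of maximal absolute flagellar displacement to stimulus magnitude."""
    if stimulus.amplitude <= 0:
        raise ValueError("stimulus amplitude must be positive for sensitivity")
    return float(np.max(np.abs(displacement)) / stimulus.amplitude)


def _sigmoid(x: np.ndarray, a: float, x0: float, b: float) -> np.ndarray:
    return a / (1.0 + np.exp(-(x - x0) / b))


def displacement_gain_from_sensitivities(
    curve: SensitivityCurve,
    r2_floor: float = 0.9,
) -> DisplacementGainFit:
    """Fit ``a / (1 + exp(-(x - x0)/b))`` to sensitivity vs log10(intensity).

    The displacement gain is the ratio of the maximal to minimal fitted value
    over the tested intensity range (the endpoints, for a monotone sigmoid).
    Near-constant input degenerates gracefully to gain 1.
    """
    x = np.log10(curve.intensities)
    y = curve.sensitivities
    if x.size < 5:
        raise ValueError("need at least 5 intensities for a sigmoid fit")

    rel_range = np.ptp(y) / np.max(y)
    if rel_range < 1e-9:
        return DisplacementGainFit(
            asymptote=float(np.mean(y)),
            midpoint=float(np.mean(x)),
            slope=1.0,
            r_squared=1.0,
            gain=1.0,
            below_floor=False,
            r2_floor=r2_floor,
        )

    span = np.ptp(x)
    p0 = (float(np.max(y)), float(np.mean(x)), span / 4.0)
    bounds = (
        [np.max(y) * 1e-3, x.min() - 5 * span, span * 1e-3],
        [np.max(y) * 1e3, x.max() + 5 * span, span * 10.0],
    )
    try:
        popt, _ = curve_fit(_sigmoid, x, y, p0=p0, bounds=bounds, maxfev=20000)
        fitted = _sigmoid(x, *popt)
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    except RuntimeError:
        popt = (float(np.mean(y)), float(np.mean(x)), span)
        r2 = -math.inf
    lo = float(_sigmoid(np.array([x.min()]), *popt)[0])
    hi = float(_sigmoid(np.array([x.max()]), *popt)[0])
    top, bottom = max(lo, hi), min(lo, hi)
    gain = top / bottom if bottom > 0 else math.inf
    return DisplacementGainFit(
        asymptote=float(popt[0]),
        midpoint=float(popt[1]),
        slope=float(popt[2]),
        r_squared=r2,
        gain=gain,
        below_floor=bool(r2 < r2_floor),
        r2_floor=r2_floor,
    )
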