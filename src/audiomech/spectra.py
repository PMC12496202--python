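"""Velocity amplitude spectra and the forced damped-harmonic-oscillator fit.

The fitted model is the velocity-amplitude resonance curve

    V(f) = A * f * f0^2 / sqrt((f0^2 - f^2)^2 + (f0 * f / Q)^2)

(the displacement Lorentzian times frequency), optionally with an additive
white noise floor. Free-fluctuation fits are restricted to 101-1000 Hz by
default because low-frequency recording noise dominates below 100 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import welch

from .synthetic import VelocityTrace

__all__ = [
    "AmplitudeSpectrum",
    "OscillatorFit",
    "RecoveryCheck",
    "compute_spectrum",
    "oscillator_velocity_model",
    "fit_oscillator",
    "check_recovery",
]

DEFAULT_FIT_BAND = (101.0, 1000.0)
DEFAULT_MAX_FREQUENCY = 1e4


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided velocity amplitude spectrum on a uniform frequency grid.

    Normalization: a pure sine of amplitude ``v0`` occupying a whole number of
    cycles produces a bin value of ``v0``; for broadband signals the bins are
    power-calibrated so that ``sum(bin^2) / 2`` equals the trace mean square.
    """

    frequencies_hz: np.ndarray
    amplitudes: np.ndarray  # m/s per bin

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "amplitudes", a)
        if f.shape != a.shape or f.ndim != 1:
            raise ValueError("frequency grid and amplitudes must be aligned 1-D arrays")
        if f.size < 2 or np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        steps = np.diff(f)
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("frequency grid must be uniform")
        if np.any(a < 0) or not np.all(np.isfinite(a)):
            raise ValueError("amplitudes must be finite and non-negative")

    @property
    def bin_width_hz(self) -> float:
        return float(self.frequencies_hz[1] - self.frequencies_hz[0])


@dataclass(frozen=True)
class OscillatorFit:
    """Best-fit resonance parameters from a velocity amplitude spectrum."""

    best_frequency_hz: float
    quality_factor: float
    amplitude_scale: float  # A, m/s per unit of the dimensionless response
    r_squared: float
    fit_band_hz: tuple[float, float]
    bin_width_hz: float  # spectral bin width the amplitudes were calibrated on
    noise_floor: float | None = None
    valid: bool = True
    message: str = ""

    @property
    def omega0(self) -> float:
        return 2.0 * math.pi * self.best_frequency_hz


@dataclass(frozen=True)
class RecoveryCheck:
    """Baseline-vs-final comparison of free-fluctuation fits (recovery criterion)."""

    baseline: OscillatorFit
    final: OscillatorFit
    relative_changes: dict
    threshold: float
    passed: bool


def compute_spectrum(
    trace: VelocityTrace,
    max_frequency_hz: float = DEFAULT_MAX_FREQUENCY,
    segment_seconds: float = 1.0,
    min_segments: int = 8,
) -> AmplitudeSpectrum:
    """Amplitude spectrum of a velocity trace, covering up to 10 kHz (or Nyquist).

    When the trace is long enough for at least ``min_segments`` half-
    overlapping Hann segments of ``segment_seconds``, a Welch average is used
    and bins are power-calibrated from the density estimate
    (``a = sqrt(2 * PSD * df)``); otherwise a single full-length rectangular
    FFT gives sine-amplitude-exact bins (``a = 2 |X| / n``).
    """
    x = trace.samples
    fs = 1.0 / trace.dt
    nyquist = fs / 2.0
    f_hi = min(max_frequency_hz, nyquist)

    nperseg = int(round(segment_seconds * fs))
    n_segments = (x.size - nperseg // 2) // (nperseg - nperseg // 2) if nperseg > 1 else 0
    if nperseg >= 16 and n_segments >= min_segments:
        freqs, psd = welch(
            x,
            fs=fs,
            window="hann",
            nperseg=nperseg,
            noverlap=nperseg // 2,
            detrend="constant",
            scaling="density",
        )
        df = freqs[1] - freqs[0]
        amps = np.sqrt(2.0 * psd * df)
    else:
        spectrum = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(x.size, d=trace.dt)
        amps = 2.0 * np.abs(spectrum) / x.size
        if x.size % 2 == 0 and amps.size:
            amps[-1] /= 2.0  # Nyquist bin is not doubled
    keep = (freqs > 0) & (freqs <= f_hi)
    return AmplitudeSpectrum(frequencies_hz=freqs[keep], amplitudes=amps[keep])


def oscillator_velocity_model(
    f: np.ndarray, f0: float, q: float, amplitude: float, noise_floor: float = 0.0
) -> np.ndarray:
    """Velocity-amplitude resonance curve evaluated on frequency grid ``f``."""
    f = np.asarray(f, dtype=float)
    denom = np.sqrt((f0**2 - f**2) ** 2 + (f0 * f / q) ** 2)
    return amplitude * f * f0**2 / denom + noise_floor


def fit_oscillator(
    spectrum: AmplitudeSpectrum,
    fit_band: tuple[float, float] = DEFAULT_FIT_BAND,
    with_noise_floor: bool = False,
    r2_floor: float = 0.2,
) -> OscillatorFit:
    """Least-squares oscillator fit restricted to ``fit_band``.

    Initialization: f0 at the in-band amplitude argmax, Q from a small
    deterministic grid of starts, A from the peak height. Q is bounded in
    [0.1, 1e5] (self-sustained oscillations can reach Q of a few thousand).
    Poor fits are flagged ``valid=False`` rather than silently returned.
    """
    lo, hi = fit_band
    mask = (spectrum.frequencies_hz >= lo) & (spectrum.frequencies_hz <= hi)
    f = spectrum.frequencies_hz[mask]
    a = spectrum.amplitudes[mask]
    if f.size < 10:
        raise ValueError(f"need >= 10 bins inside fit band {fit_band}, got {f.size}")

    peak_idx = int(np.argmax(a))
    f0_init = float(f[peak_idx])
    peak = float(a[peak_idx])
    df = spectrum.bin_width_hz

    def invalid(msg: str) -> OscillatorFit:
        return OscillatorFit(
            best_frequency_hz=f0_init,
            quality_factor=math.nan,
            amplitude_scale=math.nan,
            r_squared=-math.inf,
            fit_band_hz=fit_band,
            bin_width_hz=df,
            valid=False,
            message=msg,
        )

    if peak <= 0 or np.ptp(a) == 0:
        return invalid("no resonance: flat or empty spectrum in band")

    # fit in peak-normalized units so the optimizer sees O(1) parameters
    y = a / peak
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    best = None
    q_bounds = (0.1, 1e5)
    for q_init in (0.7, 2.0, 20.0, 500.0):
        amp_init = 1.0 / (f0_init * q_init)
        if with_noise_floor:
            p0 = [f0_init, q_init, amp_init, 0.0]
            lower = [lo, q_bounds[0], 0.0, 0.0]
            upper = [hi, q_bounds[1], np.inf, 1.0]
            model = oscillator_velocity_model
        else:
            p0 = [f0_init, q_init, amp_init]
            lower = [lo, q_bounds[0], 0.0]
            upper = [hi, q_bounds[1], np.inf]

            def model(ff, f0, q, amp):
                return oscillator_velocity_model(ff, f0, q, amp)

        try:
            popt, _ = curve_fit(
                model, f, y, p0=p0, bounds=(lower, upper), maxfev=40000
            )
        except RuntimeError:
            continue
        resid = y - model(f, *popt)
        ss = float(np.sum(resid**2))
        if best is None or ss < best[1]:
            best = (popt, ss)
    if best is None:
        return invalid("optimizer failed to converge")
    popt, ss_res = best
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = OscillatorFit(
        best_frequency_hz=float(popt[0]),
        quality_factor=float(popt[1]),
        amplitude_scale=float(popt[2]) * peak,
        noise_floor=float(popt[3]) * peak if with_noise_floor else None,
        r_squared=r2,
        fit_band_hz=fit_band,
        bin_width_hz=df,
        valid=True,
        message="",
    )
    if r2 < r2_floor:
        fit = replace(fit, valid=False, message=f"r_squared {r2:.3f} below floor {r2_floor}")
    return fit


def check_recovery(
    baseline: OscillatorFit, final: OscillatorFit, threshold: float = 0.20
) -> RecoveryCheck:
    """Recovery criterion: best frequency and amplitude changed by < ``threshold``.

    Mirrors the sedation-recovery rule: recordings whose final free-fluctuation
    fit deviates from baseline by 20% or more in either monitored parameter
    fail and should be excluded.
    """
    if not (baseline.valid and final.valid):
        raise ValueError("recovery check requires two valid fits")
    changes = {
        "best_frequency": abs(final.best_frequency_hz - baseline.best_frequency_hz)
        / baseline.best_frequency_hz,
        "amplitude": abs(final.amplitude_scale - baseline.amplitude_scale)
        / baseline.amplitude_scale,
    }
    passed = all(change < threshold for change in changes.values())
    return RecoveryCheck(
        baseline=baseline,
        final=final,
        relative_changes=changes,
        threshold=threshold,
        passed=passed,
    )
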