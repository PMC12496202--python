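"""Synthetic-data generators with planted ground truth.

Everything the analysis chain consumes can be generated here: stochastic
free-fluctuation traces of a damped harmonic oscillator, forced sweep trials,
two-state gating force-step experiments, sensitivity curves, and
differential-expression tables with planted intersectional subset structure.
All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import brentq
from scipy.signal import lfilter, lfiltic

from .constants import BOLTZMANN, DEFAULT_TEMPERATURE
from .de_subsets import (
    LABEL_FEMALE_SIDE,
    LABEL_FULL,
    LABEL_INDEPENDENT,
    LABEL_MVF_ONLY,
    LABEL_NOT_UP,
    LABEL_PARTIAL,
)
from .sweeps import SweepStimulus
from .transducer import GatingFit, gating_force_model

__all__ = [
    "SsoMode",
    "OscillatorParams",
    "VelocityTrace",
    "SweepTrial",
    "GatingExperiment",
    "DESimParams",
    "DETables",
    "langevin_trajectory",
    "simulate_free_fluctuation",
    "simulate_sweep_trial",
    "simulate_gating_experiment",
    "simulate_sensitivity_curve",
    "simulate_de_tables",
]


# ---------------------------------------------------------------------------
# oscillator parameters and traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SsoMode:
    """Self-sustained limit-cycle oscillation superposed on the thermal motion."""

    amplitude_m: float
    frequency_hz: float
    relaxation_rate: float = 50.0  # 1/s; amplitude relaxation onto the cycle

    def __post_init__(self) -> None:
        if self.amplitude_m <= 0 or self.frequency_hz <= 0:
            raise ValueError("SSO amplitude and frequency must be positive")


@dataclass(frozen=True)
class OscillatorParams:
    """Mechanical parameters of the flagellar receiver model.

    ``active_boost`` injects energy as an effective-temperature factor:
    ``T_eff = temperature * (1 + active_boost)``; 0 means passive.
    """

    mass_kg: float
    stiffness_n_per_m: float
    damping_ns_per_m: float
    temperature_k: float = DEFAULT_TEMPERATURE
    active_boost: float = 0.0
    sso: SsoMode | None = None

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("mass must be positive")
        if self.stiffness_n_per_m <= 0:
            raise ValueError("stiffness must be positive")
        if self.damping_ns_per_m <= 0:
            raise ValueError("damping must be positive")
        if self.temperature_k < 0:
            raise ValueError("temperature must be non-negative")
        if self.active_boost < 0:
            raise ValueError("active_boost must be >= 0")
        if not (
            math.isfinite(self.natural_frequency_hz)
            and math.isfinite(self.quality_factor)
        ):
            raise ValueError("derived f0 and Q must be finite")

    @classmethod
    def from_resonance(
        cls,
        natural_frequency_hz: float,
        quality_factor: float,
        mass_kg: float,
        temperature_k: float = DEFAULT_TEMPERATURE,
        active_boost: float = 0.0,
        sso: SsoMode | None = None,
    ) -> "OscillatorParams":
        """Build from (f0, Q, m): k = m (2 pi f0)^2, gamma = sqrt(m k) / Q."""
        if natural_frequency_hz <= 0 or quality_factor <= 0:
            raise ValueError("f0 and Q must be positive")
        omega0 = 2.0 * math.pi * natural_frequency_hz
        stiffness = mass_kg * omega0**2
        damping = math.sqrt(mass_kg * stiffness) / quality_factor
        return cls(
            mass_kg=mass_kg,
            stiffness_n_per_m=stiffness,
            damping_ns_per_m=damping,
            temperature_k=temperature_k,
            active_boost=active_boost,
            sso=sso,
        )

    @property
    def natural_frequency_hz(self) -> float:
        return math.sqrt(self.stiffness_n_per_m / self.mass_kg) / (2.0 * math.pi)

    @property
    def quality_factor(self) -> float:
        return (
            math.sqrt(self.mass_kg * self.stiffness_n_per_m) / self.damping_ns_per_m
        )

    @property
    def effective_temperature_k(self) -> float:
        return self.temperature_k * (1.0 + self.active_boost)


@dataclass(frozen=True)
class VelocityTrace:
    """Uniformly sampled flagellar velocity (m/s) with state metadata."""

    samples: np.ndarray
    dt: float
    state_label: str = "passive"  # {"active", "passive"}
    oscillation_label: str = "n/a"  # {"quiescent", "SSO", "n/a"}
    seed: int | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("trace must be 1-D with length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


def _transition(params: OscillatorParams, dt: float) -> np.ndarray:
    """One-step transition matrix exp(M dt) of the linear (x, v) system."""
    m, k, g = params.mass_kg, params.stiffness_n_per_m, params.damping_ns_per_m
    drift = np.array([[0.0, 1.0], [-k / m, -g / m]])
    return expm(drift * dt)


def langevin_trajectory(
    params: OscillatorParams,
    duration: float,
    dt: float,
    seed: int | None = None,
    x0: float | None = None,
    v0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the thermally driven oscillator exactly on a uniform grid.

    Integrates ``m x'' + gamma x' + k x = sqrt(2 gamma k_B T_eff) xi(t)`` using
    the exact Gaussian one-step discretization (matrix-exponential propagator
    with the stationary-covariance increment), so the sampled process has the
    continuous-time stationary statistics at any stable ``dt``. Unless an
    initial condition is given, the state is drawn from the stationary
    distribution — no burn-in is required.

    Returns ``(t, x, v)`` in SI units.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    if n < 2:
        raise ValueError("duration must cover at least 2 samples")

    m, k = params.mass_kg, params.stiffness_n_per_m
    t_eff = params.effective_temperature_k
    phi = _transition(params, dt)
    p, q = phi[0, 0], phi[0, 1]
    r, s = phi[1, 0], phi[1, 1]

    # Stationary covariance of (x, v) and the exact one-step noise covariance.
    sigma_inf = np.diag([BOLTZMANN * t_eff / k, BOLTZMANN * t_eff / m])
    sigma_dt = sigma_inf - phi @ sigma_inf @ phi.T
    sigma_dt = 0.5 * (sigma_dt + sigma_dt.T)

    rng = np.random.default_rng(seed)
    if t_eff > 0:
        evals, evecs = np.linalg.eigh(sigma_dt)
        root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
        w = rng.standard_normal((n, 2)) @ root.T  # w[i] drives step i -> i+1
    else:
        w = np.zeros((n, 2))

    if x0 is None and v0 is None and t_eff > 0:
        init = rng.multivariate_normal([0.0, 0.0], sigma_inf)
        x_init, v_init = float(init[0]), float(init[1])
    else:
        x_init = 0.0 if x0 is None else float(x0)
        v_init = 0.0 if v0 is None else float(v0)

    # The 2-D AR(1) recursion collapses to a scalar ARMA(2,1) in x:
    #   x[i+2] = (p+s) x[i+1] - (ps-qr) x[i] + (w1[i+1] - s w1[i] + q w2[i])
    x = np.empty(n)
    x[0] = x_init
    x[1] = p * x_init + q * v_init + w[0, 0]
    if n > 2:
        e = w[1 : n - 1, 0] - s * w[0 : n - 2, 0] + q * w[0 : n - 2, 1]
        a = [1.0, -(p + s), p * s - q * r]
        zi = lfiltic([1.0], a, y=[x[1], x[0]])
        x[2:], _ = lfilter([1.0], a, e, zi=zi)

    # Recover velocities from x[i+2] = p x[i+1] + q v[i+1] + w1[i+1].
    v = np.empty(n)
    v[0] = v_init
    v[1 : n - 1] = (x[2:] - p * x[1:-1] - w[1 : n - 1, 0]) / q
    v[n - 1] = r * x[n - 2] + s * v[n - 2] + w[n - 2, 1]

    t = np.arange(n) * dt
    return t, x, v


def _sso_component(
    sso: SsoMode, t: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Limit-cycle displacement and velocity (Stuart-Landau normal form).

    The amplitude relaxes onto the cycle radius with closed-form dynamics
    ``a(t) = A / sqrt(1 + ((A/a0)^2 - 1) exp(-2 mu t))``; by default the cycle
    is entered on-radius with a random phase.
    """
    a_cycle = sso.amplitude_m
    mu = sso.relaxation_rate
    omega = 2.0 * math.pi * sso.frequency_hz
    a0 = a_cycle  # start on the cycle
    amp = a_cycle / np.sqrt(1.0 + ((a_cycle / a0) ** 2 - 1.0) * np.exp(-2.0 * mu * t))
    damp_dt = mu * amp * (1.0 - (amp / a_cycle) ** 2)
    phase0 = rng.uniform(0.0, 2.0 * math.pi)
    x = amp * np.sin(omega * t + phase0)
    v = damp_dt * np.sin(omega * t + phase0) + amp * omega * np.cos(omega * t + phase0)
    return x, v


def simulate_free_fluctuation(
    params: OscillatorParams,
    duration: float,
    dt: float,
    seed: int | None = None,
    x0: float | None = None,
    v0: float | None = None,
) -> VelocityTrace:
    """Simulate a free-fluctuation velocity recording.

    Thermal (optionally boosted) Langevin motion, with an additive limit-cycle
    component when ``params.sso`` is set. Identical arguments and seed yield
    bit-identical traces.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    f0 = params.natural_frequency_hz
    if dt >= 1.0 / (20.0 * f0):
        raise ValueError(
            f"dt={dt:g} too coarse for f0={f0:.1f} Hz; need dt < 1/(20 f0) "
            f"= {1.0 / (20.0 * f0):.2e} s"
        )
    _, _, v = langevin_trajectory(params, duration, dt, seed=seed, x0=x0, v0=v0)
    if params.sso is not None:
        rng = np.random.default_rng(None if seed is None else seed + 0x5505)
        t = np.arange(v.size) * dt
        _, v_sso = _sso_component(params.sso, t, rng)
        v = v + v_sso
        oscillation = "SSO"
    else:
        oscillation = "quiescent" if params.active_boost > 0 else "n/a"
    state = "active" if (params.active_boost > 0 or params.sso is not None) else "passive"
    return VelocityTrace(
        samples=v, dt=dt, state_label=state, oscillation_label=oscillation, seed=seed
    )


# ---------------------------------------------------------------------------
# sweep trials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepTrial:
    """One simulated sweep-stimulation trial with planted ground truth."""

    stimulus: SweepStimulus
    displacement: np.ndarray  # nm
    cap: np.ndarray  # uV
    dt: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.displacement.shape != self.cap.shape:
            raise ValueError("displacement and CAP traces must share a grid")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _mech_response_factor(f: np.ndarray, f0: float, q: float) -> np.ndarray:
    """Dimensionless steady-state displacement response, normalized to 1 at DC."""
    return f0**2 / np.sqrt((f0**2 - f**2) ** 2 + (f0 * f / q) ** 2)


def simulate_sweep_trial(
    params: OscillatorParams,
    stimulus: SweepStimulus,
    electrical_tuning: tuple[float, float] = (300.0, 150.0),
    cap_saturation: tuple[float, float, float] = (40.0, 50.0, 20.0),
    noise_level: float = 0.0,
    dt: float = 1e-4,
    seed: int | None = None,
) -> SweepTrial:
    """Forced steady-state-tracking response of the oscillator to a linear sweep.

    The displacement trace (nm) follows the oscillator's steady-state amplitude
    at the instantaneous sweep frequency; the CAP trace (uV) is a saturating
    sigmoid of the displacement envelope weighted by a Gaussian electrical
    tuning curve. ``noise_level`` is the additive-noise standard deviation as a
    fraction of the peak envelope (absolute units when the stimulus amplitude
    is zero).
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    nyquist = 0.5 / dt
    if max(stimulus.f_start_hz, stimulus.f_end_hz) >= nyquist:
        raise ValueError("stimulus frequencies must stay below Nyquist")
    n = int(round(stimulus.duration_s / dt)) + 1
    t = np.arange(n) * dt
    f_inst = np.asarray(stimulus.frequency_at(t), dtype=float)
    f0, q = params.natural_frequency_hz, params.quality_factor

    env = stimulus.amplitude * _mech_response_factor(f_inst, f0, q)
    disp = env * np.sin(np.asarray(stimulus.phase_at(t), dtype=float))

    cap_max, cap_mid_nm, cap_slope_nm = cap_saturation
    fc, fw = electrical_tuning
    tuning = np.exp(-((f_inst - fc) ** 2) / (2.0 * fw**2))
    drive = env * tuning
    cap_env = cap_max / (1.0 + np.exp(-(drive - cap_mid_nm) / cap_slope_nm))
    cap_env = cap_env - cap_max / (1.0 + np.exp(cap_mid_nm / cap_slope_nm))  # zero at rest
    # nerve response phase-locks to the stimulus; the saturating envelope rides a carrier
    cap = cap_env * np.sin(np.asarray(stimulus.phase_at(t), dtype=float))

    rng = np.random.default_rng(seed)
    disp_scale = float(np.max(env)) if stimulus.amplitude > 0 else 1.0
    cap_scale = float(np.max(cap)) if np.max(cap) > 0 else 1.0
    disp = disp + noise_level * disp_scale * rng.standard_normal(n)
    cap = cap + noise_level * cap_scale * rng.standard_normal(n)

    mech_bf = f0 * math.sqrt(1.0 - 1.0 / (2.0 * q**2)) if q > 1.0 / math.sqrt(2) else 0.0
    grid = np.linspace(
        min(stimulus.f_start_hz, stimulus.f_end_hz),
        max(stimulus.f_start_hz, stimulus.f_end_hz),
        20001,
    )
    grid_drive = (
        stimulus.amplitude
        * _mech_response_factor(grid, f0, q)
        * np.exp(-((grid - fc) ** 2) / (2.0 * fw**2))
    )
    elec_profile = 1.0 / (1.0 + np.exp(-(grid_drive - cap_mid_nm) / cap_slope_nm))
    truth = {
        "mechanical_bf_hz": mech_bf if mech_bf > 0 else f0,
        "electrical_bf_hz": float(grid[int(np.argmax(elec_profile))]),
        "sensitivity": float(np.max(env) / stimulus.amplitude)
        if stimulus.amplitude > 0
        else math.nan,
    }
    return SweepTrial(stimulus=stimulus, displacement=disp, cap=cap, dt=dt, truth=truth)


def simulate_sensitivity_curve(
    gain: float,
    n_intensities: int = 10,
    decades: float = 2.0,
    noise: float = 0.0,
    scale: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Sensitivity-vs-intensity points from a sigmoid with a planted gain.

    Solves for the sigmoid midpoint so that the ratio of the curve's endpoint
    values over ``decades`` log-spaced intensities equals ``gain`` exactly,
    then perturbs with multiplicative Gaussian noise. Returns
    ``(intensities, sensitivities, truth)``.
    """
    if gain < 1:
        raise ValueError("planted gain must be >= 1")
    if n_intensities < 5:
        raise ValueError("need at least 5 intensities")
    intensities = np.logspace(0.0, decades, n_intensities)
    x = np.log10(intensities)
    b = decades / 5.0
    if gain == 1.0:
        y = np.full(n_intensities, scale)
        x0 = float(np.mean(x))
    else:
        max_ratio = math.exp((x[-1] - x[0]) / b)
        if gain >= max_ratio:
            raise ValueError("planted gain unreachable for this slope/range")

        def ratio_err(x0: float) -> float:
            top = 1.0 + math.exp((x0 - x[0]) / b)
            bottom = 1.0 + math.exp((x0 - x[-1]) / b)
            return top / bottom - gain

        x0 = brentq(ratio_err, x[0] - 50.0 * b, x[-1] + 50.0 * b)
        y = scale / (1.0 + np.exp(-(x - x0) / b))
    rng = np.random.default_rng(seed)
    if noise > 0:
        y = y * (1.0 + noise * rng.standard_normal(n_intensities))
        y = np.clip(y, np.min(y[y > 0]) * 1e-3 if np.any(y > 0) else 1e-12, None)
    truth = {"gain": gain, "midpoint_log10": x0, "slope_log10": b, "scale": scale}
    return intensities, y, truth


# ---------------------------------------------------------------------------
# gating force steps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GatingExperiment:
    """Force-step series: commanded forces, steady displacements, CAP amplitudes."""

    forces: np.ndarray  # N, both signs, log-spaced magnitudes
    displacements: np.ndarray  # m
    cap_amplitudes: np.ndarray  # uV
    truth: GatingFit

    def __post_init__(self) -> None:
        if not (self.forces.shape == self.displacements.shape == self.cap_amplitudes.shape):
            raise ValueError("forces, displacements and CAP amplitudes must align")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacements must be finite")


def _solve_displacement(truth: GatingFit, force: float) -> float:
    """Invert the monotone two-state force-displacement relation."""
    lo, hi = -1e-2, 1e-2
    return brentq(lambda x: gating_force_model(truth, x) - force, lo, hi, xtol=1e-15)


def simulate_gating_experiment(
    truth: GatingFit,
    n_steps: int = 20,
    displacement_noise: float = 0.0,
    seed: int | None = None,
    force_max: float | None = None,
    force_decades: float = 2.5,
    cap_saturation: tuple[float, float, float] = (60.0, 5e-7, 2e-7),
) -> GatingExperiment:
    """Generate a force-step experiment: ``n_steps`` log-spaced forces per sign.

    Steady displacements solve the two-state force-displacement relation for
    each commanded force and are perturbed by multiplicative Gaussian noise;
    CAP amplitudes saturate sigmoidally in ``|displacement|``.
    """
    if n_steps < 4:
        raise ValueError("need at least 4 steps per sign")
    if displacement_noise < 0:
        raise ValueError("displacement_noise must be >= 0")
    if force_max is None:
        force_max = 1.5 * truth.asymptotic_stiffness_n_per_m * truth.analysis_window_m
    mags = np.logspace(
        math.log10(force_max) - force_decades, math.log10(force_max), n_steps
    )
    forces = np.concatenate([-mags[::-1], mags]) + truth.force_offset_n
    disp = np.array([_solve_displacement(truth, f) for f in forces])
    rng = np.random.default_rng(seed)
    if displacement_noise > 0:
        disp = disp * (1.0 + displacement_noise * rng.standard_normal(disp.size))
    cap_max, cap_mid, cap_slope = cap_saturation
    cap = cap_max / (1.0 + np.exp(-(np.abs(disp) - cap_mid) / cap_slope))
    cap = cap - cap_max / (1.0 + np.exp(cap_mid / cap_slope))
    return GatingExperiment(
        forces=forces, displacements=disp, cap_amplitudes=cap, truth=truth
    )


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DESimParams:
    """Planted structure for the three-way DE comparison tables.

    The four male-upregulated subset sizes follow the intersectional patterns
    recovered downstream; ``n_female_up`` transcripts are downregulated in the
    male-vs-female comparison and ``n_null`` carry no planted effect. With
    ``contaminate_nulls=False`` (default) null adjusted p-values are drawn
    above the threshold so planted counts are recovered exactly; set it to
    True for uniform-[0,1] null p-values.
    """

    n_genes: int
    n_full_recovery: int = 632
    n_male_independent: int = 172
    n_partial_recovery: int = 89
    n_mvf_only: int = 1092
    n_female_up: int = 0
    effect_size: float = 4.0
    fdr_threshold: float = 0.05
    seed: int | None = None
    contaminate_nulls: bool = False

    def __post_init__(self) -> None:
        planted = (
            self.n_full_recovery
            + self.n_male_independent
            + self.n_partial_recovery
            + self.n_mvf_only
            + self.n_female_up
        )
        if planted > self.n_genes:
            raise ValueError("planted subset sizes exceed the gene universe")
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must lie in (0, 1)")

    @property
    def n_null(self) -> int:
        return self.n_genes - (
            self.n_full_recovery
            + self.n_male_independent
            + self.n_partial_recovery
            + self.n_mvf_only
            + self.n_female_up
        )


@dataclass(frozen=True)
class DETables:
    """The three simulated comparison tables plus the planted label per transcript."""

    mvf: pd.DataFrame
    ivf: pd.DataFrame
    mvi: pd.DataFrame
    truth: pd.Series  # transcript_id -> planted label


# per-label (MvF, IvF, MvI) patterns: +1 up-significant, -1 down-significant, 0 ns
_PATTERNS = {
    LABEL_FULL: (+1, +1, 0),
    LABEL_INDEPENDENT: (+1, 0, +1),
    LABEL_PARTIAL: (+1, +1, +1),
    LABEL_MVF_ONLY: (+1, 0, 0),
    LABEL_FEMALE_SIDE: (-1, -1, 0),
    LABEL_NOT_UP: (0, 0, 0),
}


def simulate_de_tables(params: DESimParams) -> DETables:
    """Simulate MvF / IvF / MvI result tables with planted subset structure.

    Significant comparisons get ``|log2fc|`` near ``effect_size`` and adjusted
    p-values far below the threshold; non-significant ones get small fold
    changes and p-values above it (unless ``contaminate_nulls``).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    ids = np.array([f"TX{i:06d}" for i in range(n)])
    labels = np.concatenate(
        [
            np.full(params.n_full_recovery, LABEL_FULL),
            np.full(params.n_male_independent, LABEL_INDEPENDENT),
            np.full(params.n_partial_recovery, LABEL_PARTIAL),
            np.full(params.n_mvf_only, LABEL_MVF_ONLY),
            np.full(params.n_female_up, LABEL_FEMALE_SIDE),
            np.full(params.n_null, LABEL_NOT_UP),
        ]
    )
    rng.shuffle(labels)

    thr = params.fdr_threshold
    tables = []
    for comp_index in range(3):
        pattern = np.array([_PATTERNS[lab][comp_index] for lab in labels])
        sig = pattern != 0
        lfc = rng.normal(0.0, 0.15, size=n)
        lfc[sig] = pattern[sig] * (
            params.effect_size + np.abs(rng.normal(0.0, 0.25 * params.effect_size, sig.sum()))
        )
        padj = np.empty(n)
        padj[sig] = rng.uniform(1e-12, thr * 1e-3, size=sig.sum())
        if params.contaminate_nulls:
            padj[~sig] = rng.uniform(0.0, 1.0, size=(~sig).sum())
        else:
            padj[~sig] = rng.uniform(thr, 1.0, size=(~sig).sum())
        tables.append(
            pd.DataFrame({"transcript_id": ids, "log2fc": lfc, "padj": padj})
        )

    truth = pd.Series(labels, index=pd.Index(ids, name="transcript_id"), name="label")
    return DETables(mvf=tables[0], ivf=tables[1], mvi=tables[2], truth=truth)
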