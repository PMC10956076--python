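"""Jansen-Rit neural-mass model and the synthetic-EEG generator.

The model describes the average postsynaptic potentials of three coupled
cortical populations -- pyramidal cells, excitatory interneurons and
inhibitory interneurons -- as six first-order ODEs.  Its output
``y(t) = v1(t) - v2(t)`` mimics a single EEG channel.  The five
physiological parameters are the excitatory/inhibitory synaptic gains
``A`` and ``B`` (mV), the inverse synaptic time constants ``a`` and ``b``
(1/s), and the background pulse density ``p`` (1/s).  The connectivity
constants ``C1..C4`` are fixed.

Integration uses the classical fourth-order Runge-Kutta scheme; the
synthetic generator redraws the stochastic input ``p`` once per output
sample and adds white Gaussian observation noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "NMParameters",
    "ScheduleSegment",
    "SimulationScenario",
    "SyntheticRecord",
    "sigmoid",
    "nm_derivative",
    "rk4_step",
    "simulate",
    "snr",
]

#: default guard: any state component beyond this magnitude is a blow-up
BLOWUP_GUARD = 1.0e6

# canonical synaptic connectivity counts (dimensionless)
C1_DEFAULT = 135.0
C2_DEFAULT = 108.0
C3_DEFAULT = 33.75
C4_DEFAULT = 33.75


@dataclass(frozen=True)
class NMParameters:
    """The five time-varying parameters plus fixed connectivity constants.

    Attributes
    ----------
    A, B : float
        Excitatory / inhibitory synaptic gain (mV).
    a, b : float
        Inverse excitatory / inhibitory synaptic time constant (1/s);
        ``tau_e = 1/a`` so a in [5, 200] spans tau_e of 5-200 ms.
    p : float
        Background input pulse density (1/s).
    C1..C4 : float
        Synaptic connectivity counts; fixed at 135, 108, 33.75, 33.75
        unless explicitly overridden.
    """

    A: float = 3.25
    a: float = 100.0
    B: float = 22.0
    b: float = 50.0
    p: float = 220.0
    C1: float = C1_DEFAULT
    C2: float = C2_DEFAULT
    C3: float = C3_DEFAULT
    C4: float = C4_DEFAULT

    def __post_init__(self) -> None:
        for name in ("A", "a", "B", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        """Return the estimable parameter block ``[A, a, B, b, p]``."""
        return np.array([self.A, self.a, self.B, self.b, self.p], dtype=float)


def sigmoid(v):
    """Population firing-rate sigmoid, 5 / (1 + exp(0.56 (6 - v))).

    Strictly increasing, bounded in (0, 5), firing rate in 1/s for a
    membrane potential ``v`` in mV.  Implemented with a numerically safe
    logistic so extreme potentials saturate instead of overflowing.
    """
    return 5.0 * expit(0.56 * (np.asarray(v, dtype=float) - 6.0))


def nm_derivative(state, params: NMParameters):
    """Vector field g(v, theta) of the six-dimensional neural-mass ODE.

    Parameters
    ----------
    state : array_like, shape (..., 6)
        ``[v0, v1, v2, v3, v4, v5]`` -- postsynaptic potentials of the
        pyramidal, excitatory and inhibitory populations and their
        derivatives.  Broadcasts over leading axes.
    params : NMParameters or tuple of arrays
        Either a single parameter set or per-row arrays
        ``(A, a, B, b, p)`` broadcastable against ``state[..., 0]``
        (connectivity constants then take their canonical values).

    Returns
    -------
    ndarray, shape (..., 6)
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite neural-mass state")
    if isinstance(params, NMParameters):
        A, a, B, b, p = params.A, params.a, params.B, params.b, params.p
        C = (params.C1, params.C2, params.C3, params.C4)
    else:
        A, a, B, b, p = params
        C = (C1_DEFAULT, C2_DEFAULT, C3_DEFAULT, C4_DEFAULT)
    return _vector_field(state, A, a, B, b, p, C)


def _vector_field(state, A, a, B, b, p, C=(C1_DEFAULT, C2_DEFAULT, C3_DEFAULT, C4_DEFAULT)):
    # unchecked core of nm_derivative; broadcasts parameters over rows
    C1, C2, C3, C4 = C
    v0, v1, v2, v3, v4, v5 = np.moveaxis(state, -1, 0)
    dv = np.empty_like(state)
    dv[..., 0] = v3
    dv[..., 1] = v4
    dv[..., 2] = v5
    dv[..., 3] = A * a * sigmoid(v1 - v2) - 2.0 * a * v3 - a**2 * v0
    dv[..., 4] = A * a * (p + C2 * sigmoid(C1 * v0)) - 2.0 * a * v4 - a**2 * v1
    dv[..., 5] = B * b * C4 * sigmoid(C3 * v0) - 2.0 * b * v5 - b**2 * v2
    return dv


def rk4_step(state, params, dt: float, guard: float = BLOWUP_GUARD):
    """One classical Runge-Kutta-4 step of the neural-mass ODE.

    Parameters (including the realized stochastic input ``p``) are held
    constant across the four substage evaluations.  Raises
    ``FloatingPointError`` if any output component exceeds ``guard`` in
    magnitude (numerical blow-up).
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    state = np.asarray(state, dtype=float)
    k1 = nm_derivative(state, params)
    k2 = nm_derivative(state + 0.5 * dt * k1, params)
    k3 = nm_derivative(state + 0.5 * dt * k2, params)
    k4 = nm_derivative(state + dt * k3, params)
    out = state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.abs(out) <= guard):
        raise FloatingPointError("neural-mass integration blew up (|state| > guard)")
    return out


@dataclass(frozen=True)
class ScheduleSegment:
    """Parameter values over the half-open time interval [t_start, t_end).

    ``p`` is stochastic: redrawn each output sample from
    ``N(p_mean, p_var)`` (second moment given as a *variance*).
    """

    t_start: float
    t_end: float
    A: float = 3.25
    a: float = 100.0
    B: float = 22.0
    b: float = 50.0
    p_mean: float = 220.0
    p_var: float = 22.0

    def params_with_p(self, p: float) -> NMParameters:
        return NMParameters(A=self.A, a=self.a, B=self.B, b=self.b, p=p)


@dataclass(frozen=True)
class SimulationScenario:
    """A piecewise-constant parameter schedule plus observation noise.

    Segments must tile ``[0, duration_samples * dt)`` without overlap.
    ``burn_in_s`` > 0 lets the model settle from the zero state under the
    first segment's parameters for that many seconds before recording
    starts (discarded; useful for spectral analyses and SNR summaries of
    the steady oscillation).
    """

    duration_samples: int
    dt: float
    schedule: tuple[ScheduleSegment, ...]
    obs_noise_variance: float = 1.3
    seed: int = 0
    burn_in_s: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.obs_noise_variance < 0:
            raise ValueError("obs_noise_variance must be non-negative")
        segs = sorted(self.schedule, key=lambda s: s.t_start)
        object.__setattr__(self, "schedule", tuple(segs))
        total = self.duration_samples * self.dt
        t = 0.0
        for seg in segs:
            if not np.isclose(seg.t_start, t):
                raise ValueError("schedule segments must tile [0, duration) without gaps")
            if seg.t_end <= seg.t_start:
                raise ValueError("empty schedule segment")
            t = seg.t_end
        if t < total - 1e-9:
            raise ValueError("schedule does not cover the full duration")

    def segment_at(self, t: float) -> ScheduleSegment:
        for seg in self.schedule:
            if seg.t_start <= t < seg.t_end:
                return seg
        return self.schedule[-1]

    def to_dict(self) -> dict:
        return {
            "duration_samples": self.duration_samples,
            "dt": self.dt,
            "obs_noise_variance": self.obs_noise_variance,
            "seed": self.seed,
            "burn_in_s": self.burn_in_s,
            "schedule": [vars(s) for s in self.schedule],
        }


@dataclass
class SyntheticRecord:
    """Output of :func:`simulate`: clean/noisy EEG plus ground truth."""

    clean_eeg: np.ndarray
    noisy_eeg: np.ndarray
    states: np.ndarray          # (n, 6)
    true_params: np.ndarray     # (n, 5): A, a, B, b, p (realized)
    noise: np.ndarray
    dt: float
    seed: int
    scenario: SimulationScenario | None = None

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.clean_eeg.size) * self.dt

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "t": self.t,
            "y_clean": self.clean_eeg,
            "y_obs": self.noisy_eeg,
        }
        for i in range(6):
            cols[f"v{i}"] = self.states[:, i]
        for i, name in enumerate(("A", "a", "B", "b", "p")):
            cols[name] = self.true_params[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the record as CSV plus a JSON sidecar with the scenario."""
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {
                "dt": self.dt,
                "seed": self.seed,
                "scenario": self.scenario.to_dict() if self.scenario else None,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)


def simulate(scenario: SimulationScenario, initial_state=None) -> SyntheticRecord:
    """Generate a synthetic single-channel EEG record.

    Iterates RK4 over the parameter schedule starting from the zero state
    (configurable), redrawing ``p`` from its Gaussian once per output
    sample and holding it constant within the four RK4 substages.  White
    observation noise ``N(0, obs_noise_variance)`` is added to the clean
    output ``y = v1 - v2``.  Fully reproducible from ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.duration_samples
    state = np.zeros(6) if initial_state is None else np.asarray(initial_state, float)

    if scenario.burn_in_s > 0:
        seg = scenario.schedule[0]
        for _ in range(int(round(scenario.burn_in_s / scenario.dt))):
            p = rng.normal(seg.p_mean, np.sqrt(seg.p_var))
            state = rk4_step(state, seg.params_with_p(p), scenario.dt)

    states = np.empty((n, 6))
    true_params = np.empty((n, 5))
    for k in range(n):
        t = k * scenario.dt
        seg = scenario.segment_at(t)
        p = rng.normal(seg.p_mean, np.sqrt(seg.p_var))
        states[k] = state
        true_params[k] = (seg.A, seg.a, seg.B, seg.b, p)
        state = rk4_step(state, seg.params_with_p(p), scenario.dt)

    clean = states[:, 1] - states[:, 2]
    noise = rng.normal(0.0, np.sqrt(scenario.obs_noise_variance), size=n)
    return SyntheticRecord(
        clean_eeg=clean,
        noisy_eeg=clean + noise,
        states=states,
        true_params=true_params,
        noise=noise,
        dt=scenario.dt,
        seed=scenario.seed,
        scenario=scenario,
    )


def snr(clean, noise) -> tuple[float, float]:
    """Power-ratio SNR var(clean)/var(noise) and its base-10 logarithm."""
    clean = np.asarray(clean, float)
    noise = np.asarray(noise, float)
    if clean.shape != noise.shape:
        raise ValueError("clean and noise series must have equal length")
    var_noise = np.var(noise)
    if var_noise == 0:
        raise ValueError("noise series has zero variance")
    ratio = float(np.var(clean) / var_noise)
    return ratio, float(np.log10(ratio))
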