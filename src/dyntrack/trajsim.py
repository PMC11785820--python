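"""Synthetic cargo trajectories, stepping traces, and dwell-time samples.

Emulates retrograde endosome transport driven by one to several dynein
motors walking on a microtubule: each engaged motor steps as an independent
Poisson process with step sizes drawn from a mixture on the 4-nm
binding-site half-lattice, and the cargo sits at the arithmetic mean of the
motor positions (so a single d-nm motor step moves an n-motor cargo by
d/n).  Observed positions carry i.i.d. Gaussian localization noise.
Motion-state switching (diffusive / retrograde / anterograde) is a
continuous-time Markov chain sampled at the frame interval.

All generators take an explicit seed and record it in the output metadata;
the same seed reproduces the trajectory bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "DEFAULT_LATTICE",
    "MotorStepModel",
    "MotionState",
    "CargoConfig",
    "Trajectory",
    "DwellSample",
    "simulate_cargo_trajectory",
    "simulate_step_trace",
    "simulate_dwells",
    "cargo_displacement_per_step",
    "minimum_cargo_step",
    "default_states",
    "default_transition_rates",
]

#: Allowed per-step motor displacements (nm).  Microtubule binding sites are
#: spaced 8 nm apart; with two heads and midpoint coupling the observable
#: half-lattice is 4 nm, so steps live on +/-{4, 8, 16, 24} nm.
DEFAULT_LATTICE: tuple[float, ...] = (-24.0, -16.0, -8.0, -4.0, 4.0, 8.0, 16.0, 24.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotorStepModel:
    """Per-motor step-size mixture and stepping rate.

    Parameters
    ----------
    step_mean : float
        Mean step size d (nm), signed; retrograde positive.
    step_variance : float
        Per-step variance v (nm^2).
    step_sizes, step_probs : tuple of float
        Finite mixture over lattice multiples of 4 nm; probabilities sum to
        one and reproduce (d, v) exactly.
    step_rate : float
        Stepping rate per motor (steps / s).
    """

    step_mean: float
    step_variance: float
    step_sizes: tuple[float, ...]
    step_probs: tuple[float, ...]
    step_rate: float

    def __post_init__(self) -> None:
        p = np.asarray(self.step_probs, dtype=float)
        x = np.asarray(self.step_sizes, dtype=float)
        if p.shape != x.shape:
            raise ValueError("step_sizes and step_probs must have equal length")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("step probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("step probabilities must sum to 1 within 1e-12")
        m = float(p @ x)
        v = float(p @ x**2) - m**2
        if abs(m - self.step_mean) > 1e-9:
            raise ValueError(f"mixture mean {m} != step_mean {self.step_mean}")
        if abs(v - self.step_variance) > 1e-9:
            raise ValueError(f"mixture variance {v} != step_variance {self.step_variance}")
        if self.step_rate < 0:
            raise ValueError("step_rate must be >= 0")

    @classmethod
    def from_moments(
        cls,
        step_mean: float = 8.0,
        step_variance: float = 96.0,
        step_rate: float = 150.0,
        lattice: Sequence[float] = DEFAULT_LATTICE,
    ) -> "MotorStepModel":
        """Solve mixture probabilities on ``lattice`` matching (d, v).

        The moment constraints (normalization, mean, second moment) are
        solved by non-negative least squares; an infeasible (d, v) pair on
        the given lattice raises ``ValueError``.  The defaults d = 8 nm,
        v = 96 nm^2 calibrate the single-motor quantum
        phi_1 = 2d/(d^2 + v) = 0.1 nm^-1.
        """
        x = np.asarray(lattice, dtype=float)
        a = np.vstack([np.ones_like(x), x, x**2])
        b = np.array([1.0, step_mean, step_mean**2 + step_variance])
        # scale rows so the residual check is dimensionless
        scale = np.maximum(np.abs(b), 1.0)
        p, res = nnls(a / scale[:, None], b / scale)
        if res > 1e-9:
            raise ValueError(
                f"(mean={step_mean}, variance={step_variance}) is not representable "
                f"as a mixture on lattice {tuple(x)}"
            )
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        keep = p > 1e-15
        return cls(
            step_mean=float(p @ x),
            step_variance=float(p @ x**2 - (p @ x) ** 2),
            step_sizes=tuple(x[keep]),
            step_probs=tuple(p[keep]),
            step_rate=step_rate,
        )

    def flipped(self) -> "MotorStepModel":
        """Mirror the step distribution (anterograde <-> retrograde)."""
        return MotorStepModel(
            step_mean=-self.step_mean,
            step_variance=self.step_variance,
            step_sizes=tuple(-s for s in self.step_sizes),
            step_probs=self.step_probs,
            step_rate=self.step_rate,
        )


@dataclass(frozen=True)
class MotionState:
    """One motion state of the cargo: 'diffusive', 'retrograde' or 'anterograde'.

    ``velocity_nm_s`` is the drift produced by motor stepping (0 for the
    diffusive state); ``diffusion_nm2_s`` adds Brownian motion on top.
    The per-motor stepping rate in a transport state is |v| / |d|.
    """

    name: str
    diffusion_nm2_s: float = 0.0
    velocity_nm_s: float = 0.0


def default_states() -> tuple[MotionState, ...]:
    """Diffusive + retrograde + anterograde states at the measured velocities
    (2.81 um/s retrograde, 5.06 um/s anterograde)."""
    return (
        MotionState("diffusive", diffusion_nm2_s=1.0e4, velocity_nm_s=0.0),
        MotionState("retrograde", diffusion_nm2_s=0.0, velocity_nm_s=2810.0),
        MotionState("anterograde", diffusion_nm2_s=0.0, velocity_nm_s=-5060.0),
    )


def default_transition_rates(n_states: int = 3, rate_s: float = 0.25) -> np.ndarray:
    """Uniform off-diagonal switching rates (s^-1); mean state duration
    1 / ((n-1) * rate) = 2 s by default, mimicking stop-and-go transport."""
    q = np.full((n_states, n_states), rate_s, dtype=float)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@dataclass(frozen=True)
class CargoConfig:
    """Simulation settings for one cargo trajectory."""

    n_motors: int = 1
    localization_sd_nm: float = 2.0
    frame_interval_s: float = 0.01
    duration_s: float = 60.0
    states: tuple[MotionState, ...] = field(default_factory=default_states)
    transition_rates_s: np.ndarray | None = None
    initial_state: int = 1
    photons_per_frame: float = 1000.0
    temperature_c: float = 37.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_motors <= 10):
            raise ValueError("n_motors must be in [1, 10]")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if len(self.states) == 0:
            raise ValueError("state set must be nonempty")
        if self.transition_rates_s is not None:
            q = np.asarray(self.transition_rates_s, dtype=float)
            if q.shape != (len(self.states),) * 2:
                raise ValueError("transition-rate matrix shape must match state count")
            off = q[~np.eye(len(self.states), dtype=bool)]
            if np.any(off < 0):
                raise ValueError("off-diagonal transition rates must be nonnegative")


@dataclass
class Trajectory:
    """Time-stamped positions with photon counts.

    1-D traces use ``y_nm`` filled with zeros.  ``meta`` carries acquisition
    settings and, for synthetic data, the ground truth (state sequence, true
    positions, step times/sizes).
    """

    frame: np.ndarray
    t_s: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    photons: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        self.photons = np.asarray(self.photons, dtype=float)
        n = len(self.frame)
        for arr in (self.t_s, self.x_nm, self.y_nm, self.photons):
            if len(arr) != n:
                raise ValueError("all trajectory columns must have equal length")
        if n > 1:
            if np.any(np.diff(self.t_s) <= 0):
                raise ValueError("time stamps must be strictly increasing")
            if np.any(np.diff(self.frame) != 1):
                raise ValueError("frames must be contiguous within a record block")
        if np.any(self.photons < 0):
            raise ValueError("photon counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dt_s(self) -> float:
        if "dt_s" in self.meta:
            return float(self.meta["dt_s"])
        return float(np.median(np.diff(self.t_s)))


@dataclass
class DwellSample:
    """Dwell times between successive steps (s)."""

    dwells_s: np.ndarray
    temperature_c: float | None = None
    censor_s: float = 0.0

    def __post_init__(self) -> None:
        self.dwells_s = np.asarray(self.dwells_s, dtype=float)
        if np.any(self.dwells_s <= 0):
            raise ValueError("dwell times must be > 0")

    @property
    def n(self) -> int:
        return len(self.dwells_s)


# ---------------------------------------------------------------------------
# Coupling geometry
# ---------------------------------------------------------------------------

def cargo_displacement_per_step(motor_step_nm: float, n_motors: int) -> float:
    """Cargo displacement when one of ``n_motors`` rigidly averaged motors
    takes a step: the mean position moves by step / n."""
    if n_motors < 1:
        raise ValueError("n_motors must be >= 1")
    return motor_step_nm / n_motors


def minimum_cargo_step(site_spacing_nm: float = 8.0, n_units: int = 2) -> float:
    """Minimum observable cargo step under midpoint coupling.

    Binding sites on the microtubule are 8 nm apart; when one of the two
    motor domains advances by one site and the other stays put, the dimer
    midpoint (and the cargo) advances by half a site: 4 nm.
    """
    if site_spacing_nm <= 0:
        raise ValueError("site spacing must be > 0")
    return cargo_displacement_per_step(site_spacing_nm, n_units)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _sample_state_path(
    rng: np.random.Generator,
    q: np.ndarray,
    initial: int,
    n_frames: int,
    dt: float,
) -> np.ndarray:
    """Continuous-time Markov chain sampled at the frame grid."""
    labels = np.empty(n_frames, dtype=int)
    t = 0.0
    state = initial
    frame = 0
    t_end = n_frames * dt
    while frame < n_frames:
        rate_out = -q[state, state]
        if rate_out <= 0:
            labels[frame:] = state
            break
        stay = rng.exponential(1.0 / rate_out)
        until = min(t + stay, t_end)
        last = min(int(np.ceil(until / dt - 1e-12)), n_frames)
        labels[frame:last] = state
        frame = last
        t += stay
        probs = q[state].copy()
        probs[state] = 0.0
        probs = np.clip(probs, 0.0, None)
        if probs.sum() == 0:
            labels[frame:] = state
            break
        state = rng.choice(len(probs), p=probs / probs.sum())
    return labels


def _compound_poisson_increments(
    rng: np.random.Generator,
    n_events: np.ndarray,
    sizes: np.ndarray,
    probs: np.ndarray,
) -> np.ndarray:
    """Sum of ``n_events[i]`` i.i.d. mixture draws, per entry, vectorized."""
    total = int(n_events.sum())
    out = np.zeros(len(n_events))
    if total == 0:
        return out
    draws = rng.choice(sizes, size=total, p=probs)
    bounds = np.concatenate([[0], np.cumsum(n_events)])
    sums = np.add.reduceat(np.concatenate([draws, [0.0]]), bounds[:-1])
    sums[n_events == 0] = 0.0
    return sums


def simulate_cargo_trajectory(
    step_model: MotorStepModel, config: CargoConfig
) -> Trajectory:
    """Simulate one cargo driven by ``config.n_motors`` independent motors.

    During a transport state every motor steps as a Poisson process whose
    rate is |state velocity| / |step mean| (so the cargo's expected velocity
    matches the state and is independent of the motor count), with step
    sizes from the mixture; each motor step displaces the cargo by
    step / n_motors.  Diffusive states add Brownian increments.  Gaussian
    localization noise of SD ``localization_sd_nm`` is added independently
    per frame and axis.  Ground truth is stored in ``meta``.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_s
    n_frames = int(round(config.duration_s / dt)) + 1
    q = (
        np.asarray(config.transition_rates_s, dtype=float)
        if config.transition_rates_s is not None
        else default_transition_rates(len(config.states))
    )
    if len(config.states) == 1:
        state_path = np.zeros(n_frames, dtype=int)
    else:
        state_path = _sample_state_path(rng, q, config.initial_state, n_frames, dt)

    sizes = np.asarray(step_model.step_sizes)
    probs = np.asarray(step_model.step_probs)
    n = config.n_motors
    dx_true = np.zeros(n_frames - 1)
    for s_idx, state in enumerate(config.states):
        mask = state_path[:-1] == s_idx
        if not mask.any():
            continue
        if state.velocity_nm_s != 0.0 and step_model.step_mean != 0.0:
            lam = abs(state.velocity_nm_s / step_model.step_mean)
            counts = rng.poisson(lam * n * dt, size=int(mask.sum()))
            incr = _compound_poisson_increments(rng, counts, sizes, probs) / n
            if np.sign(state.velocity_nm_s) != np.sign(step_model.step_mean):
                incr = -incr
            dx_true[mask] = incr
        elif state.velocity_nm_s == 0.0 and step_model.step_rate > 0 and state.name != "diffusive":
            # stationary transport state driven by the model's own rate
            counts = rng.poisson(step_model.step_rate * n * dt, size=int(mask.sum()))
            dx_true[mask] = _compound_poisson_increments(rng, counts, sizes, probs) / n
        if state.diffusion_nm2_s > 0:
            dx_true[mask] += rng.normal(
                0.0, np.sqrt(2.0 * state.diffusion_nm2_s * dt), size=int(mask.sum())
            )

    x_true = np.concatenate([[0.0], np.cumsum(dx_true)])
    y_true = np.zeros(n_frames)
    sd = config.localization_sd_nm
    x_obs = x_true + rng.normal(0.0, sd, n_frames) if sd > 0 else x_true.copy()
    y_obs = y_true + rng.normal(0.0, sd, n_frames) if sd > 0 else y_true.copy()
    photons = rng.poisson(config.photons_per_frame, n_frames).astype(float)

    return Trajectory(
        frame=np.arange(n_frames),
        t_s=np.arange(n_frames) * dt,
        x_nm=x_obs,
        y_nm=y_obs,
        photons=photons,
        meta={
            "dt_s": dt,
            "temperature_C": config.temperature_c,
            "seed": config.seed,
            "n_motors": n,
            "localization_sd_nm": sd,
            "true_x_nm": x_true,
            "true_state": state_path,
            "state_names": tuple(s.name for s in config.states),
        },
    )


def simulate_step_trace(
    step_model: MotorStepModel,
    dwell_rate_s: float,
    n_steps: int,
    noise_sd_nm: float,
    frame_interval_s: float,
    seed: int = 0,
    temperature_c: float | None = None,
) -> Trajectory:
    """1-D staircase with Erlang-2 dwells (density k^2 t e^{-kt}).

    Dwell times between plateaus are the convolution of two equal-rate
    exponentials at ``dwell_rate_s``; plateau jumps are drawn from the step
    mixture.  Sampled at ``frame_interval_s`` with additive Gaussian noise.
    Ground-truth step times and sizes go to ``meta``.
    """
    if dwell_rate_s <= 0:
        raise ValueError("dwell rate must be > 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    mean_dwell = 2.0 / dwell_rate_s
    if frame_interval_s >= mean_dwell:
        warnings.warn(
            "frame interval >= mean dwell: individual steps will not be resolvable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    dwells = rng.gamma(shape=2.0, scale=1.0 / dwell_rate_s, size=n_steps)
    step_times = np.cumsum(dwells)
    step_sizes = rng.choice(
        np.asarray(step_model.step_sizes), size=n_steps, p=np.asarray(step_model.step_probs)
    )
    duration = step_times[-1] + mean_dwell
    n_frames = int(np.ceil(duration / frame_interval_s)) + 1
    t = np.arange(n_frames) * frame_interval_s
    # position = sum of steps taken by time t
    x_true = np.zeros(n_frames)
    idx = np.searchsorted(step_times, t, side="right")
    cum = np.concatenate([[0.0], np.cumsum(step_sizes)])
    x_true = cum[idx]
    x_obs = x_true + rng.normal(0.0, noise_sd_nm, n_frames) if noise_sd_nm > 0 else x_true.copy()
    return Trajectory(
        frame=np.arange(n_frames),
        t_s=t,
        x_nm=x_obs,
        y_nm=np.zeros(n_frames),
        photons=np.full(n_frames, 5000.0),
        meta={
            "dt_s": frame_interval_s,
            "temperature_C": temperature_c,
            "seed": seed,
            "true_step_times_s": step_times,
            "true_step_sizes_nm": step_sizes,
            "true_dwells_s": dwells,
            "dwell_rate_s": dwell_rate_s,
        },
    )


def simulate_dwells(
    model_id: str, params: dict, n: int, seed: int = 0
) -> DwellSample:
    """I.i.d. dwell times from the requested law.

    ``erlang2``: sum of two equal-rate exponentials, params ``{"k": rate}``.
    ``single_exp``: one exponential, params ``{"k": rate}``.
    ``cycle``: waiting times of a chemomechanical cycle, params
    ``{"model": CycleModel}`` (delegates to :mod:`dyntrack.cyclesim`).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    temperature = params.get("temperature_c")
    if model_id == "erlang2":
        k = float(params["k"])
        if k <= 0:
            raise ValueError("rate must be > 0")
        d = rng.gamma(shape=2.0, scale=1.0 / k, size=n)
    elif model_id == "single_exp":
        k = float(params["k"])
        if k <= 0:
            raise ValueError("rate must be > 0")
        d = rng.exponential(1.0 / k, size=n)
    elif model_id == "cycle":
        from . import cyclesim  # local import: cyclesim imports DwellSample from here

        return cyclesim.sample_cycle_dwells(params["model"], n, seed=seed)
    else:
        raise ValueError(f"unknown dwell model {model_id!r}")
    return DwellSample(dwells_s=d, temperature_c=temperature)
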