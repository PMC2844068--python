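"""Agent-based pollen-tube growth simulator.

Each virtual tube carries a position, a growth rate and a unit growth
direction.  Per time step (dt = 0.1 min by default) the tube is advanced
ballistically, the attractant field is evaluated at the advanced position
and time, and the direction is rotated by a Langevin turn

    d_theta = kappa' * delta_c * dt + sqrt(2 v dt / L) * z,      z ~ N(0, 1)

whose drift follows the across-tip concentration difference (toggle T) and
whose diffusive part is calibrated so that the tangent direction
decorrelates over the persistence length L independently of dt.  With the
slowing response enabled (toggle S) the rate relaxes exponentially toward
the minimal rate with a timescale set by the perceived concentration
difference:

    dv/dt = -(1/tau) * (v - v_min) * k_v |delta_c| / (1 + k_v |delta_c|),

which reproduces the periodic-adjustment update
``v_new = v_min + (v_old - v_min)/(k_v delta_c + 1)`` over a ~20 min
sampling interval and is stable for any dt.  A fixed-noise variant computes
the random-turn variance at the initial rate throughout, decoupling the
noise amplitude from slowing.

Tubes are marked captured when their tip comes within the capture radius of
a micropyle and escaped when they grow beyond the escape radius from the
style-exit origin; resolved tubes never move again.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .field import AttractantParams
from .io import OvuleSet


@dataclass
class MotilityParams:
    """Growth-rate and random-turn parameters of a pollen tube.

    v_init : initial growth rate, µm/min.
    v_min : minimal growth rate near a strong source, µm/min.
    L : persistence length of undirected growth, µm.
    k_v : slowing sensitivity, 1/(dimensionless concentration).
    tau : slowing timescale, min.
    noise_mode : 'rate-coupled' scales the random-turn variance with the
        instantaneous rate (2 v dt / L); 'fixed-at-v-init' keeps it at the
        initial rate (the (*) simulation variant).
    """

    v_init: float = 2.76
    v_min: float = 0.5
    L: float = 1042.70
    k_v: float = 533.39
    tau: float = 19.20
    noise_mode: str = "rate-coupled"

    def __post_init__(self) -> None:
        if not (self.v_init >= self.v_min > 0):
            raise ValidationError("need v_init >= v_min > 0")
        if self.L <= 0:
            raise ValidationError("persistence length must be positive")
        if self.noise_mode not in ("rate-coupled", "fixed-at-v-init"):
            raise ValidationError(f"unknown noise_mode {self.noise_mode!r}")


@dataclass
class SimConfig:
    """Configuration of one simulation run.

    ``initial_positions``/``initial_directions`` give the starting state of
    each tube (directions need not be normalised).  ``duration=None`` runs
    until every tube is captured or escaped (bounded by ``max_time``).
    """

    ovules: OvuleSet
    initial_positions: np.ndarray
    initial_directions: np.ndarray
    dt: float = 0.1
    capture_radius: float = 10.0
    escape_radius: float = 800.0
    duration: float | None = None
    max_time: float = 4000.0
    turning: bool = True
    slowing: bool = True
    seed: int | None = None
    record_interval: float = 20.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if not self.capture_radius < self.escape_radius:
            raise ConfigError("capture radius must be below the escape radius")
        self.initial_positions = np.atleast_2d(np.asarray(self.initial_positions, float))
        self.initial_directions = np.atleast_2d(np.asarray(self.initial_directions, float))
        if self.initial_positions.shape != self.initial_directions.shape:
            raise ConfigError("positions and directions must have matching shapes")

    @property
    def n_tubes(self) -> int:
        return len(self.initial_positions)


ACTIVE, CAPTURED, ESCAPED = 0, 1, 2


@dataclass
class SimResult:
    """Outcome of a simulation: decimated paths plus per-tube bookkeeping."""

    paths: pd.DataFrame  # tube_id, t_min, x_um, y_um (recorded cadence)
    status: np.ndarray  # per tube: ACTIVE / CAPTURED / ESCAPED
    capture_times: np.ndarray  # min; NaN unless captured
    captured_by: np.ndarray  # ovule row index; -1 unless captured
    n_tubes: int
    end_time: float

    @property
    def n_captured(self) -> int:
        return int(np.sum(self.status == CAPTURED))

    @property
    def n_escaped(self) -> int:
        return int(np.sum(self.status == ESCAPED))


def simulate(
    config: SimConfig,
    attractant: AttractantParams,
    motility: MotilityParams,
) -> SimResult:
    """Run the growth model for every tube in the configuration."""
    n = config.n_tubes
    dt = config.dt
    if motility.v_init * dt > config.capture_radius:
        warnings.warn("dt * v exceeds the capture radius: tunneling risk", stacklevel=2)
    rng = np.random.default_rng(config.seed)

    pos = config.initial_positions.copy()
    norms = np.hypot(config.initial_directions[:, 0], config.initial_directions[:, 1])
    if np.any(norms == 0):
        raise ConfigError("initial directions must be non-zero")
    direction = config.initial_directions / norms[:, None]
    v = np.full(n, motility.v_init)
    status = np.full(n, ACTIVE, dtype=int)
    capture_times = np.full(n, np.nan)
    captured_by = np.full(n, -1, dtype=int)

    mp = config.ovules.positions  # (k, 2)
    offsets = config.ovules.incubation_offsets
    if len(mp) == 0 and config.turning:
        raise ConfigError("turning requested but no ovules present")
    center = np.asarray(config.center, float)

    t_end = config.duration if config.duration is not None else config.max_time
    n_steps = int(round(t_end / dt))
    record_every = max(1, int(round(config.record_interval / dt)))

    rec_t = [0.0]
    rec_xy = [pos.copy()]
    t = 0.0
    for step in range(1, n_steps + 1):
        active = status == ACTIVE
        if not active.any():
            break
        t = step * dt
        # step 2: advance along the previous direction
        pos[active] += direction[active] * (v[active, None] * dt)

        # step 3: field at the advanced position and time
        if len(mp) > 0:
            ages = np.maximum(t + offsets, 0.0)
            dx = mp[None, :, 0] - pos[active, None, 0]
            dy = mp[None, :, 1] - pos[active, None, 1]
            r = np.hypot(dx, dy)
            rr = r + attractant.r0
            safe_ages = np.where(ages > 0, ages, 1.0)
            g = np.exp(-(rr**2) / (4.0 * attractant.D * safe_ages[None, :]))
            g /= 2.0 * np.pi * rr
            g = np.where(ages[None, :] > 0, g, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                inv_r = np.where(r > 0, 1.0 / r, 0.0)
            # cross(dir, u_ov): positive when the ovule is on the left
            sin_mp = (direction[active, 0, None] * dy - direction[active, 1, None] * dx) * inv_r
            delta_c = np.sum(g * sin_mp, axis=1)
        else:
            delta_c = np.zeros(int(active.sum()))

        # step 4: Langevin turn (drift zeroed when turning is off)
        v_noise = v[active] if motility.noise_mode == "rate-coupled" else np.full(
            int(active.sum()), motility.v_init
        )
        z = rng.standard_normal(n)[active]
        d_theta = np.sqrt(2.0 * v_noise * dt / motility.L) * z
        if config.turning:
            d_theta = d_theta + attractant.kappa_prime * delta_c * dt

        # step 5: slowing response (exact exponential relaxation over dt)
        if config.slowing:
            x = motility.k_v * np.abs(delta_c)
            rate = x / ((1.0 + x) * motility.tau)
            v[active] = motility.v_min + (v[active] - motility.v_min) * np.exp(-rate * dt)

        # step 6: rotate the direction
        cos_t, sin_t = np.cos(d_theta), np.sin(d_theta)
        dx_dir = direction[active, 0]
        dy_dir = direction[active, 1]
        direction[active, 0] = cos_t * dx_dir - sin_t * dy_dir
        direction[active, 1] = sin_t * dx_dir + cos_t * dy_dir

        # step 7: capture / escape at the new position
        if len(mp) > 0:
            d_mp = np.hypot(
                mp[None, :, 0] - pos[active, None, 0],
                mp[None, :, 1] - pos[active, None, 1],
            )
            nearest = np.argmin(d_mp, axis=1)
            d_nearest = d_mp[np.arange(len(nearest)), nearest]
        else:
            nearest = np.zeros(int(active.sum()), dtype=int)
            d_nearest = np.full(int(active.sum()), np.inf)
        d_center = np.hypot(pos[active, 0] - center[0], pos[active, 1] - center[1])
        idx = np.flatnonzero(active)
        caught = d_nearest <= config.capture_radius
        gone = (d_center >= config.escape_radius) & ~caught
        status[idx[caught]] = CAPTURED
        capture_times[idx[caught]] = t
        captured_by[idx[caught]] = nearest[caught]
        status[idx[gone]] = ESCAPED

        if step % record_every == 0:
            rec_t.append(t)
            rec_xy.append(pos.copy())

    frames = []
    times = np.asarray(rec_t)
    for j in range(n):
        frames.append(
            pd.DataFrame(
                {
                    "tube_id": f"sim{j:04d}",
                    "t_min": times,
                    "x_um": [xy[j, 0] for xy in rec_xy],
                    "y_um": [xy[j, 1] for xy in rec_xy],
                }
            )
        )
    paths = pd.concat(frames, ignore_index=True)
    return SimResult(paths, status, capture_times, captured_by, n, t)


def targeting_fraction(result: SimResult) -> float:
    """Fraction of tubes whose tip reached the capture radius of a micropyle."""
    return result.n_captured / result.n_tubes


def bootstrap_initial_conditions(
    observed_positions: np.ndarray,
    observed_directions: np.ndarray,
    n_tubes: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (position, direction) pairs uniformly with replacement."""
    observed_positions = np.atleast_2d(np.asarray(observed_positions, float))
    observed_directions = np.atleast_2d(np.asarray(observed_directions, float))
    if len(observed_positions) == 0:
        raise ValidationError("empty pool of initial conditions")
    if observed_positions.shape != observed_directions.shape:
        raise ValidationError("positions and directions must match in shape")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(observed_positions), size=n_tubes)
    return observed_positions[idx].copy(), observed_directions[idx].copy()
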