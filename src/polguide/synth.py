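"""Synthetic semi-in-vitro datasets.

The generator emulates the statistical structure of the tracked microscopy
data so every downstream analysis stage can be exercised without the (never
deposited) experimental trajectories:

* ovules are placed in a fan (uniform on an arc of +/-60 degrees about the
  style axis) at radial distances of ~430 +/- 20 µm from the style exit,
  matching the reported starting distances for the 4-hour condition;
* tubes start at the style exit with directions drawn from a Gaussian fan
  (SD 15 degrees) about the style axis, mirroring tubes that emerge from
  the transmitting tract already oriented toward the ovule field;
* trajectories are produced by the full growth simulator at dt = 0.1 min,
  sampled at the 20-min imaging cadence, with independent isotropic
  Gaussian position noise (SD 4 µm, the tracking error) added to each
  recorded coordinate — measurement noise only, the process noise being the
  Langevin term itself;
* penetration times of synthetic ovules are the first capture times
  recorded by the simulator.

A small helper also fabricates per-slice fluorescence profiles (smooth
background plus a sharp surface peak) for exercising the Z-drift
registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .field import AttractantParams
from .io import OvuleSet, StackProfile, TrajectorySet
from .sim import MotilityParams, SimConfig, SimResult, simulate

OVULE_ARC_HALF_ANGLE = np.deg2rad(60.0)
TUBE_FAN_SD = np.deg2rad(15.0)


@dataclass
class SynthConfig:
    """Stated world of the synthetic assay (defaults follow the 4-h condition)."""

    n_tubes: int = 30
    n_ovules: int = 3
    start_distance_mean: float = 430.16
    start_distance_sd: float = 20.19
    incubation_offset: float = 270.0  # ovule age at imaging start, min (4-h condition)
    attractant: AttractantParams = field(default_factory=AttractantParams)
    motility: MotilityParams = field(default_factory=MotilityParams)
    position_noise_sd: float = 4.0
    sampling_interval: float = 20.0
    duration: float = 320.0
    turning: bool = True
    slowing: bool = True
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("start_distance_mean", "sampling_interval", "duration", "dt"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.start_distance_sd < 0 or self.position_noise_sd < 0:
            raise ConfigError("scales must be non-negative")
        if self.n_ovules == 0 and self.turning:
            raise ConfigError("turning (attraction) requested but n_ovules = 0")


def generate_geometry(
    config: SynthConfig,
) -> tuple[OvuleSet, np.ndarray, np.ndarray]:
    """Sample ovule positions and initial tube states.

    Returns ``(ovules, initial_positions, initial_directions)``.  The style
    exit is the origin; the mean initial growth direction is +x.
    """
    rng = np.random.default_rng(config.seed)
    angles = rng.uniform(-OVULE_ARC_HALF_ANGLE, OVULE_ARC_HALF_ANGLE, config.n_ovules)
    dists = rng.normal(config.start_distance_mean, config.start_distance_sd, config.n_ovules)
    dists = np.clip(dists, 1.0, None)
    ovules = OvuleSet(
        pd.DataFrame(
            {
                "ovule_id": [f"ov{k}" for k in range(config.n_ovules)],
                "x_um": dists * np.cos(angles),
                "y_um": dists * np.sin(angles),
                "functional": True,
                "incubation_offset_min": config.incubation_offset,
                "penetration_time_min": np.nan,
            }
        )
    )
    tube_angles = rng.normal(0.0, TUBE_FAN_SD, config.n_tubes)
    init_pos = np.zeros((config.n_tubes, 2))
    init_dir = np.column_stack([np.cos(tube_angles), np.sin(tube_angles)])
    return ovules, init_pos, init_dir


def generate_trajectories(
    config: SynthConfig,
) -> tuple[TrajectorySet, OvuleSet, SimResult]:
    """Simulate tubes and record them like a tracked time-lapse.

    The simulator runs at ``config.dt`` for the full imaging duration (no
    early stop); positions are sampled at the imaging cadence and perturbed
    by the measurement-noise model.  Returns the noisy trajectory set, the
    ovule set with simulated penetration times filled in, and the raw
    simulation result.
    """
    ovules, init_pos, init_dir = generate_geometry(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sim_config = SimConfig(
        ovules=ovules,
        initial_positions=init_pos,
        initial_directions=init_dir,
        dt=config.dt,
        duration=config.duration,
        turning=config.turning,
        slowing=config.slowing,
        seed=int(rng.integers(2**31)),
        record_interval=config.sampling_interval,
    )
    result = simulate(sim_config, config.attractant, config.motility)

    # truncate each tube at its capture/escape: tracking ends when a tube
    # penetrates an ovule or leaves the field (frozen positions would
    # otherwise turn into spurious jitter-only steps once noise is added)
    paths = result.paths.copy()
    resolve_time = np.full(result.n_tubes, np.inf)
    resolved = result.status != 0
    resolve_time[resolved] = np.where(
        np.isfinite(result.capture_times[resolved]),
        result.capture_times[resolved],
        config.duration,
    )
    tube_ids = paths["tube_id"].unique()
    cutoff = {
        tid: np.ceil(resolve_time[j] / config.sampling_interval) * config.sampling_interval
        for j, tid in enumerate(tube_ids)
    }
    paths = paths[paths["t_min"] <= paths["tube_id"].map(cutoff)].reset_index(drop=True)
    # escaped tubes: freeze time unknown at 20-min resolution; drop trailing
    # duplicate positions instead
    keep = np.ones(len(paths), bool)
    for tid, grp in paths.groupby("tube_id", sort=False):
        xy = grp[["x_um", "y_um"]].to_numpy()
        same = np.all(xy == xy[-1], axis=1)
        # last index where the tube still moved
        moving = np.flatnonzero(~same)
        last = moving[-1] + 1 if len(moving) else 0
        keep[grp.index[last + 1 :]] = False
    paths = paths[keep].reset_index(drop=True)
    paths = paths.groupby("tube_id", sort=False).filter(lambda g: len(g) >= 2)
    if config.position_noise_sd > 0:
        noise = rng.normal(0.0, config.position_noise_sd, size=(len(paths), 2))
        paths[["x_um", "y_um"]] += noise
    traj = TrajectorySet(
        paths,
        position_noise_sd=config.position_noise_sd,
        sampling_interval=config.sampling_interval,
    )

    pen = np.full(len(ovules), np.nan)
    for k in range(len(ovules)):
        hits = result.capture_times[result.captured_by == k]
        if len(hits):
            pen[k] = np.nanmin(hits)
    return traj, ovules.with_penetration_times(pen), result


def generate_profiles(
    n_slices: int,
    true_shift: int,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> tuple[StackProfile, StackProfile]:
    """A smooth stack profile with a sharp surface peak, plus a shifted copy.

    The moving profile shows every feature ``true_shift`` slices deeper than
    the reference (positive shift = drift toward higher Z).  Optional
    additive Gaussian noise is expressed in intensity units (the surface
    peak has height ~1 above a background of ~0.2).
    """
    if abs(true_shift) >= n_slices / 2:
        raise ConfigError("|true_shift| must be below half the stack depth")
    rng = np.random.default_rng(seed)
    z = np.arange(n_slices, dtype=float)
    peak_at = n_slices / 2.0

    def profile(center: float) -> np.ndarray:
        background = 0.2 * np.exp(-0.5 * ((z - center) / (n_slices / 3.0)) ** 2)
        surface = np.exp(-0.5 * ((z - center) / 1.2) ** 2)
        return background + surface

    ref = profile(peak_at)
    mov = profile(peak_at + true_shift)
    if noise_sd > 0:
        ref = np.clip(ref + rng.normal(0, noise_sd, n_slices), 0, None)
        mov = np.clip(mov + rng.normal(0, noise_sd, n_slices), 0, None)
    return StackProfile(ref, "reference"), StackProfile(mov, "moving")


def replicate_configs(config: SynthConfig, n_replicates: int) -> list[SynthConfig]:
    """Independent replicate geometries: same stated world, distinct seeds."""
    return [replace(config, seed=config.seed + 1000 * (i + 1)) for i in range(n_replicates)]


def generate_condition_series(
    config: SynthConfig,
    incubation_offsets: tuple[float, ...] = (30.0, 150.0, 270.0),
    separation: float = 1e5,
) -> tuple[TrajectorySet, OvuleSet]:
    """Pooled dataset spanning several ovule incubation conditions.

    One independent replicate dish per incubation offset (the 0/2/4-hour
    conditions correspond to source ages of 30/150/270 min at imaging
    start), shifted ``separation`` µm apart so dishes cannot interact.
    Pooling conditions with different source ages is what makes the three
    field parameters separately identifiable: a single age leaves kappa',
    D and r0 strongly covariant.
    """
    traj_frames, ovule_frames = [], []
    for i, offset in enumerate(incubation_offsets):
        cfg = replace(config, incubation_offset=float(offset), seed=config.seed + 1000 * i)
        traj, ovules, _ = generate_trajectories(cfg)
        td = traj.data.copy()
        td["tube_id"] = td["tube_id"].astype(str) + f"_c{i}"
        td["y_um"] += i * separation
        od = ovules.data.copy()
        od["ovule_id"] = od["ovule_id"].astype(str) + f"_c{i}"
        od["y_um"] += i * separation
        traj_frames.append(td)
        ovule_frames.append(od)
    pooled_traj = TrajectorySet(
        pd.concat(traj_frames, ignore_index=True),
        position_noise_sd=config.position_noise_sd,
        sampling_interval=config.sampling_interval,
    )
    pooled_ovules = OvuleSet(pd.concat(ovule_frames, ignore_index=True))
    return pooled_traj, pooled_ovules
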