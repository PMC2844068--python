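"""Domain containers and flat-file I/O.

Tracked pollen-tube tip positions and ovule (micropyle) coordinates are
exchanged as plain CSV.  All coordinates are continuous micrometres in the
plane of the medium surface (projected confocal slices), with y increasing
upward.  Times are minutes from the start of imaging.

Also implements the confocal Z-drift correction: each stack is summarised by
a per-slice total-fluorescence profile, and stacks are registered to a
reference stack by the integer slice shift that minimises the mismatch of
their normalised adjacent-slice intensity differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import FormatError, UndefinedStatisticError, ValidationError

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ["tube_id", "t_min", "x_um", "y_um"]
OVULE_COLUMNS = [
    "ovule_id",
    "x_um",
    "y_um",
    "functional",
    "incubation_offset_min",
    "penetration_time_min",
]
PROFILE_COLUMNS = ["stack_id", "z_index", "intensity"]


@dataclass
class TrajectorySet:
    """Time-stamped 2D tip positions for a set of pollen tubes.

    Parameters
    ----------
    data
        Long-format table with columns ``tube_id, t_min, x_um, y_um``.
    position_noise_sd
        Isotropic standard error of the tracked tip positions, µm.  The
        default of 4 µm corresponds to a 2-pixel tracking box.
    sampling_interval
        Time between consecutive samples, minutes (confocal cadence).
    """

    data: pd.DataFrame
    position_noise_sd: float = 4.0
    sampling_interval: float = 20.0

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"trajectory table missing columns: {missing}")
        df = self.data.loc[:, TRAJECTORY_COLUMNS].copy()
        if len(df) == 0:
            raise ValidationError("trajectory table contains no samples")
        df = df.sort_values(["tube_id", "t_min"], kind="mergesort").reset_index(drop=True)
        for tube_id, grp in df.groupby("tube_id", sort=False):
            t = grp["t_min"].to_numpy(float)
            if len(t) < 2:
                raise ValidationError(f"tube {tube_id!r} has fewer than 2 samples")
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValidationError(
                    f"tube {tube_id!r} has non-increasing (or duplicated) times"
                )
            if not np.allclose(dt, self.sampling_interval, rtol=1e-6, atol=1e-6):
                raise ValidationError(
                    f"tube {tube_id!r} is not uniformly sampled at "
                    f"{self.sampling_interval} min"
                )
        self.data = df

    @property
    def tube_ids(self) -> list:
        return list(dict.fromkeys(self.data["tube_id"]))

    @property
    def n_tubes(self) -> int:
        return self.data["tube_id"].nunique()

    def tubes(self) -> Iterator[tuple[object, np.ndarray, np.ndarray]]:
        """Yield ``(tube_id, t, xy)`` with ``xy`` of shape (n, 2)."""
        for tube_id, grp in self.data.groupby("tube_id", sort=False):
            yield tube_id, grp["t_min"].to_numpy(float), grp[["x_um", "y_um"]].to_numpy(float)

    def with_positions(self, xy_by_tube: dict) -> "TrajectorySet":
        """Return a copy with positions replaced per tube (same time stamps)."""
        df = self.data.copy()
        for tube_id, xy in xy_by_tube.items():
            mask = df["tube_id"] == tube_id
            df.loc[mask, ["x_um", "y_um"]] = np.asarray(xy, float)
        return TrajectorySet(df, self.position_noise_sd, self.sampling_interval)


@dataclass
class OvuleSet:
    """Micropyle positions plus per-ovule bookkeeping.

    ``incubation_offset_min`` is the time the ovule had been releasing
    attractant on the medium before imaging started, so the diffusion age of
    the source at imaging time ``t`` is ``t + incubation_offset_min``.
    ``penetration_time_min`` is NaN for ovules never penetrated; heat-treated
    (non-functional) ovules must never carry a penetration time.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in OVULE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"ovule table missing columns: {missing}")
        df = self.data.loc[:, OVULE_COLUMNS].copy()
        df["functional"] = df["functional"].astype(bool)
        df["penetration_time_min"] = pd.to_numeric(df["penetration_time_min"])
        if (df["incubation_offset_min"] < 0).any():
            raise ValidationError("incubation_offset_min must be non-negative")
        bad = (~df["functional"]) & df["penetration_time_min"].notna()
        if bad.any():
            raise ValidationError(
                "heat-treated (non-functional) ovules cannot have a penetration time"
            )
        if len(df) == 0:
            logger.warning("ovule table is empty")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def positions(self) -> np.ndarray:
        """Micropyle coordinates, shape (n_ovules, 2)."""
        return self.data[["x_um", "y_um"]].to_numpy(float)

    @property
    def incubation_offsets(self) -> np.ndarray:
        return self.data["incubation_offset_min"].to_numpy(float)

    def with_penetration_times(self, times: np.ndarray) -> "OvuleSet":
        df = self.data.copy()
        df["penetration_time_min"] = np.asarray(times, float)
        return OvuleSet(df)


@dataclass
class StackProfile:
    """Per-slice total fluorescence I(Z) of one confocal stack."""

    values: np.ndarray
    stack_id: str = "stack"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 1 or len(v) < 2:
            raise ValidationError("profile needs at least 2 slices")
        if np.any(v < 0):
            raise ValidationError("fluorescence values must be non-negative")
        self.values = v

    def normalized_differences(self) -> np.ndarray:
        """Adjacent-slice differences of the max-normalised profile."""
        peak = self.values.max()
        if peak <= 0:
            raise UndefinedStatisticError(f"stack {self.stack_id!r}: all-zero profile")
        norm = self.values / peak
        return np.diff(norm)


# ---------------------------------------------------------------------------
# CSV readers / writers


def read_trajectories(
    path: str | Path,
    position_noise_sd: float = 4.0,
    sampling_interval: float = 20.0,
) -> TrajectorySet:
    """Read a ``tube_id,t_min,x_um,y_um`` CSV into a :class:`TrajectorySet`."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["tube_id", "t_min"])
    if dup.any():
        raise ValidationError(f"{path}: duplicated (tube_id, t_min) rows")
    return TrajectorySet(df, position_noise_sd, sampling_interval)


def write_trajectories(traj: TrajectorySet, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        traj.data.to_csv(fh, index=False)


def read_ovules(path: str | Path) -> OvuleSet:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in OVULE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        warnings.warn(f"{path}: no ovules in file", stacklevel=2)
    return OvuleSet(df)


def write_ovules(ovules: OvuleSet, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        ovules.data.to_csv(fh, index=False)


def read_profiles(path: str | Path) -> dict[str, StackProfile]:
    """Read a ``stack_id,z_index,intensity`` CSV into profiles keyed by stack."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = {}
    for stack_id, grp in df.groupby("stack_id", sort=False):
        grp = grp.sort_values("z_index")
        out[str(stack_id)] = StackProfile(grp["intensity"].to_numpy(float), str(stack_id))
    return out


def write_profiles(profiles: dict[str, StackProfile], path: str | Path) -> None:
    rows = []
    for stack_id, prof in profiles.items():
        for z, val in enumerate(prof.values):
            rows.append((stack_id, z, val))
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stack alignment


def peak_peak_difference(
    reference: StackProfile, moving: StackProfile, shift: int
) -> float:
    """Mismatch Q between the normalised difference-profiles at a given shift.

    Q is the sum of squared differences between the two difference-profiles
    over their overlap, with the moving profile displaced by ``shift`` slices.
    A positive shift means features of the reference appear ``shift`` slices
    deeper (at higher Z index) in the moving stack.  Out-of-overlap slices
    are excluded rather than zero-padded.
    """
    d_ref = reference.normalized_differences()
    d_mov = moving.normalized_differences()
    n_ref, n_mov = len(d_ref), len(d_mov)
    # overlap: compare d_ref[i] with d_mov[i + shift]
    i_lo = max(0, -shift)
    i_hi = min(n_ref, n_mov - shift)
    if i_hi <= i_lo:
        return np.inf
    a = d_ref[i_lo:i_hi]
    b = d_mov[i_lo + shift : i_hi + shift]
    return float(np.sum((a - b) ** 2))


def align_stack(reference: StackProfile, moving: StackProfile, max_shift: int) -> int:
    """Integer Z-drift of ``moving`` relative to ``reference``.

    Searches shifts in ``[-max_shift, +max_shift]`` and returns the one
    minimising the peak-peak difference Q of the normalised adjacent-slice
    intensity differences.  Ties prefer the smallest ``|shift|`` (i.e. no
    correction when the evidence is ambiguous).
    """
    if max_shift >= min(len(reference.values), len(moving.values)):
        raise ValidationError("max_shift must be smaller than the profile length")
    d_ref = reference.normalized_differences()
    d_mov = moving.normalized_differences()
    if np.allclose(d_ref, 0) or np.allclose(d_mov, 0):
        raise UndefinedStatisticError("flat profile: alignment is undefined")
    shifts = np.arange(-max_shift, max_shift + 1)
    scores = [peak_peak_difference(reference, moving, int(s)) for s in shifts]
    order = sorted(range(len(shifts)), key=lambda i: (scores[i], abs(shifts[i]), shifts[i]))
    return int(shifts[order[0]])
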