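"""Angle extraction and circular statistics.

Turning behaviour is described by three signed angles per interior time
point of a tube:

* ``theta_tip`` — the turn the tube makes, i.e. the signed angle from the
  current growth direction ``v_cur(t) = r(t) - r(t - dt)`` to the new
  direction ``v_new(t) = r(t + dt) - r(t)``;
* ``theta_mp``  — the turn that would aim the tube straight at the nearest
  micropyle, i.e. the signed angle from ``v_cur`` to the tip-to-micropyle
  vector;
* ``delta_theta = theta_mp - theta_tip`` — the deviation of the realised
  turn from the direct path.

Counter-clockwise turns are positive, so ``theta_mp > 0`` when the
micropyle lies to the left of the growth direction.  All angles are wrapped
to (-pi, pi].

Because angles are periodic they are summarised with circular statistics:
each angle maps to a unit vector, the mean direction is the direction of
the resultant, and the spread is ``sigma0 = sqrt(-2 ln R)`` where R is the
mean resultant length (the wrapped-normal correspondence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .io import OvuleSet, TrajectorySet

ANGLE_COLUMNS = [
    "tube_id",
    "t_min",
    "x_um",
    "y_um",
    "dir_x",
    "dir_y",
    "l1_um",
    "l2_um",
    "rate_um_min",
    "theta_tip_rad",
    "theta_mp_rad",
    "delta_theta_rad",
    "distance_um",
    "nearest_ovule",
    "approaching",
    "pre_penetration",
]


def wrap_angle(theta):
    """Wrap angle(s) to the interval (-pi, pi]."""
    wrapped = np.mod(-np.asarray(theta) + np.pi, 2 * np.pi)
    return -(wrapped - np.pi)


def signed_angle(v_from: np.ndarray, v_to: np.ndarray):
    """Signed angle rotating ``v_from`` onto ``v_to`` (CCW positive)."""
    v_from = np.asarray(v_from, float)
    v_to = np.asarray(v_to, float)
    cross = v_from[..., 0] * v_to[..., 1] - v_from[..., 1] * v_to[..., 0]
    dot = v_from[..., 0] * v_to[..., 0] + v_from[..., 1] * v_to[..., 1]
    return np.arctan2(cross, dot)


@dataclass
class AngleSeries:
    """Per-(tube, time) angle observations, the substrate of all analyses.

    Wraps a long-format table (one row per interior time point) carrying the
    three angles, the tip position and current direction at the interval
    start, both segment lengths (for error propagation), the distance to the
    nearest micropyle and bookkeeping flags.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANGLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"angle table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "AngleSeries":
        return AngleSeries(self.data.loc[mask].reset_index(drop=True))


@dataclass
class CircularSummary:
    mean_direction: float
    R: float
    sigma0: float
    n: int


def extract_angles(traj: TrajectorySet, ovules: OvuleSet) -> AngleSeries:
    """Compute the angle series of a trajectory set against an ovule set.

    The nearest micropyle is chosen by Euclidean distance at time ``t``
    (ties broken by ovule order).  ``pre_penetration`` is True when that
    ovule is functional, eventually penetrated, and not yet penetrated at
    ``t`` (strict inequality).  Zero-length steps make the turn undefined;
    such samples are dropped with a warning.
    """
    if len(ovules) == 0:
        raise ValidationError("need at least one ovule to define theta_mp")
    mp = ovules.positions
    pen = ovules.data["penetration_time_min"].to_numpy(float)
    functional = ovules.data["functional"].to_numpy(bool)
    rows = []
    n_dropped = 0
    for tube_id, t, xy in traj.tubes():
        if len(t) < 3:
            continue
        steps = np.diff(xy, axis=0)
        lengths = np.hypot(steps[:, 0], steps[:, 1])
        for i in range(1, len(t) - 1):
            v_cur = steps[i - 1]
            v_new = steps[i]
            if lengths[i - 1] == 0 or lengths[i] == 0:
                n_dropped += 1
                continue
            d = np.hypot(mp[:, 0] - xy[i, 0], mp[:, 1] - xy[i, 1])
            k = int(np.argmin(d))
            v_ov = mp[k] - xy[i]
            theta_tip = signed_angle(v_cur, v_new)
            theta_mp = signed_angle(v_cur, v_ov)
            rows.append(
                (
                    tube_id,
                    t[i],
                    xy[i, 0],
                    xy[i, 1],
                    v_cur[0] / lengths[i - 1],
                    v_cur[1] / lengths[i - 1],
                    lengths[i - 1],
                    lengths[i],
                    lengths[i] / (t[i + 1] - t[i]),
                    theta_tip,
                    theta_mp,
                    wrap_angle(theta_mp - theta_tip),
                    d[k],
                    ovules.data["ovule_id"].iloc[k],
                    np.cos(theta_mp) >= 0,
                    bool(
                        functional[k]
                        and np.isfinite(pen[k])
                        and t[i] < pen[k]
                    ),
                )
            )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} samples with zero-length steps (angle undefined)",
            stacklevel=2,
        )
    return AngleSeries(pd.DataFrame(rows, columns=ANGLE_COLUMNS))


def _resultant(angles: np.ndarray) -> tuple[float, float]:
    angles = np.asarray(angles, float)
    if angles.size == 0:
        raise UndefinedStatisticError("empty angle sample")
    c = np.mean(np.cos(angles))
    s = np.mean(np.sin(angles))
    return float(np.hypot(c, s)), float(np.arctan2(s, c))


def circ_mean(angles) -> float:
    """Mean direction: direction of the resultant of the unit vectors."""
    R, direction = _resultant(angles)
    if R < 1e-12:
        raise UndefinedStatisticError("zero resultant: mean direction undefined")
    return direction


def circ_R(angles) -> float:
    """Mean resultant length R in [0, 1]."""
    R, _ = _resultant(angles)
    return R


def circ_sd(angles) -> float:
    """Circular standard deviation sigma0 = sqrt(-2 ln R), radians.

    Returns ``inf`` when R = 0 (uniform spread).  No small-sample correction
    is applied; this is the plain wrapped-normal correspondence.
    """
    R = circ_R(angles)
    if R <= 1e-12:  # resultant of zero up to rounding
        return np.inf
    return float(np.sqrt(-2.0 * np.log(R)))


def circ_summary(angles) -> CircularSummary:
    angles = np.asarray(angles, float)
    R, direction = _resultant(angles)
    sigma0 = np.inf if R <= 0 else float(np.sqrt(-2.0 * np.log(R)))
    return CircularSummary(direction, R, sigma0, len(angles))


def bootstrap_se(
    angles,
    statistic: str = "mean",
    n_resamples: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap standard error of the circular mean or circular SD.

    Resamples with replacement; for the mean the spread of the resampled
    mean directions is measured after centring on the point estimate (so the
    value is a proper circular dispersion), for the SD it is the plain SD of
    the resampled sigma0 values.
    """
    angles = np.asarray(angles, float)
    if len(angles) < 2:
        raise ValidationError("need at least 2 angles for a bootstrap SE")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(angles), size=(n_resamples, len(angles)))
    samples = angles[idx]
    if statistic == "mean":
        c = np.mean(np.cos(samples), axis=1)
        s = np.mean(np.sin(samples), axis=1)
        means = np.arctan2(s, c)
        center = circ_mean(angles)
        dev = wrap_angle(means - center)
        return float(np.sqrt(np.mean(dev**2)))
    if statistic == "sd":
        c = np.mean(np.cos(samples), axis=1)
        s = np.mean(np.sin(samples), axis=1)
        R = np.hypot(c, s)
        with np.errstate(divide="ignore"):
            sds = np.sqrt(-2.0 * np.log(np.clip(R, 0, 1)))
        return float(np.std(sds))
    raise ValueError(f"unknown statistic {statistic!r}")


def perm_test_sd_ratio(
    a,
    b,
    n_perm: int = 10000,
    seed: int | None = None,
) -> float:
    """One-sided permutation test of log(sigma0[a]/sigma0[b]).

    Returns the plus-one-corrected fraction of label permutations whose
    statistic is at least the observed one; small p means sample ``a`` is
    significantly more dispersed than ``b``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    observed = np.log(circ_sd(a) / circ_sd(b))
    pooled = np.concatenate([a, b])
    n_a = len(a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = np.log(circ_sd(perm[:n_a]) / circ_sd(perm[n_a:]))
        if stat >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)


def angle_measurement_sd(l1: float, l2: float, sigma_pos: float) -> float:
    """Propagated measurement SD of an angle between two tracked segments.

    With isotropic position error ``sigma_pos`` on each endpoint and segment
    lengths ``l1`` and ``l2``:  sigma_theta^2 = (sigma/l1)^2 + (sigma/l2)^2.
    """
    l1 = np.asarray(l1, float)
    l2 = np.asarray(l2, float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValidationError("segment lengths must be positive")
    return np.sqrt((sigma_pos / l1) ** 2 + (sigma_pos / l2) ** 2)
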