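"""Continuous-release 2D diffusion field of the ovule attractant.

An ovule releases attractant at a constant rate from its micropyle, and the
attractant spreads by two-dimensional diffusion in the thin fluid film on
the medium surface.  The concentration around a single source that has been
releasing for time t, in prefactor-stripped units (the release-rate /
diffusivity prefactor k_p/D is absorbed into the turning constant kappa'),
is

    c(r, t) = (1 / 4 pi) * E1( (r + r0)^2 / (4 D t) )

where E1 is the exponential integral and r0 is an additive radial offset
accounting for diffusion over the ovule surface before deposition on the
medium (it also regularises the r -> 0 divergence of the point source).
The radial gradient magnitude, pointing toward the source, is

    g(r, t) = (1 / 2 pi) * exp( -(r + r0)^2 / (4 D t) ) / (r + r0).

At long times g approaches the steady 1/(2 pi (r + r0)) law, so the
gradient is maintained by the competition between release and diffusion.

The quantity the pollen tube senses is the concentration difference across
its tip.  With the tip width absorbed into kappa', this is the projection of
the (superposed, multi-ovule) gradient onto the tip-lateral axis:
``delta_c = sum_i g_i sin(theta_mp_i)``, positive when the net attractant
excess is on the left of the growth direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import exp1

from .errors import ValidationError
from .io import OvuleSet


@dataclass
class AttractantParams:
    """Parameters of the turning/attractant model.

    kappa_prime : effective turning constant kappa * (k_p / D),
        rad / (dimensionless concentration * min).
    D : diffusion constant of the attractant on the medium, µm^2/min.
    r0 : radial offset for surface diffusion on the ovule, µm.

    Defaults are the fitted values of the turning model.
    """

    kappa_prime: float = 40.11
    D: float = 66.72
    r0: float = 117.56

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValidationError("D must be positive")
        if self.r0 < 0:
            raise ValidationError("r0 must be non-negative")


def concentration(r, t, params: AttractantParams):
    """Dimensionless concentration at distance r from a source of age t.

    Vectorised over ``r`` and ``t``.  Zero before any release (t = 0).
    """
    r = np.asarray(r, float)
    t = np.asarray(t, float)
    if np.any(r < 0):
        raise ValidationError("r must be non-negative")
    if np.any(t < 0):
        raise ValidationError("t must be non-negative")
    rr = r + params.r0
    out = np.zeros(np.broadcast(r, t).shape)
    with np.errstate(divide="ignore"):
        arg = np.where(t > 0, rr**2 / (4.0 * params.D * np.where(t > 0, t, 1.0)), np.inf)
    np.copyto(out, exp1(arg) / (4.0 * np.pi), where=np.asarray(t > 0))
    return out if out.ndim else float(out)


def gradient(r, t, params: AttractantParams):
    """Radial gradient magnitude (toward the source), conc/µm.

    Vectorised over ``r`` and ``t``; returns 0 at t = 0.
    """
    r = np.asarray(r, float)
    t = np.asarray(t, float)
    if np.any(r < 0):
        raise ValidationError("r must be non-negative")
    if np.any(t < 0):
        raise ValidationError("t must be non-negative")
    rr = r + params.r0
    if np.all(rr <= 0):
        raise ValidationError("r + r0 must be positive for the gradient")
    safe_t = np.where(t > 0, t, 1.0)
    g = np.exp(-(rr**2) / (4.0 * params.D * safe_t)) / (2.0 * np.pi * rr)
    g = np.where(t > 0, g, 0.0)
    return g if g.ndim else float(g)


def source_gradients(
    pos: np.ndarray,
    t_now: float,
    ovules: OvuleSet,
    params: AttractantParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-ovule gradient magnitudes and unit direction vectors at ``pos``.

    ``pos`` has shape (n, 2).  Returns ``(g, ux, uy)`` each of shape
    (n, n_ovules), where the unit vector points from the tip toward the
    micropyle.  The diffusion age of ovule i at imaging/simulation time
    ``t_now`` is ``t_now + incubation_offset_i`` (clipped at 0).
    """
    pos = np.atleast_2d(np.asarray(pos, float))
    mp = ovules.positions
    ages = np.maximum(t_now + ovules.incubation_offsets, 0.0)
    dx = mp[None, :, 0] - pos[:, None, 0]
    dy = mp[None, :, 1] - pos[:, None, 1]
    r = np.hypot(dx, dy)
    rr = r + params.r0
    safe_ages = np.where(ages > 0, ages, 1.0)
    g = np.exp(-(rr**2) / (4.0 * params.D * safe_ages[None, :])) / (2.0 * np.pi * rr)
    g = np.where(ages[None, :] > 0, g, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, dx / r, 0.0)
        uy = np.where(r > 0, dy / r, 0.0)
    return g, ux, uy


def delta_c_tip(
    pos,
    growth_dir,
    ovules: OvuleSet,
    t_now: float,
    params: AttractantParams,
) -> float:
    """Signed concentration difference across the tip (lateral projection).

    Sums per-ovule gradients and projects onto the axis perpendicular to the
    growth direction; positive when the excess lies to the left (so a
    positive, counter-clockwise turn steers toward it).
    """
    pos = np.asarray(pos, float)
    d = np.asarray(growth_dir, float)
    norm = np.hypot(d[0], d[1])
    if norm == 0:
        raise ValidationError("growth direction must be non-zero")
    d = d / norm
    g, ux, uy = source_gradients(pos[None, :], t_now, ovules, params)
    sin_mp = d[0] * uy[0] - d[1] * ux[0]  # cross(dir, u): + when ovule on the left
    return float(np.sum(g[0] * sin_mp))
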