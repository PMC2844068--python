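"""Descriptive trajectory analyses.

Implements the four quantitative summaries of tracked tube growth:

* radial attraction frequencies: per 50-µm distance bin, the time-averaged
  frequency that a tip moved into a closer (``f_closer``) or farther
  (``f_farther``) bin by the next time point, with Bernoulli standard
  errors and chi-square comparisons across conditions;
* turning response: the slope A of the ordinary-least-squares line
  ``theta_tip = A sin(theta_mp) + eps`` in a distance band — the average
  tendency to turn toward the micropyle, proportional to the local
  attractant gradient;
* growth-rate profile: step speeds binned by distance to the nearest
  micropyle on a 5-µm grid with +/-5 µm windows;
* persistence length: tangent-direction correlation of spline-resampled
  paths, fit with the linear model ``<cos theta(ds)> = (1 + b) - ds / L``
  over the initial decay.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass

from scipy import stats
from scipy.interpolate import CubicSpline

from .circular import AngleSeries
from .errors import FitError, ValidationError
from .io import OvuleSet, TrajectorySet


# ---------------------------------------------------------------------------
# pre-penetration filter


def filter_pre_penetration(angles: AngleSeries, ovules: OvuleSet) -> AngleSeries:
    """Keep samples approaching a functional, eventually-but-not-yet
    penetrated ovule.

    A dataset with no functional ovules (the heat-treated control, which is
    never penetrated) passes through unfiltered, preserving the control
    semantics: it shows what unguided growth looks like in each statistic.
    """
    if not ovules.data["functional"].any():
        return angles
    return angles.subset(angles.data["pre_penetration"].to_numpy(bool))


# ---------------------------------------------------------------------------
# radial attraction frequencies


@dataclass
class FreqTable:
    """Per-radial-bin closer/farther counts and frequencies."""

    data: pd.DataFrame  # bin_lo_um, bin_hi_um, n_total, n_closer, n_farther, ...

    def __post_init__(self) -> None:
        d = self.data
        if ((d["n_closer"] + d["n_farther"]) > d["n_total"]).any():
            raise ValidationError("closer + farther counts exceed totals")

    @property
    def n_same(self) -> np.ndarray:
        d = self.data
        return (d["n_total"] - d["n_closer"] - d["n_farther"]).to_numpy()


def _step_distances(
    traj: TrajectorySet, ovules: OvuleSet, pre_penetration_only: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Distance to the nearest micropyle at t and, for the same micropyle,
    at t + dt, for every consecutive step of every tube."""
    mp = ovules.positions
    if len(mp) == 0:
        raise ValidationError("need at least one ovule")
    pen = ovules.data["penetration_time_min"].to_numpy(float)
    functional = ovules.data["functional"].to_numpy(bool)
    any_functional = functional.any()
    d_now, d_next = [], []
    for _, t, xy in traj.tubes():
        d = np.hypot(mp[None, :, 0] - xy[:, None, 0], mp[None, :, 1] - xy[:, None, 1])
        nearest = np.argmin(d, axis=1)
        for i in range(len(t) - 1):
            k = nearest[i]
            if pre_penetration_only and any_functional:
                if not (functional[k] and np.isfinite(pen[k]) and t[i] < pen[k]):
                    continue
            d_now.append(d[i, k])
            d_next.append(d[i + 1, k])
    return np.asarray(d_now), np.asarray(d_next)


def radial_frequencies(
    traj: TrajectorySet,
    ovules: OvuleSet,
    bin_width: float = 50.0,
    max_dist: float = 200.0,
    pre_penetration_only: bool = False,
) -> FreqTable:
    """Closer/farther transition frequencies per half-open radial bin.

    Each consecutive pair of time points contributes one observation binned
    by the distance to the nearest micropyle at the earlier time; it counts
    as closer (farther) when the distance to that same micropyle at the
    later time falls in a lower (higher) bin.  Same-bin transitions count
    toward the total only.  By default post-penetration points are included
    (for unbiased comparison with controls); the pre-penetration variant is
    available as a flag.
    """
    d_now, d_next = _step_distances(traj, ovules, pre_penetration_only)
    n_bins = int(np.ceil(max_dist / bin_width))
    rows = []
    bin_now = np.floor(d_now / bin_width).astype(int)
    bin_next = np.floor(d_next / bin_width).astype(int)
    for k in range(n_bins):
        in_bin = bin_now == k
        n_total = int(in_bin.sum())
        n_closer = int(np.sum(in_bin & (bin_next < k)))
        n_farther = int(np.sum(in_bin & (bin_next > k)))
        if n_total > 0:
            f_c, f_f = n_closer / n_total, n_farther / n_total
            se_c = np.sqrt(f_c * (1 - f_c) / n_total)
            se_f = np.sqrt(f_f * (1 - f_f) / n_total)
        else:
            f_c = f_f = se_c = se_f = np.nan
        rows.append(
            (k * bin_width, (k + 1) * bin_width, n_total, n_closer, n_farther,
             f_c, f_f, se_c, se_f)
        )
    return FreqTable(
        pd.DataFrame(
            rows,
            columns=[
                "bin_lo_um", "bin_hi_um", "n_total", "n_closer", "n_farther",
                "f_closer", "f_farther", "se_closer", "se_farther",
            ],
        )
    )


def chi2_frequency_test(
    tables: list[FreqTable], bin_index: int, outcome: str = "farther"
) -> float:
    """Chi-square test of one dichotomous outcome across conditions.

    Builds the 2 x k contingency table (outcome vs not, one column per
    condition) for the requested radial bin and returns the p-value of the
    uncorrected chi-square test; with two tables this is the pairwise 2 x 2
    comparison.
    """
    if len(tables) < 2:
        raise ValidationError("need at least two frequency tables")
    if outcome not in ("closer", "farther"):
        raise ValidationError("outcome must be 'closer' or 'farther'")
    yes, no = [], []
    for tab in tables:
        row = tab.data.iloc[bin_index]
        yes.append(row[f"n_{outcome}"])
        no.append(row["n_total"] - row[f"n_{outcome}"])
    contingency = np.array([yes, no], dtype=float)
    if np.any(contingency.sum(axis=0) == 0) or np.any(contingency.sum(axis=1) == 0):
        raise ValidationError("zero expected count in the contingency table")
    res = stats.chi2_contingency(contingency, correction=False)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# turning-response regression


@dataclass
class RegressionFit:
    A: float
    se_A: float
    epsilon: float
    se_epsilon: float
    pearson_r: float
    p_value: float
    n: int
    residual_sd: float
    residual_sd_trimmed: float


def turning_response(
    angles: AngleSeries,
    dist_lo: float,
    dist_hi: float,
    approaching_only: bool = False,
    iqr_trim_factor: float = 2.0,
) -> RegressionFit:
    """OLS fit of theta_tip on sin(theta_mp) within a distance band.

    The slope A is the mean turning response; the intercept eps should be
    indistinguishable from zero for unbiased turning.  The residual SD
    summarises the random component; a variant with residuals outside
    ``iqr_trim_factor`` times the inter-quartile range removed is also
    reported (used only where outliers dominate, e.g. nearest to the
    micropyle).
    """
    d = angles.data
    mask = (d["distance_um"] >= dist_lo) & (d["distance_um"] < dist_hi)
    if approaching_only:
        mask &= d["approaching"]
    sub = d.loc[mask]
    if len(sub) < 3:
        raise FitError(f"fewer than 3 samples in the band [{dist_lo}, {dist_hi})")
    x = np.sin(sub["theta_mp_rad"].to_numpy())
    y = sub["theta_tip_rad"].to_numpy()
    if np.allclose(x, x[0]):
        raise FitError("sin(theta_mp) has zero variance in this band")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    pearson = stats.pearsonr(x, y)
    q1, q3 = np.percentile(resid, [25, 75])
    iqr = q3 - q1
    keep = (resid >= q1 - iqr_trim_factor * iqr) & (resid <= q3 + iqr_trim_factor * iqr)
    return RegressionFit(
        A=float(res.slope),
        se_A=float(res.stderr),
        epsilon=float(res.intercept),
        se_epsilon=float(res.intercept_stderr),
        pearson_r=float(pearson.statistic),
        p_value=float(pearson.pvalue),
        n=len(sub),
        residual_sd=float(np.std(resid, ddof=1)),
        residual_sd_trimmed=float(np.std(resid[keep], ddof=1)) if keep.sum() > 1 else np.nan,
    )


# ---------------------------------------------------------------------------
# growth-rate profile


@dataclass
class GrowthProfile:
    data: pd.DataFrame  # r_um, mean_rate_um_min, se, n


def growth_rate_profile(
    traj: TrajectorySet,
    ovules: OvuleSet,
    grid_lo: float = 10.0,
    grid_hi: float = 200.0,
    grid_step: float = 5.0,
    window: float = 5.0,
) -> GrowthProfile:
    """Mean step speed vs distance to the nearest micropyle.

    Each step contributes its speed (step length / sampling interval) at
    the distance of its first point; grid points average steps within
    ``window`` µm.  SE uses the maximum-likelihood SD (ddof 0).
    """
    mp = ovules.positions
    if len(mp) == 0:
        raise ValidationError("need at least one ovule")
    dists, rates = [], []
    for _, t, xy in traj.tubes():
        steps = np.diff(xy, axis=0)
        speed = np.hypot(steps[:, 0], steps[:, 1]) / np.diff(t)
        d = np.min(
            np.hypot(mp[None, :, 0] - xy[:-1, None, 0], mp[None, :, 1] - xy[:-1, None, 1]),
            axis=1,
        )
        dists.append(d)
        rates.append(speed)
    dists = np.concatenate(dists)
    rates = np.concatenate(rates)
    rows = []
    for r in np.arange(grid_lo, grid_hi + 0.5 * grid_step, grid_step):
        sel = np.abs(dists - r) <= window
        n = int(sel.sum())
        if n > 0:
            mean = float(np.mean(rates[sel]))
            se = float(np.std(rates[sel]) / np.sqrt(n))
        else:
            mean = se = np.nan
        rows.append((r, mean, se, n))
    return GrowthProfile(pd.DataFrame(rows, columns=["r_um", "mean_rate_um_min", "se", "n"]))


# ---------------------------------------------------------------------------
# persistence length


@dataclass
class PersistenceFit:
    L: float  # µm; inf for perfectly straight growth
    b: float  # deviation of the intercept from unity
    ci_L: tuple[float, float] | None
    curve: pd.DataFrame  # lag_um, mean_cos, n_pairs
    fit_max_lag: float  # largest lag used in the linear fit


def _resample_arclength(t: np.ndarray, xy: np.ndarray, step: float) -> np.ndarray:
    """Spline-smooth a path and resample it at equal arc-length intervals."""
    chord = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(xy, axis=0).T))])
    if chord[-1] <= step:
        return np.empty((0, 2))
    # collapse zero-length chords (repeated points) for a valid spline parameter
    keep = np.concatenate([[True], np.diff(chord) > 0])
    chord, xy = chord[keep], xy[keep]
    if len(chord) < 2:
        return np.empty((0, 2))
    spline = CubicSpline(chord, xy, axis=0)
    dense = spline(np.linspace(0, chord[-1], max(20 * len(chord), 100)))
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(dense, axis=0).T))])
    targets = np.arange(0.0, arc[-1], step)
    out = np.column_stack(
        [np.interp(targets, arc, dense[:, 0]), np.interp(targets, arc, dense[:, 1])]
    )
    return out


def persistence_length(
    traj: TrajectorySet,
    resample_step: float = 5.0,
    max_lag: float = 500.0,
    linear_regime_min_cos: float = 0.9,
    n_mc: int = 0,
    seed: int | None = None,
) -> PersistenceFit:
    """Persistence length from the tangent-direction correlation.

    Paths are spline-smoothed, resampled every ``resample_step`` µm of arc
    length, and the mean cosine of the turn over a growth distance ``ds``
    is averaged over all point pairs and tubes for each lag up to
    ``max_lag``.  The linear model ``<cos theta> = (1 + b) - ds / L`` is the
    small-``ds`` expansion of the exponential tangent decorrelation, so the
    fit is restricted to the initial regime where ``<cos theta>`` is at
    least ``linear_regime_min_cos`` (at least 4 lags); the full curve is
    still reported for inspection.  Perfectly straight growth yields a
    zero slope and ``L = inf``.

    When ``n_mc`` > 0, a (5th, 95th) percentile confidence interval for L
    is computed by re-estimating after jittering the raw positions with the
    trajectory set's isotropic measurement noise.
    """
    curve, n_pairs = _correlation_curve(traj, resample_step, max_lag)
    if curve.empty:
        raise FitError("no tube long enough for two resampled points")
    L, b, fit_max = _fit_linear_regime(curve, linear_regime_min_cos)
    ci = None
    if n_mc > 0:
        rng = np.random.default_rng(seed)
        sigma = traj.position_noise_sd
        estimates = []
        for _ in range(n_mc):
            jittered = {}
            for tube_id, t, xy in traj.tubes():
                jittered[tube_id] = xy + rng.normal(0, sigma, xy.shape)
            traj_j = traj.with_positions(jittered)
            curve_j, _ = _correlation_curve(traj_j, resample_step, max_lag)
            if curve_j.empty:
                continue
            L_j, _, _ = _fit_linear_regime(curve_j, linear_regime_min_cos)
            estimates.append(L_j)
        if estimates:
            lo, hi = np.percentile(np.asarray(estimates), [5, 95])
            ci = (float(lo), float(hi))
    return PersistenceFit(L, b, ci, curve, fit_max)


def _correlation_curve(
    traj: TrajectorySet, resample_step: float, max_lag: float
) -> tuple[pd.DataFrame, int]:
    max_k = int(np.floor(max_lag / resample_step))
    sums = np.zeros(max_k + 1)
    counts = np.zeros(max_k + 1, dtype=int)
    total_pairs = 0
    for _, t, xy in traj.tubes():
        pts = _resample_arclength(t, xy, resample_step)
        if len(pts) < 3:
            continue
        tangents = np.diff(pts, axis=0)
        tangents /= np.hypot(tangents[:, 0], tangents[:, 1])[:, None]
        m = len(tangents)
        for k in range(1, min(max_k, m - 1) + 1):
            dots = np.sum(tangents[:-k] * tangents[k:], axis=1)
            sums[k] += dots.sum()
            counts[k] += len(dots)
            total_pairs += len(dots)
    lags = np.arange(1, max_k + 1) * resample_step
    with np.errstate(invalid="ignore"):
        mean_cos = np.where(counts[1:] > 0, sums[1:] / np.maximum(counts[1:], 1), np.nan)
    df = pd.DataFrame({"lag_um": lags, "mean_cos": mean_cos, "n_pairs": counts[1:]})
    return df.dropna().reset_index(drop=True), total_pairs


def _fit_linear_regime(curve: pd.DataFrame, min_cos: float) -> tuple[float, float, float]:
    lag = curve["lag_um"].to_numpy()
    cosv = np.clip(curve["mean_cos"].to_numpy(), -1.0, 1.0)
    in_regime = cosv >= min_cos
    n_fit = max(int(in_regime.sum()), min(4, len(lag)))
    # lags are sorted; use the first n_fit of them
    x, y = lag[:n_fit], cosv[:n_fit]
    if len(x) < 2:
        raise FitError("not enough lags to fit the tangent correlation")
    slope, intercept = np.polyfit(x, y, 1)
    b = float(intercept - 1.0)
    L = np.inf if slope >= -1e-12 else float(-1.0 / slope)
    return L, b, float(x[-1])
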