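"""Headline in-silico experiments, packaged as reusable protocols.

These functions wire together the generator, simulator and fitting modules
into the experiments the model makes claims about:

* :func:`targeting_experiment` — the turning/slowing toggle comparison:
  replicate synthetic geometries (micropyles ~430 +/- 20 µm from the style
  exit, 4-hour incubation), 500 tubes per replicate, run to resolution, and
  the captured fraction reported per toggle set, including the fixed-noise
  variant that decouples the random-turn amplitude from slowing.
* :func:`turning_recovery_experiment` — simulate pooled 0/2/4-hour
  condition data at experimental scale with the fitted parameters and 4 µm
  tracking noise, then refit the turning model.  Pooling source ages is
  essential: a single incubation time leaves (kappa', D, r0) nearly
  unidentifiable along a common valley.

Simulations run until every tube is captured or escaped (bounded at
``max_time``): the targeting fraction asks whether a tube is *able* to
reach a micropyle, and tubes that slow near an ovule need more than the
imaging window to close the final tens of micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .circular import extract_angles
from .field import AttractantParams
from .fit import FitResult, fit_turning, parametric_bootstrap_ci
from .sim import MotilityParams, SimConfig, simulate, targeting_fraction
from .synth import SynthConfig, generate_condition_series, generate_geometry

TOGGLE_SETS = {
    "T-S-": dict(turning=False, slowing=False, noise_mode="rate-coupled"),
    "T-S+": dict(turning=False, slowing=True, noise_mode="rate-coupled"),
    "T+S-": dict(turning=True, slowing=False, noise_mode="rate-coupled"),
    "T+S+": dict(turning=True, slowing=True, noise_mode="rate-coupled"),
    "T+S+*": dict(turning=True, slowing=True, noise_mode="fixed-at-v-init"),
}


def targeting_experiment(
    seed: int,
    labels: tuple[str, ...] = ("T-S-", "T+S-", "T+S+", "T+S+*"),
    n_tubes: int = 500,
    n_replicates: int = 5,
    incubation_offset: float = 270.0,
    max_time: float = 4000.0,
) -> dict[str, float]:
    """Mean captured fraction (in %) per toggle set over replicate geometries.

    Replicates share seeds across toggle sets (paired comparison); each
    replicate draws its own ovule arrangement and initial tube fan.
    """
    attractant = AttractantParams()
    fractions: dict[str, list[float]] = {label: [] for label in labels}
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % 2**31)
        geom_cfg = SynthConfig(
            n_tubes=n_tubes, incubation_offset=incubation_offset, seed=rep_seed
        )
        ovules, init_pos, init_dir = generate_geometry(geom_cfg)
        for label in labels:
            toggles = TOGGLE_SETS[label]
            motility = MotilityParams(noise_mode=toggles["noise_mode"])
            cfg = SimConfig(
                ovules=ovules,
                initial_positions=init_pos,
                initial_directions=init_dir,
                turning=toggles["turning"],
                slowing=toggles["slowing"],
                seed=rep_seed,
                duration=None,
                max_time=max_time,
            )
            result = simulate(cfg, attractant, motility)
            fractions[label].append(targeting_fraction(result))
    return {label: 100.0 * float(np.mean(vals)) for label, vals in fractions.items()}


def _pooled_angles(params, seed, n_tubes, position_noise_sd):
    cfg = SynthConfig(
        n_tubes=n_tubes,
        slowing=False,
        seed=int(seed) % 2**30,
        position_noise_sd=position_noise_sd,
        attractant=params,
    )
    traj, ovules = generate_condition_series(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occasional zero-length noisy steps
        angles = extract_angles(traj, ovules)
    return angles, traj, ovules


def turning_recovery_experiment(
    seed: int,
    n_tubes: int = 200,
    n_ci_sets: int = 25,
    position_noise_sd: float = 4.0,
) -> tuple[FitResult, dict]:
    """Fit the turning model to pooled synthetic 0/2/4-h data; bootstrap CIs.

    The 90% intervals come from a full parametric bootstrap (datasets
    re-simulated at the fitted parameters and refit): the random-turn
    variance dominates the 4-µm tracking error at this scale, so CIs from
    position-jitter resampling alone (:func:`polguide.fit.param_ci`, the
    printed protocol) understate the estimator spread severalfold.
    """
    angles, traj, ovules = _pooled_angles(
        AttractantParams(), seed, n_tubes, position_noise_sd
    )
    motility = MotilityParams()
    fit = fit_turning(
        angles, ovules, motility, seed=seed, n_restarts=3,
        position_noise_sd=position_noise_sd,
    )

    def simulate_dataset(params, set_seed):
        angles_b, _, ovules_b = _pooled_angles(
            params, set_seed, n_tubes, position_noise_sd
        )
        return angles_b, ovules_b

    ci = parametric_bootstrap_ci(
        fit, simulate_dataset, motility,
        n_sets=n_ci_sets, seed=seed, position_noise_sd=position_noise_sd,
    )
    return replace(fit, ci90=ci), ci
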