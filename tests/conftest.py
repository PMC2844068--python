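"""Shared fixtures: small hand-built datasets used across the suite."""

import numpy as np
import pandas as pd
import pytest

from polguide.io import OvuleSet, TrajectorySet


def make_trajectories(rows, noise_sd=4.0, interval=20.0):
    df = pd.DataFrame(rows, columns=["tube_id", "t_min", "x_um", "y_um"])
    return TrajectorySet(df, position_noise_sd=noise_sd, sampling_interval=interval)


def make_ovules(rows):
    df = pd.DataFrame(
        rows,
        columns=[
            "ovule_id",
            "x_um",
            "y_um",
            "functional",
            "incubation_offset_min",
            "penetration_time_min",
        ],
    )
    return OvuleSet(df)


def empty_ovules():
    return make_ovules([])


@pytest.fixture
def straight_tube():
    """One tube growing at 2 µm/min along +x for 100 min."""
    rows = [("tube1", t, 2.0 * t, 0.0) for t in np.arange(0.0, 101.0, 20.0)]
    return make_trajectories(rows)


@pytest.fixture
def single_ovule():
    return make_ovules([("ov0", 500.0, 0.0, True, 150.0, np.nan)])
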