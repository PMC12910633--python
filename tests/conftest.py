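"""Shared fixtures: small seeded landscapes and simulated track sets.

Everything is generated programmatically at test time; session scope keeps
the heavier simulations to a single run.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from sympatry import synthetic as syn


@pytest.fixture(scope="session")
def landscape():
    """Default coastal landscape on a fixed seed."""
    return syn.generate_landscape(syn.LandscapeSpec(), seed=1)


@pytest.fixture(scope="session")
def rich_landscape():
    """Landscape with denser feeder sites for selection-recovery tests."""
    spec = syn.LandscapeSpec(n_landfills=10, n_harbours=8)
    return syn.generate_landscape(spec, seed=1)


@pytest.fixture(scope="session")
def inland_landscape():
    """Nearly all-land landscape for step-selection recovery (no sea drift)."""
    spec = syn.LandscapeSpec(
        coast_x=2000.0, colony_xy=(1000.0, 40_000.0),
        n_landfills=80, n_harbours=3, site_range_m=30_000.0,
    )
    return syn.generate_landscape(spec, seed=11)


@pytest.fixture(scope="session")
def sim_small(landscape):
    """Three birds, three days, no planted corruption (behaviour tests)."""
    cfg = syn.SimConfig(n_individuals={"LBBGU": 3}, n_days=3.0, seed=2, p_bad_fix=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fixes, truth = syn.simulate_tracks(cfg, landscape)
    return fixes, truth


@pytest.fixture(scope="session")
def sim_corrupted(landscape):
    """Two birds, two days, with planted bad fixes (cleaning tests)."""
    cfg = syn.SimConfig(n_individuals={"LBBGU": 2}, n_days=2.0, seed=3, p_bad_fix=0.03)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fixes, truth = syn.simulate_tracks(cfg, landscape)
    return fixes, truth


@pytest.fixture(scope="session")
def fitted(landscape, sim_small):
    """EMbC model fitted to the pooled trips of the small simulation.

    Returns (model, trips, truth); each trip's fixes keep the original
    positional row in an 'index' column for truth alignment.
    """
    from sympatry import behaviour as bh
    from sympatry import trips as tr

    fixes, truth = sim_small
    kins, trip_list = [], []
    for bird, track in fixes.groupby("bird_id"):
        track = track.reset_index(drop=False)
        trips, _ = tr.segment_trips(track, landscape.colony)
        for t_ in trips:
            kin = bh.compute_kinematics(t_.fixes)
            if len(kin):
                kins.append(kin)
            trip_list.append(t_)
    model = bh.fit_embc(pd.concat(kins, ignore_index=True), seed=0)
    return model, trip_list, truth


def per_bird(fixes: pd.DataFrame, truth: syn.TruthRecord):
    """Yield (bird_id, track, truth_rows) with aligned positional indices."""
    for bird, track in fixes.groupby("bird_id", sort=True):
        idx = track.index
        yield bird, track.reset_index(drop=True), truth.fixes.loc[idx].reset_index(drop=True)
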