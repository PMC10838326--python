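import numpy as np
import pytest

import dyadsync as ds
from dyadsync.types import ChannelSeries, CouplingProfile, SyncConfig


@pytest.fixture(scope="session")
def study_roster():
    """Roster at the study's scale: 28 mixed + 16 control dyads."""
    return ds.generate_roster(28, 16, seed=11)


@pytest.fixture(scope="session")
def small_roster():
    return ds.generate_roster(3, 2, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort_features(small_roster):
    """Feature sets from a fully simulated 5-dyad cohort (short recordings,
    proportionally shortened windows)."""
    bundles = ds.simulate_cohort(small_roster, duration=30, fps=30, seed=7)
    cfgs = {
        "face": SyncConfig(150, 30, 60),
        "head": SyncConfig(150, 30, 60),
        "body": SyncConfig(300, 60, 120),
    }
    summaries = ds.features.compute_sync_summaries(bundles, small_roster, configs=cfgs)
    movement = ds.features.compute_movement_scalars(bundles, small_roster)
    return ds.assemble_all_feature_sets(small_roster, summaries, movement)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def delayed_copy_pair():
    """Partner B is a noise-free copy of A delayed by 15 frames."""
    profile = CouplingProfile(
        coupling_strength={"face": 1.0, "head": 1.0, "body": 1.0},
        coupling_lag=0.5,
        noise_sd=0.0,
    )
    return ds.simulate_dyad_timeseries(profile, duration=20, fps=30, seed=3)


def naive_wclc(x, y, window, step, max_lag):
    """Brute-force triple-loop windowed cross-lagged correlation oracle.

    Same symmetric-anchor full-overlap convention as the library, written
    with explicit loops and np.corrcoef only.
    """
    T = len(x)
    n_win = (T - window - 2 * max_lag) // step + 1
    lags = list(range(-max_lag, max_lag + 1))
    out = np.full((n_win, len(lags)), np.nan)
    for w in range(n_win):
        start = w * step
        for j, k in enumerate(lags):
            xa = start + max(-k, 0)
            yb = start + max(k, 0)
            xs = x[xa : xa + window]
            ys = y[yb : yb + window]
            if np.std(xs) == 0 or np.std(ys) == 0:
                continue
            out[w, j] = np.corrcoef(xs, ys)[0, 1]
    return out, np.array(lags)
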