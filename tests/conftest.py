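import numpy as np
import pandas as pd
import pytest

from migtrack.io_formats import GPSTrack


def make_track(lons, lats, start="2019-03-01", interval_min=30.0,
               individual_id="bird1", hdop=None, speed=None):
    """Small helper: build a GPSTrack from coordinate lists."""
    n = len(lons)
    ts = pd.date_range(start, periods=n, freq=f"{int(interval_min)}min", tz="UTC")
    return GPSTrack(individual_id, ts, np.asarray(lons, float),
                    np.asarray(lats, float), hdop, speed, interval_min)


@pytest.fixture
def simple_track():
    return make_track([-96.0, -96.0, -96.0, -96.0], [30.0, 30.1, 30.2, 30.3])


@pytest.fixture(scope="session")
def two_state_model():
    """A well-separated two-state step/turn model used across HMM tests."""
    from migtrack.hmm import HMMModel
    b0 = np.array([[np.nan, np.log(0.05 / 0.95)],
                   [np.log(0.1 / 0.9), np.nan]])
    b1 = np.where(np.isnan(b0), np.nan, 0.0)
    return HMMModel(
        n_states=2,
        step_mean=np.array([0.2, 30.0]), step_sd=np.array([0.2, 10.0]),
        zero_mass=np.zeros(2), angle_mean=np.array([np.pi, 0.0]),
        angle_conc=np.array([0.5, 8.0]),
        tpm_intercept=b0, tpm_slope=b1,
        initial=np.array([2 / 3, 1 / 3]))


@pytest.fixture(scope="session")
def four_state_model():
    """Four-state model with the field-typical roost/forage/local/migratory
    structure (migratory mean 32.3 km per 30-min step)."""
    from migtrack.hmm import HMMModel
    n = 4
    b0 = np.log(np.full((n, n), 0.02 / 0.94))
    np.fill_diagonal(b0, np.nan)
    b1 = np.where(np.isnan(b0), np.nan, 0.0)
    return HMMModel(
        n_states=n,
        step_mean=np.array([0.012, 0.12, 1.4, 32.3]),
        step_sd=np.array([0.012, 0.12, 1.0, 10.0]),
        zero_mass=np.zeros(n),
        angle_mean=np.array([np.pi, 0.0, 0.0, 0.0]),
        angle_conc=np.array([0.3, 0.7, 1.5, 20.0]),
        tpm_intercept=b0, tpm_slope=b1,
        initial=np.full(n, 0.25))


def random_hmm(rng, n_states):
    """Random small model for oracle-equivalence property tests."""
    from migtrack.hmm import HMMModel
    n = n_states
    b0 = rng.normal(-2.0, 1.0, (n, n))
    np.fill_diagonal(b0, np.nan)
    b1 = np.where(np.isnan(b0), np.nan, 0.0)
    initial = rng.dirichlet(np.ones(n))
    means = np.sort(rng.uniform(0.05, 30.0, n))
    return HMMModel(
        n_states=n,
        step_mean=means,
        step_sd=means * rng.uniform(0.5, 1.5, n),  # non-degenerate gamma shape
        zero_mass=np.zeros(n),
        angle_mean=rng.uniform(-np.pi, np.pi, n),
        angle_conc=rng.uniform(0.0, 5.0, n),
        tpm_intercept=b0, tpm_slope=b1, initial=initial)
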