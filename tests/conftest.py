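"""Shared fixtures: montages, synthetic sessions, detection areas."""

import warnings

import numpy as np
import pytest

from thetawake.events import AreaSet
from thetawake.montage_io import ANALYSIS_56, build_neighbors, standard_montage
from thetawake.preprocess import average_reference
from thetawake.synthetic_data import (
    BackgroundSpec,
    SessionSpec,
    gen_session,
)


@pytest.fixture(scope="session")
def montage56():
    return build_neighbors(standard_montage(ANALYSIS_56))


@pytest.fixture(scope="session")
def areas():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return AreaSet.default(fix_central_overlap=True)


@pytest.fixture(scope="session")
def quiet_session(montage56):
    """One 90 s quiet-background session with 30 frontal theta events."""
    bg = BackgroundSpec(
        n_channels=56, fs=256.0, duration=90.0, amplitude_sd=0.1,
        unit="zscored", seed=11,
    )
    spec = SessionSpec(
        background=bg, n_events=30, radius_mean=30.0, radius_sd=2.0,
        amplitude=3.5, amplitude_sd=0.2,
        center_labels=("Fz", "F1", "F2", "AFz"),
    )
    rec, truth = gen_session(spec, montage56, seed=17)
    return average_reference(rec), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
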