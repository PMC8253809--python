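import numpy as np
import pytest

import screenfit as sf


@pytest.fixture
def threefold_series():
    """Canonical 10-point threefold dilution from 35 uM."""
    return sf.build_dilution_series(35e-6, 10, 3.0)


@pytest.fixture
def small_layout(threefold_series):
    """One 384-well plate: 16+16 controls, two drugs' dilution series."""
    return sf.default_layout("P1", ["D1", "D2"], threefold_series)


@pytest.fixture
def two_drug_truth():
    curves = {
        ("D1", "L1"): sf.CurveTruth("D1", "L1", 0.0, 85.0, -1.2, 1e-7),
        ("D2", "L1"): sf.CurveTruth("D2", "L1", 0.0, 100.0, -2.0, 1e-8),
    }
    return sf.ScreenTruth(curves, cv=0.05)


def noiseless(truth: sf.ScreenTruth) -> sf.ScreenTruth:
    return sf.ScreenTruth(truth.curves, truth.neg_mean, truth.pos_mean, cv=0.0)


@pytest.fixture
def noiseless_truth(two_drug_truth):
    return noiseless(two_drug_truth)


def make_dataset(y0, yfin, hill, ec50, series=None, replicates=3,
                 noise_sd=0.0, rng=None, compound="D", line="L"):
    """Dose-response dataset from a known log-logistic curve."""
    if series is None:
        series = sf.build_dilution_series(35e-6, 10, 3.0)
    conc = np.tile(series.concentrations, replicates)
    act = sf.loglogistic(conc, y0, yfin, hill, ec50)
    if noise_sd > 0:
        act = act + rng.normal(0.0, noise_sd, size=act.shape)
    return sf.DoseResponseDataset(compound, line, conc, act)
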