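import numpy as np
import pytest

from p53mdm2.synthetic import GroundTruth, Kind


@pytest.fixture
def wt_tfe_truth():
    """WT-like two-state TFE titration ground truth (midpoint 7%, m 130)."""
    return GroundTruth(
        kind=Kind.TFE_TITRATION,
        params={"dG_water": 910.0, "m_value": 130.0,
                "theta_coil": -2000.0, "theta_helix": -30000.0},
        noise_sd=0.0, seed=7)


@pytest.fixture
def wt_itc_truth():
    """WT-like 1:1 isotherm ground truth (log KA 5.73, ΔH −10.07)."""
    return GroundTruth(
        kind=Kind.ITC_HEATS,
        params={"KA": 10.0 ** 5.73, "dH": -10.07, "n": 1.0},
        noise_sd=0.0, seed=7)


@pytest.fixture
def tfe_grid():
    return np.linspace(0.0, 60.0, 25)
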