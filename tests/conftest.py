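import numpy as np
import pandas as pd
import pytest

from cospart.synthetic_campaign import preset, simulate_campaign, simulate_meteo, simulate_truth


@pytest.fixture(scope="session")
def gra_truth():
    """Noise-free GRA-like truth table, 8 days (fast)."""
    scen = preset("GRA", seed=11, n_days=8)
    return scen, simulate_truth(scen, simulate_meteo(scen))


@pytest.fixture(scope="session")
def gra_campaign():
    """Small noisy GRA campaign with truth-based soil correction applied."""
    scen = preset("GRA", seed=11, n_days=8)
    flux, chambers = simulate_campaign(scen)
    flux = flux.copy()
    flux["f_cos_canopy"] = flux["fcos_eco"] - flux["f_soil_true"]
    return scen, flux, chambers
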