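"""Synthetic half-hourly flux campaigns with known truth.

Generates campaigns with the statistical structure the partitioning
analysis assumes: diel meteorology (half-sine PAR, lagged temperature
sinusoids), truth fluxes composed exactly from the process equations in
:mod:`cospart.forward_models`, a radiation-driven soil COS source/sink,
nocturnal residual canopy COS uptake from incomplete stomatal closure,
and iid Gaussian observation noise.  Four presets (GRA: mountain
grassland, SAV: Mediterranean savanna, DBF: beech forest, CRO: soybean
crop) emulate the flux magnitudes of the corresponding field campaigns,
including the per-site high-light LRU (iota) optima 1.02, 2.27, 2.22 and
0.89 and peak canopy COS uptake near 40 pmol m-2 s-1 (about twice that
for the forest).

Truth columns are exact (no noise); observation columns add noise drawn
from the scenario seed, so every campaign is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forward_models import (
    AmbientMoleFractions,
    LightParams,
    LRUParams,
    RespirationParams,
    fcos_forward,
    gpp_light_response,
    lru_light,
    reco_lloyd_taylor,
)
from .soil_cos import DEFAULT_CHAMBER_AREA, molar_flow_from_volumetric

__all__ = [
    "SiteScenario",
    "PRESETS",
    "preset",
    "simulate_meteo",
    "simulate_truth",
    "simulate_observations",
    "simulate_chamber_campaign",
    "simulate_campaign",
]

#: PAR (umol photons) to shortwave (W) conversion, umol J-1.
PAR_TO_SW = 2.1

#: PAR threshold separating daytime from nighttime records, umol m-2 s-1.
DAYTIME_PAR_THRESHOLD = 10.0


@dataclass(frozen=True)
class SiteScenario:
    """Everything needed to generate one synthetic campaign.

    ``soil_coeffs`` = (baseline uptake magnitude pmol m-2 s-1, radiative
    emission slope pmol m-2 s-1 per W m-2): the true soil COS flux is
    -baseline + slope * sw_soil, reproducing nocturnal uptake and
    radiation-driven daytime emission.  ``noise`` = (sigma_NEE in
    umol m-2 s-1, sigma_COS in pmol m-2 s-1).  ``nocturnal_fraction`` is
    the nighttime canopy COS uptake as a fraction of the mean daytime
    uptake (incomplete stomatal closure).
    """

    name: str
    n_days: int = 30
    daylength_h: float = 14.0
    par_max: float = 1500.0
    t_mean: float = 15.0
    t_amplitude: float = 8.0
    chi_co2_mean: float = 400.0
    chi_cos_mean: float = 500.0
    true_light: LightParams = field(default_factory=lambda: LightParams(0.05, 30.0))
    true_resp: RespirationParams = field(default_factory=lambda: RespirationParams(3.0, 150.0))
    true_lru: LRUParams = field(default_factory=lambda: LRUParams(1.7, 25.0))
    soil_coeffs: tuple = (1.0, 0.01)
    noise: tuple = (1.0, 3.0)
    canopy_transmission: float = 0.1
    nocturnal_fraction: float = 0.2
    swc_mean: float = 0.28
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.canopy_transmission <= 1.0):
            raise ValueError("canopy_transmission must be in [0, 1]")
        for v in (self.n_days, self.daylength_h, self.par_max, self.chi_co2_mean, self.chi_cos_mean):
            if v <= 0:
                raise ValueError("scenario scales must be positive")
        if any(s < 0 for s in self.noise):
            raise ValueError("noise sigmas must be >= 0")


PRESETS = {
    "GRA": SiteScenario(
        name="GRA", daylength_h=15, par_max=1500, t_mean=14, t_amplitude=8,
        true_light=LightParams(0.06, 40.0), true_resp=RespirationParams(3.0, 150.0),
        true_lru=LRUParams(1.02, 25.0), soil_coeffs=(1.0, 0.005),
        canopy_transmission=0.05,
    ),
    "SAV": SiteScenario(
        name="SAV", daylength_h=13, par_max=1600, t_mean=18, t_amplitude=10,
        true_light=LightParams(0.05, 16.0), true_resp=RespirationParams(3.0, 120.0),
        true_lru=LRUParams(2.27, 40.0), soil_coeffs=(1.5, 0.012),
        canopy_transmission=0.5,
    ),
    "DBF": SiteScenario(
        name="DBF", daylength_h=16, par_max=1400, t_mean=16, t_amplitude=6,
        true_light=LightParams(0.06, 40.0), true_resp=RespirationParams(4.0, 180.0),
        true_lru=LRUParams(2.22, 30.0), soil_coeffs=(2.8, 0.01),
        canopy_transmission=0.05,
    ),
    "CRO": SiteScenario(
        name="CRO", daylength_h=15, par_max=1700, t_mean=20, t_amplitude=9,
        true_light=LightParams(0.07, 45.0), true_resp=RespirationParams(4.0, 140.0),
        true_lru=LRUParams(0.89, 15.0), soil_coeffs=(0.8, 0.008),
        canopy_transmission=0.2,
    ),
}


def preset(name: str, *, seed: int = 0, n_days: int | None = None) -> SiteScenario:
    """Return a site preset, optionally overriding seed and campaign length."""
    try:
        s = PRESETS[name.upper()]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    kwargs = {"seed": seed}
    if n_days is not None:
        kwargs["n_days"] = n_days
    return replace(s, **kwargs)


def _timestamps(s: SiteScenario) -> pd.DatetimeIndex:
    # local time, CET; solar noon at 12:00
    return pd.date_range("2016-06-01 00:00", periods=s.n_days * 48, freq="30min", name="timestamp")


def simulate_meteo(s: SiteScenario) -> pd.DataFrame:
    """Half-hourly meteorological drivers for a scenario.

    PAR follows a half sine over the daylength peaking at par_max at solar
    noon (12:00 CET) and is exactly zero at night; air temperature is a
    sinusoid lagged 2 h after solar noon, soil temperature a damped
    sinusoid lagged further; shortwave at the soil surface is
    canopy_transmission * PAR / 2.1; mole fractions ripple +-1% around
    their means.  Deterministic given the scenario seed.
    """
    idx = _timestamps(s)
    rng = np.random.default_rng(s.seed)
    h = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    day = (idx - idx[0]).days.to_numpy()

    start = 12.0 - s.daylength_h / 2.0
    in_day = (h >= start) & (h <= start + s.daylength_h)
    par = np.where(in_day, s.par_max * np.sin(np.pi * (h - start) / s.daylength_h), 0.0)
    par = np.clip(par, 0.0, None)

    t_air = s.t_mean + s.t_amplitude * np.cos(2 * np.pi * (h - 14.0) / 24.0)
    t_soil = s.t_mean + 0.5 * s.t_amplitude * np.cos(2 * np.pi * (h - 17.0) / 24.0)
    swc = s.swc_mean - 0.001 * day + rng.normal(0.0, 0.002, len(idx))
    swc = np.clip(swc, 0.01, 0.6)
    sw_soil = s.canopy_transmission * par / PAR_TO_SW

    chi_co2 = s.chi_co2_mean * (1.0 + 0.01 * np.cos(2 * np.pi * (h - 4.0) / 24.0))
    chi_cos = s.chi_cos_mean * (1.0 - 0.01 * np.cos(2 * np.pi * (h - 14.0) / 24.0))

    return pd.DataFrame(
        {
            "par": par,
            "t_air": t_air,
            "t_soil": t_soil,
            "swc": swc,
            "sw_soil": sw_soil,
            "chi_co2": chi_co2,
            "chi_cos": chi_cos,
        },
        index=idx,
    )


def simulate_truth(s: SiteScenario, meteo: pd.DataFrame) -> pd.DataFrame:
    """Augment drivers with exact truth fluxes from the process equations.

    Daytime (PAR above threshold): GPP from the light response, LRU from
    the light-dependent model and canopy COS uptake from the COS-GPP
    relation, all evaluated at the scenario's true parameters.  Nighttime:
    GPP = 0, LRU undefined (NaN), canopy COS uptake continues at
    ``nocturnal_fraction`` of the mean daytime uptake.  The soil COS flux
    is -baseline + slope * sw_soil throughout.  Truth carries no noise,
    so the forward-model identities hold exactly.
    """
    out = meteo.copy()
    par = out["par"].to_numpy()
    day_mask = par > DAYTIME_PAR_THRESHOLD

    gpp = np.zeros(len(out))
    gpp[day_mask] = gpp_light_response(s.true_light, par[day_mask])
    reco = reco_lloyd_taylor(s.true_resp, out["t_air"].to_numpy())

    lru = np.full(len(out), np.nan)
    lru[day_mask] = lru_light(s.true_lru, par[day_mask])

    f_canopy = np.zeros(len(out))
    amb_day = AmbientMoleFractions(
        out["chi_co2"].to_numpy()[day_mask], out["chi_cos"].to_numpy()[day_mask]
    )
    f_canopy[day_mask] = -fcos_forward(gpp[day_mask], lru[day_mask], amb_day)
    mean_day_uptake = float(np.mean(-f_canopy[day_mask])) if day_mask.any() else 0.0
    f_canopy[~day_mask] = -s.nocturnal_fraction * mean_day_uptake

    baseline, slope = s.soil_coeffs
    f_soil = -baseline + slope * out["sw_soil"].to_numpy()

    out["gpp_true"] = gpp
    out["reco_true"] = reco
    out["lru_true"] = lru
    out["nee_true"] = reco - gpp
    out["f_cos_canopy_true"] = f_canopy
    out["f_soil_true"] = f_soil
    out["f_cos_eco_true"] = f_canopy + f_soil
    return out


def simulate_observations(truth: pd.DataFrame, noise, seed: int) -> pd.DataFrame:
    """Add iid Gaussian observation noise to the truth fluxes.

    nee_obs = nee_true + N(0, sigma_NEE); f_cos_eco_obs = ecosystem COS
    truth (canopy + soil) + N(0, sigma_COS).  Independent draws per
    stream, reproducible per seed; sigma = 0 returns the truth exactly.
    """
    s_nee, s_cos = noise
    if s_nee < 0 or s_cos < 0:
        raise ValueError("noise sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    out = truth.copy()
    out["nee"] = truth["nee_true"] + rng.normal(0.0, s_nee, len(truth)) if s_nee else truth["nee_true"]
    out["fcos_eco"] = (
        truth["f_cos_eco_true"] + rng.normal(0.0, s_cos, len(truth)) if s_cos else truth["f_cos_eco_true"]
    )
    return out


def simulate_chamber_campaign(
    s: SiteScenario,
    n_chambers: int = 3,
    times: pd.DatetimeIndex | None = None,
    seed: int | None = None,
    noise_ppt: float = 1.0,
) -> pd.DataFrame:
    """Soil chamber observations consistent with the campaign's soil truth.

    Inverts the chamber equation: given the true soil flux F at each
    measurement time, the chamber mole fraction is C2 = C1 + F*A/q, plus
    Gaussian noise of ``noise_ppt`` on C2.  ``times`` defaults to every
    3 h over the campaign; ``n_chambers`` replicate rings are measured at
    each time.  Returns the chamber CSV dialect columns plus the soil
    drivers at the measurement times and the underlying ``f_soil_true``.
    """
    seed = s.seed + 1 if seed is None else seed
    rng = np.random.default_rng(seed)
    truth = simulate_truth(s, simulate_meteo(s))
    if times is None:
        times = truth.index[::6]  # every 3 h
    else:
        missing = pd.DatetimeIndex(times).difference(truth.index)
        if len(missing):
            raise ValueError(f"chamber times outside campaign: {list(missing[:3])}")
    sub = truth.loc[times]

    rows = []
    for ts, rec in sub.iterrows():
        q = molar_flow_from_volumetric(7.0, rec["t_air"], 1013.25)
        for _ in range(n_chambers):
            c1 = rec["chi_cos"]
            c2 = c1 + rec["f_soil_true"] * DEFAULT_CHAMBER_AREA / q
            if noise_ppt:
                c2 += rng.normal(0.0, noise_ppt)
            rows.append(
                {
                    "timestamp": ts,
                    "q_lpm": 7.0,
                    "temp_c": rec["t_air"],
                    "press_hpa": 1013.25,
                    "c_ambient_ppt": c1,
                    "c_chamber_ppt": c2,
                    "area_m2": DEFAULT_CHAMBER_AREA,
                    "stable_flag": 1,
                    "sw_soil": rec["sw_soil"],
                    "t_soil": rec["t_soil"],
                    "swc": rec["swc"],
                    "f_soil_true": rec["f_soil_true"],
                }
            )
    return pd.DataFrame(rows).set_index("timestamp")


def simulate_campaign(s: SiteScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full campaign: (half-hourly flux table, chamber table).

    Convenience wrapper chaining meteorology, truth, observations and the
    chamber campaign, all seeded from the scenario.
    """
    truth = simulate_truth(s, simulate_meteo(s))
    obs = simulate_observations(truth, s.noise, seed=s.seed + 2)
    chambers = simulate_chamber_campaign(s)
    return obs, chambers
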