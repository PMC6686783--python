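"""Soil COS fluxes: chamber computation, gap-filling, soil correction.

Soil can be a source or a sink of COS, so ecosystem-scale COS fluxes must
be corrected for the soil contribution before canopy COS uptake can be
used as a GPP proxy.  This module computes steady-state flow-through
chamber fluxes, trains a per-site random-forest regression of soil flux
on its environmental drivers (shortwave radiation at the soil surface,
soil temperature, soil moisture), predicts half-hourly soil fluxes, and
subtracts them from the ecosystem flux.

All fluxes here use the micrometeorological convention: positive = net
emission to the atmosphere, negative = net uptake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ChamberMeasurement",
    "SoilFluxModel",
    "DRIVER_COLUMNS",
    "chamber_flux",
    "molar_flow_from_volumetric",
    "fit_soil_model",
    "predict_soil_flux",
    "canopy_cos_flux",
]

#: Environmental drivers of the soil COS flux, in the order the model uses.
DRIVER_COLUMNS = ("sw_soil", "t_soil", "swc")

#: Soil surface area covered by the chamber, m2 (instrument default).
DEFAULT_CHAMBER_AREA = 0.032

R_GAS = 8.314462618  # J mol-1 K-1


@dataclass(frozen=True)
class ChamberMeasurement:
    """One steady-state flow-through soil chamber observation.

    q : molar flow rate through the chamber, mol s-1.
    c_ambient : ambient COS mole fraction C1, ppt.
    c_chamber : chamber COS mole fraction C2, ppt.
    area : soil surface area covered, m2 (default 0.032).

    Only measurements taken after readings inside the chamber are stable
    satisfy the steady-state assumption; stability is an input flag
    handled upstream, not detected here.
    """

    q: float
    c_ambient: float
    c_chamber: float
    area: float = DEFAULT_CHAMBER_AREA

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise ValueError(f"flow rate q must be > 0, got {self.q}")
        if not self.area > 0:
            raise ValueError(f"chamber area must be > 0, got {self.area}")
        if self.c_ambient < 0 or self.c_chamber < 0:
            raise ValueError("mole fractions must be >= 0")


def chamber_flux(m: ChamberMeasurement) -> float:
    """Soil COS flux from one chamber measurement, pmol m-2 s-1.

    F = q * (C2 - C1) / A.  With C in ppt (= pmol mol-1) and q in mol s-1
    the result is directly in pmol m-2 s-1.  Positive = emission (chamber
    air enriched over ambient), exactly linear in q and in (C2 - C1).
    """
    return m.q * (m.c_chamber - m.c_ambient) / m.area


def molar_flow_from_volumetric(v_flow: float, temperature: float, pressure: float) -> float:
    """Convert a volumetric flow (L min-1) to a molar flow (mol s-1).

    Ideal gas at the stated conditions: n = P*V/(R*T), with ``temperature``
    in degC and ``pressure`` in hPa.
    """
    if v_flow <= 0 or pressure <= 0:
        raise ValueError("flow and pressure must be > 0")
    t_kelvin = temperature + 273.15
    if t_kelvin <= 0:
        raise ValueError(f"temperature below absolute zero: {temperature} degC")
    vol_m3_s = v_flow * 1e-3 / 60.0
    return pressure * 100.0 * vol_m3_s / (R_GAS * t_kelvin)


@dataclass
class SoilFluxModel:
    """Fitted per-site regression of soil COS flux on its drivers.

    Wraps a random-forest ensemble; predictions are deterministic given
    the training seed.  Metadata records the sample size, driver names
    and out-of-bag R2 for provenance.
    """

    regressor: RandomForestRegressor
    n_train: int
    driver_names: tuple
    oob_score: float | None
    seed: int
    train_min: np.ndarray = field(repr=False, default=None)
    train_max: np.ndarray = field(repr=False, default=None)


def _driver_matrix(drivers: pd.DataFrame, names) -> np.ndarray:
    missing = [c for c in names if c not in drivers.columns]
    if missing:
        raise ValueError(f"driver columns missing: {missing}")
    x = drivers.loc[:, list(names)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("driver values contain NaN; complete records required")
    return x


def fit_soil_model(
    drivers: pd.DataFrame,
    fluxes,
    seed: int,
    driver_names=DRIVER_COLUMNS,
) -> SoilFluxModel:
    """Train the soil-flux regression on paired chamber observations.

    ``drivers`` is a DataFrame with the columns in ``driver_names``;
    ``fluxes`` the matching soil COS fluxes (pmol m-2 s-1, positive =
    emission).  Requires at least 20 complete pairs; a constant target
    only triggers a warning (the ensemble then predicts the constant).

    The ensemble uses 500 trees, one third of the features per split,
    minimum leaf size 5 and out-of-bag scoring -- conservative defaults
    for small-n environmental regression, recorded in the metadata.
    """
    y = np.asarray(fluxes, dtype=float)
    x = _driver_matrix(drivers, driver_names)
    if len(y) != len(x):
        raise ValueError("drivers and fluxes must have equal length")
    if len(y) < 20:
        raise ValueError(
            f"need >= 20 paired observations to fit a soil model, got {len(y)}; "
            "consider pooling measurement days"
        )
    if np.isnan(y).any():
        raise ValueError("fluxes contain NaN")
    constant = np.ptp(y) == 0
    if constant:
        warnings.warn("constant soil-flux target; model will predict the constant")
    rf = RandomForestRegressor(
        n_estimators=500,
        max_features=1 / 3,
        min_samples_leaf=5,
        oob_score=not constant,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # OOB warning on tiny n is expected and recorded via oob_score=None
        warnings.simplefilter("ignore", UserWarning)
        rf.fit(x, y)
    oob = float(rf.oob_score_) if getattr(rf, "oob_score_", None) is not None else None
    return SoilFluxModel(
        regressor=rf,
        n_train=len(y),
        driver_names=tuple(driver_names),
        oob_score=oob,
        seed=seed,
        train_min=x.min(axis=0),
        train_max=x.max(axis=0),
    )


def predict_soil_flux(model: SoilFluxModel, drivers: pd.DataFrame):
    """Predict the soil COS flux series (pmol m-2 s-1) at new drivers.

    One finite prediction per record, bit-reproducible for a given model.
    Drivers outside the training hull are extrapolated with a logged
    warning, never rejected.
    """
    if model is None or model.regressor is None:
        raise RuntimeError("soil model is not fitted")
    x = _driver_matrix(drivers, model.driver_names)
    if model.train_min is not None:
        outside = (x < model.train_min).any() or (x > model.train_max).any()
        if outside:
            warnings.warn(
                "some driver values lie outside the training range; "
                "random-forest predictions saturate at the hull"
            )
    pred = model.regressor.predict(x)
    return pd.Series(pred, index=drivers.index, name="f_soil")


def canopy_cos_flux(f_ecosystem: pd.Series, f_soil: pd.Series) -> pd.Series:
    """Canopy COS flux = ecosystem flux minus soil contribution.

    Both series are micrometeorological (negative = uptake) and must share
    aligned timestamps; the identity ecosystem = canopy + soil holds
    exactly after correction.
    """
    if not f_ecosystem.index.equals(f_soil.index):
        gaps = f_ecosystem.index.symmetric_difference(f_soil.index)
        raise ValueError(
            f"ecosystem and soil flux timestamps differ at {len(gaps)} "
            f"point(s), e.g. {list(gaps[:3])}"
        )
    out = f_ecosystem - f_soil
    out.name = "f_cos_canopy"
    return out
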