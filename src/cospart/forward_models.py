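"""Process-model equations linking NEE, GPP, Reco and canopy COS uptake.

The ecosystem CO2 budget is NEE = Reco - GPP, with ecosystem respiration
Reco following the Lloyd & Taylor temperature response and GPP a
rectangular-hyperbola light response.  Canopy COS uptake is tied to GPP
through the leaf relative uptake ratio (LRU), the ratio of COS to CO2
deposition velocities, modelled as light dependent:

    Reco  = rb * exp(E0 * (1/(T_ref - T0) - 1/(T_air - T0)))
    GPP   = alpha * beta * R_PAR / (alpha * R_PAR + beta)
    LRU   = iota * exp(kappa / R_PAR)
    F_COS = GPP * LRU / (chi_CO2 / chi_COS)

Sign convention (package-wide): *measured* fluxes use the
micrometeorological convention (negative = uptake).  GPP, Reco and
modelled canopy COS uptake are returned as non-negative magnitudes;
callers negate where a micrometeorological quantity is needed.  Every
function documents the convention of its return value.

Mole fractions are kept in their native units (CO2 in ppm, COS in ppt)
and put on a common mol/mol scale only inside the ratio chi_CO2/chi_COS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RespirationParams",
    "LightParams",
    "LRUParams",
    "AmbientMoleFractions",
    "reco_lloyd_taylor",
    "gpp_light_response",
    "nee_forward",
    "lru_light",
    "fcos_forward",
    "gpp_from_cos",
]

#: Reference temperature of the respiration model, degC.
T_REF = 15.0
#: Lower temperature constant of the Lloyd & Taylor model, degC (fixed).
T_ZERO = -46.02

PPM = 1e-6  # mol/mol per ppm
PPT = 1e-12  # mol/mol per ppt
PMOL_PER_MOL = 1e12
UMOL_PER_MOL = 1e6


@dataclass(frozen=True)
class RespirationParams:
    """Lloyd & Taylor respiration parameters.

    Parameters
    ----------
    rb : float
        Ecosystem base respiration at the reference temperature,
        umol CO2 m-2 s-1.  Strictly positive.
    e0 : float
        Temperature sensitivity, degC.  Non-negative.
    t_ref : float
        Reference temperature, degC (default 15).
    t0 : float
        Lower temperature constant, degC (default -46.02, held fixed).
    """

    rb: float
    e0: float
    t_ref: float = T_REF
    t0: float = T_ZERO

    def __post_init__(self) -> None:
        if not self.rb > 0:
            raise ValueError(f"rb must be > 0, got {self.rb}")
        if self.e0 < 0:
            raise ValueError(f"E0 must be >= 0, got {self.e0}")
        if not self.t_ref > self.t0:
            raise ValueError(f"T_ref ({self.t_ref}) must exceed T0 ({self.t0})")


@dataclass(frozen=True)
class LightParams:
    """Rectangular-hyperbola light-response parameters.

    alpha : canopy light-utilization efficiency, umol CO2 / umol photons.
    beta  : maximum canopy CO2 uptake at light saturation, umol CO2 m-2 s-1.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")


@dataclass(frozen=True)
class LRUParams:
    """Light-dependent leaf relative uptake parameters.

    iota  : LRU in the high-light limit, dimensionless.
    kappa : low-light increase parameter, umol m-2 s-1 (same units as PAR).
    """

    iota: float
    kappa: float

    def __post_init__(self) -> None:
        if not self.iota > 0:
            raise ValueError(f"iota must be > 0, got {self.iota}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")


@dataclass(frozen=True)
class AmbientMoleFractions:
    """Ambient CO2 (ppm) and COS (ppt) mole fractions.

    The dimensionless ratio chi_CO2/chi_COS is always formed on a common
    mol/mol scale (ppm -> 1e-6, ppt -> 1e-12).
    """

    chi_co2: float
    chi_cos: float

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.chi_co2) > 0):
            raise ValueError("chi_co2 must be strictly positive")
        if not np.all(np.asarray(self.chi_cos) > 0):
            raise ValueError("chi_cos must be strictly positive")

    @property
    def ratio(self):
        """chi_CO2/chi_COS on a common mol/mol scale (dimensionless)."""
        return (np.asarray(self.chi_co2) * PPM) / (np.asarray(self.chi_cos) * PPT)


def reco_lloyd_taylor(p: RespirationParams, t_air):
    """Ecosystem respiration (umol m-2 s-1, non-negative magnitude).

    Lloyd & Taylor exponential temperature response evaluated at air
    temperature ``t_air`` (degC, scalar or array).  Strictly increasing in
    t_air for E0 > 0 and equal to ``rb`` at t_air = T_ref.

    Raises
    ------
    ValueError
        If any t_air is at or below the lower temperature constant T0,
        where the model is undefined.
    """
    t_air = np.asarray(t_air, dtype=float)
    if np.any(t_air <= p.t0):
        bad = np.asarray(t_air)[np.asarray(t_air) <= p.t0]
        raise ValueError(
            f"t_air must exceed T0 = {p.t0} degC; offending value(s): {bad.ravel()[:5]}"
        )
    expo = p.e0 * (1.0 / (p.t_ref - p.t0) - 1.0 / (t_air - p.t0))
    out = p.rb * np.exp(expo)
    return out if out.ndim else float(out)


def gpp_light_response(p: LightParams, r_par):
    """GPP (umol m-2 s-1, non-negative magnitude) from incident PAR.

    Rectangular hyperbola alpha*beta*R/(alpha*R + beta): zero at R = 0,
    initial slope alpha, saturating at beta.  ``r_par`` in
    umol photons m-2 s-1, scalar or array, must be >= 0.
    """
    r = np.asarray(r_par, dtype=float)
    if np.any(r < 0):
        raise ValueError("r_par must be >= 0")
    out = p.alpha * p.beta * r / (p.alpha * r + p.beta)
    return out if out.ndim else float(out)


def nee_forward(lp: LightParams, rp: RespirationParams, r_par, t_air):
    """Modelled NEE (umol m-2 s-1, micrometeorological sign).

    NEE = Reco - GPP: negative (net uptake) when photosynthesis exceeds
    respiration, positive (net release) at night.  The decomposition holds
    to machine precision by construction.
    """
    return reco_lloyd_taylor(rp, t_air) - gpp_light_response(lp, r_par)


def lru_light(p: LRUParams, r_par):
    """Leaf relative uptake ratio (dimensionless) at incident PAR.

    LRU = iota * exp(kappa / R_PAR): tends to iota at high light and
    diverges as R_PAR -> 0+ (COS uptake persists while GPP vanishes);
    monotone non-increasing in R_PAR for kappa > 0.

    Raises
    ------
    ValueError
        If any r_par <= 0 -- the LRU is undefined without photosynthesis;
        fitting code excludes sub-threshold records instead of clamping.
    """
    r = np.asarray(r_par, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r_par must be > 0; LRU is undefined without light")
    out = p.iota * np.exp(p.kappa / r)
    return out if out.ndim else float(out)


def fcos_forward(gpp, lru, amb: AmbientMoleFractions):
    """Modelled canopy COS uptake (pmol m-2 s-1, non-negative magnitude).

    F_COS = GPP * LRU / (chi_CO2/chi_COS), with GPP in umol m-2 s-1
    (magnitude) and the mole-fraction ratio on a common mol/mol scale.
    """
    gpp = np.asarray(gpp, dtype=float)
    lru = np.asarray(lru, dtype=float)
    if np.any(gpp < 0):
        raise ValueError("gpp must be a non-negative magnitude")
    if np.any(lru <= 0):
        raise ValueError("lru must be > 0")
    out = (gpp / UMOL_PER_MOL) * lru / amb.ratio * PMOL_PER_MOL
    return out if out.ndim else float(out)


def gpp_from_cos(f_cos_canopy, lru, amb: AmbientMoleFractions):
    """GPP (umol m-2 s-1, magnitude) inferred from canopy COS uptake.

    GPP = F_COS * (chi_CO2/chi_COS) / LRU -- the exact algebraic inverse
    of :func:`fcos_forward`.  ``f_cos_canopy`` is the canopy COS uptake
    magnitude in pmol m-2 s-1 (soil-corrected, sign already removed).
    """
    f = np.asarray(f_cos_canopy, dtype=float)
    lru = np.asarray(lru, dtype=float)
    if np.any(lru <= 0):
        raise ValueError("lru must be > 0")
    out = (f / PMOL_PER_MOL) * amb.ratio / lru * UMOL_PER_MOL
    return out if out.ndim else float(out)
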