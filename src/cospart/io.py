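"""CSV interchange formats and run configuration.

The half-hourly flux CSV is the interchange format for every pipeline
stage: RFC 4180, UTF-8, ISO-8601 timestamps (local time, CET), dot
decimal.  Fluxes at file boundaries always use the micrometeorological
sign convention (negative = uptake).  Missing values are empty fields.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "REQUIRED_FLUX_COLUMNS",
    "CHAMBER_COLUMNS",
    "read_flux_csv",
    "write_flux_csv",
    "read_chamber_csv",
    "write_chamber_csv",
    "load_config",
    "dump_config",
    "DEFAULT_CONFIG",
]

REQUIRED_FLUX_COLUMNS = (
    "nee",
    "fcos_eco",
    "chi_co2",
    "chi_cos",
    "par",
    "t_air",
    "t_soil",
    "swc",
    "sw_soil",
)

CHAMBER_COLUMNS = (
    "q_lpm",
    "temp_c",
    "press_hpa",
    "c_ambient_ppt",
    "c_chamber_ppt",
    "area_m2",
    "stable_flag",
)

DEFAULT_CONFIG = {
    "daytime_par_threshold": 10.0,
    "iota_prior": "informative",
    "n_chains": None,
    "n_iter": 6000,
    "retain": 2950,
    "seed": 0,
    "lod_multiplier": 1.96,
    "preset": "GRA",
    "n_days": None,
}


def read_flux_csv(path) -> pd.DataFrame:
    """Read a half-hourly flux CSV into a timestamp-indexed DataFrame.

    Requires a ``timestamp`` column plus the columns in
    ``REQUIRED_FLUX_COLUMNS``; extra columns (truth fields, soil
    corrections) pass through.  Rows are sorted by timestamp (with a
    warning if the file was unsorted); duplicate timestamps are an error.
    Missing values are allowed and stay NaN.
    """
    df = pd.read_csv(path, comment="#")
    if "timestamp" not in df.columns:
        raise ValueError("flux CSV must have a 'timestamp' column")
    # unit-suffixed mole-fraction headers are the canonical file dialect
    df = df.rename(columns={"chi_co2_ppm": "chi_co2", "chi_cos_ppt": "chi_cos"})
    missing = [c for c in REQUIRED_FLUX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"flux CSV missing required column(s): {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if df["timestamp"].duplicated().any():
        dup = df.loc[df["timestamp"].duplicated(), "timestamp"].iloc[0]
        raise ValueError(f"duplicate timestamps in flux CSV (first: {dup})")
    if not df["timestamp"].is_monotonic_increasing:
        warnings.warn("flux CSV rows were not sorted by timestamp; sorting")
        df = df.sort_values("timestamp")
    return df.set_index("timestamp")


def write_flux_csv(df: pd.DataFrame, path) -> None:
    """Write a flux table in the interchange dialect (with sign header)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.rename(columns={"chi_co2": "chi_co2_ppm", "chi_cos": "chi_cos_ppt"})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# micrometeorological sign convention: negative = uptake\n")
        out.to_csv(fh, index_label="timestamp")


def read_chamber_csv(path) -> pd.DataFrame:
    """Read soil chamber observations; requires the chamber dialect columns."""
    df = pd.read_csv(path, comment="#")
    if "timestamp" not in df.columns:
        raise ValueError("chamber CSV must have a 'timestamp' column")
    missing = [c for c in CHAMBER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"chamber CSV missing required column(s): {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.set_index("timestamp")


def write_chamber_csv(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index_label="timestamp")


def save_fit(fit, outdir, tag: str) -> None:
    """Persist a ModelFit: summary text, chains CSV and YAML metadata.

    ``chains_<tag>.csv`` holds one row per (chain, iteration) with the
    parameter columns plus loglik/logpost; ``fit_<tag>.yaml`` carries
    E0, seed, burn-in, convergence status and R-hat so the fit can be
    reconstructed without resampling.
    """
    from .inversion import PosteriorChains  # noqa: F401  (documented coupling)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"fit_{tag}.txt").write_text(fit.result.to_text(), encoding="utf-8")
    ch = fit.chains
    frame = ch.to_frame()
    frame["loglik"] = ch.loglik.reshape(-1)
    frame["logpost"] = ch.logpost.reshape(-1)
    frame.to_csv(outdir / f"chains_{tag}.csv", index=False)
    meta = {
        "model": fit.result.model,
        "e0": float(fit.e0),
        "rb_night": float(fit.rb_night),
        "seed": int(ch.seed),
        "burn_in": int(ch.burn_in),
        "converged": bool(ch.converged),
        "acceptance_rate": float(ch.acceptance_rate),
        "retain": int(ch.retain),
        "retain_start": int(ch.retain_start),
        "param_names": list(ch.param_names),
        "rhat": [float(r) for r in ch.rhat],
    }
    (outdir / f"fit_{tag}.yaml").write_text(yaml.safe_dump(meta), encoding="utf-8")


def load_fit(outdir, tag: str):
    """Reconstruct a ModelFit saved by :func:`save_fit`."""
    import numpy as np

    from .inversion import FitResult, ModelFit, PosteriorChains, posterior_summary

    outdir = Path(outdir)
    meta = yaml.safe_load((outdir / f"fit_{tag}.yaml").read_text(encoding="utf-8"))
    frame = pd.read_csv(outdir / f"chains_{tag}.csv")
    names = meta["param_names"]
    c = int(frame["chain"].max()) + 1
    n = int(frame["iter"].max()) + 1
    samples = frame[names].to_numpy().reshape(c, n, len(names))
    chains = PosteriorChains(
        samples=samples,
        loglik=frame["loglik"].to_numpy().reshape(c, n),
        logpost=frame["logpost"].to_numpy().reshape(c, n),
        param_names=tuple(names),
        burn_in=meta["burn_in"],
        seed=meta["seed"],
        acceptance_rate=meta["acceptance_rate"],
        rhat=np.asarray(meta["rhat"]),
        converged=meta["converged"],
        retain=meta["retain"],
        retain_start=meta.get("retain_start"),
    )
    result = posterior_summary(chains, model=meta["model"])
    result.e0 = meta["e0"]
    return ModelFit(result=result, chains=chains, e0=meta["e0"], rb_night=meta["rb_night"])


def load_config(path=None, **overrides) -> dict:
    """Resolve a run configuration: defaults < YAML file < overrides.

    Unknown keys in the file or overrides are rejected so typos cannot
    silently fall back to defaults.
    """
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg.update(user)
    unknown = set(overrides) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def dump_config(cfg: dict, path) -> str:
    """Write the resolved config beside outputs; returns its short hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = yaml.safe_dump(cfg, sort_keys=True)
    path.write_text(text, encoding="utf-8")
    return hashlib.sha256(text.encode()).hexdigest()[:12]
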