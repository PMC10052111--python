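"""Structured configuration: packaged defaults plus user overrides.

A single YAML file carries every auditable numeric constant -- the exposure
scenario, per-species kinetic parameters, the HDI calibration, background
level, MC/MH settings and the dose-response cap -- so a run is fully
described by (config, seed).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .kinetics import ExposureScenario, KineticParameters
from .reconstruct import ReconstructionConfig, RegressionCalibration


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_defaults() -> dict:
    text = resources.files("dihia.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Packaged defaults, deep-merged with the user's YAML file if given."""
    cfg = load_defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def scenario_from_config(cfg: dict) -> ExposureScenario:
    s = cfg["scenario"]
    return ExposureScenario(
        weeks=int(s["weeks"]),
        days_per_week=int(s["days_per_week"]),
        hours_per_day=float(s["hours_per_day"]),
        rpe_assumed=bool(s.get("rpe_assumed", False)),
    )


def kinetics_from_config(cfg: dict, species: str) -> KineticParameters:
    try:
        k = cfg["kinetics"][species]
    except KeyError:
        raise KeyError(
            f"no kinetic parameters configured for species {species!r} "
            f"(configured: {sorted(cfg.get('kinetics', {}))})"
        )
    return KineticParameters(
        absorbed_fraction=float(k["absorbed_fraction"]),
        ventilation_rate=float(k["ventilation_rate"]),
        elimination_half_life=float(k["elimination_half_life"]),
        urinary_excretion_fraction=float(k["urinary_excretion_fraction"]),
        urine_flow=float(k["urine_flow"]),
        error_gsd=float(k.get("error_gsd", 1.5)),
    )


def calibration_from_config(cfg: dict) -> RegressionCalibration:
    c = cfg["hdi_calibration"]
    return RegressionCalibration(
        slope=float(c["slope"]),
        intercept=float(c["intercept"]),
        air_range=tuple(float(v) for v in c["air_range"]),
        urine_range=tuple(float(v) for v in c["urine_range"]),
    )


def reconstruction_from_config(cfg: dict, seed: int = 0) -> ReconstructionConfig:
    r = cfg["reconstruction"]
    return ReconstructionConfig(
        background=float(r["background"]),
        n_mc=int(r["n_mc"]),
        mh_iterations=int(r["mh_iterations"]),
        mh_burn_in=int(r["mh_burn_in"]),
        proposal_scale=float(r["proposal_scale"]),
        prior_type=str(r["prior"]["type"]),
        prior_scale=float(r["prior"]["scale"]),
        include_zeros_in_gm=bool(r.get("include_zeros_in_gm", False)),
        default_creatinine=float(r.get("default_creatinine", 1.36)),
        seed=seed,
    )
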