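"""Synthetic left-censored biomonitoring and air-measurement data.

The non-public registry behind the study cannot ship with the package, so
every downstream stage is exercised on simulated data with the same
statistical structure: highly skewed concentrations, a large censored mass
below the LOQ, and rare high values.

Concentrations are drawn from a two-component lognormal mixture -- a
non-occupational background component and an exposed component
(background + occupational contribution) -- because a single lognormal
cannot reproduce both a 10-30% quantifiable fraction and the observed
max/P95 ratios.  The uncensored truth value of every record is retained so
reconstruction stages can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .measurements import Measurement
from .species import DiSpecies


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the two-component lognormal mixture generator.

    ``exposed_fraction`` of records receive an occupational contribution on
    top of background; geometric means (GM) are in the measurement's units
    and geometric standard deviations (GSD) are unitless and > 1.
    """

    n: int
    background_gm: float = 0.05
    background_gsd: float = 2.0
    exposed_fraction: float = 0.3
    exposed_gm: float = 1.0
    exposed_gsd: float = 3.0
    loq: float = 0.2
    creatinine_mean: float = 1.36  # g/L
    creatinine_gsd: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 <= self.exposed_fraction <= 1.0:
            raise ValueError("exposed_fraction must lie in [0, 1]")
        if self.background_gsd <= 1.0 or self.exposed_gsd <= 1.0 or self.creatinine_gsd <= 1.0:
            raise ValueError("GSD parameters must be > 1")
        if self.loq <= 0:
            raise ValueError("loq must be positive")


@dataclass
class SyntheticSample:
    """Censored measurements plus the uncensored truth values."""

    measurements: list[Measurement]
    truth: np.ndarray = field(repr=False)


def _draw_mixture(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    exposed = rng.random(cfg.n) < cfg.exposed_fraction
    vals = rng.lognormal(math.log(cfg.background_gm), math.log(cfg.background_gsd), cfg.n)
    n_exp = int(exposed.sum())
    if n_exp:
        vals[exposed] += rng.lognormal(
            math.log(cfg.exposed_gm), math.log(cfg.exposed_gsd), n_exp
        )
    return vals


def _censor(
    truth: np.ndarray,
    cfg: GeneratorConfig,
    analyte: str,
    matrix: str,
    sector: str,
    creatinine: np.ndarray | None,
) -> list[Measurement]:
    out = []
    for i, v in enumerate(truth):
        below = bool(v < cfg.loq)
        out.append(
            Measurement(
                analyte=analyte,
                matrix=matrix,
                value=float(v),
                loq=cfg.loq,
                below_loq=below,
                sector=sector,
                creatinine=None if creatinine is None else float(creatinine[i]),
            )
        )
    return out


def generate_urine_samples(
    cfg: GeneratorConfig, analyte: str = "MDA", sector: str = "synthetic"
) -> SyntheticSample:
    """Simulate urinary diamine concentrations (ug/L) with per-sample creatinine."""
    rng = np.random.default_rng(cfg.seed)
    truth = _draw_mixture(cfg, rng)
    creat = rng.lognormal(math.log(cfg.creatinine_mean), math.log(cfg.creatinine_gsd), cfg.n)
    return SyntheticSample(_censor(truth, cfg, analyte, "urine", sector, creat), truth)


def generate_air_samples(
    cfg: GeneratorConfig, species: DiSpecies, sector: str = "synthetic"
) -> SyntheticSample:
    """Simulate air concentrations in ug NCO/m3 for one species."""
    rng = np.random.default_rng(cfg.seed)
    truth = _draw_mixture(cfg, rng)
    return SyntheticSample(_censor(truth, cfg, species.name, "air", sector, None), truth)


def censored_fraction_analytic(cfg: GeneratorConfig) -> float:
    """Expected fraction of records below the LOQ under the mixture.

    For the exposed component the background addition is ignored (background
    GM is far below the occupational GM), giving the lognormal-CDF
    approximation that the empirical fraction converges to.
    """
    from scipy.stats import norm

    z_bg = (math.log(cfg.loq) - math.log(cfg.background_gm)) / math.log(cfg.background_gsd)
    z_exp = (math.log(cfg.loq) - math.log(cfg.exposed_gm)) / math.log(cfg.exposed_gsd)
    return (1 - cfg.exposed_fraction) * norm.cdf(z_bg) + cfg.exposed_fraction * norm.cdf(z_exp)


# ---------------------------------------------------------------------------
# Registry-like fixtures

SECTORS = ("construction", "motor_vehicle", "polyurethane", "assembly")


def _fixture_registry() -> dict:
    text = resources.files("dihia.data").joinpath("fixtures.yaml").read_text()
    return yaml.safe_load(text)


def table4_like_fixture(sector: str, metabolite: str = "MDA") -> SyntheticSample:
    """Seed-fixed urinary dataset emulating one sector/metabolite group.

    The generator configuration for each group is packaged and calibrated so
    that n, the quantifiable fraction and the GM/P95 summary of the fixture
    fall in the neighbourhood of the published sector statistics.  The same
    call always returns the identical dataset.
    """
    if sector not in SECTORS:
        raise KeyError(f"unknown sector {sector!r}; known: {SECTORS}")
    reg = _fixture_registry()
    try:
        raw = dict(reg[sector][metabolite])
    except KeyError:
        raise KeyError(f"no fixture for metabolite {metabolite!r} in sector {sector!r}")
    cfg = GeneratorConfig(**raw)
    return generate_urine_samples(cfg, analyte=metabolite, sector=sector)
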