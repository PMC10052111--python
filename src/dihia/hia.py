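"""Health impact assessment: excess BHR risks and case counts per sector.

Sector mean excess risk is the dose-response evaluated over all reconstructed
exposure draws (Monte Carlo average, capped), and the excess case count is
that unrounded risk applied to the sector's mean number of exposed workers.
Risk percentages are displayed to one decimal; case counts are rounded half
away from zero to whole workers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Sequence

import pandas as pd

from .doseresponse import DoseResponseCurve, build_spline, mean_excess_risk
from .measurements import round_half_away
from .reconstruct import ReconstructionResult


@dataclass(frozen=True)
class SectorWorkforce:
    """Worker counts for one occupation group."""

    sector: str
    total_workers: int
    exposed_range: tuple[int, int]
    mean_exposed: int

    def __post_init__(self) -> None:
        lo, hi = self.exposed_range
        if lo < 0 or hi < lo or self.total_workers < 0 or self.mean_exposed < 0:
            raise ValueError(f"{self.sector}: inconsistent worker counts")


@dataclass(frozen=True)
class SectorHIA:
    """Excess BHR risk (%) and case count for one sector/analyte pair."""

    sector: str
    analyte: str
    excess_risk: float
    excess_cases: int
    n_exposed: int


def load_workforce_table() -> list[SectorWorkforce]:
    """Packaged occupation-group worker estimates (national registry ranges)."""
    with resources.files("dihia.data").joinpath("workforce_finland.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        SectorWorkforce(
            sector=r.group,
            total_workers=int(r.total_workers),
            exposed_range=(int(r.exposed_low), int(r.exposed_high)),
            mean_exposed=int(r.mean_exposed),
        )
        for r in df.itertuples()
    ]


def load_hia_workforce() -> dict[str, int]:
    """Mean exposed workers per analysis sector (occupation groups combined)."""
    with resources.files("dihia.data").joinpath("hia_workforce.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["sector"], df["mean_exposed"].astype(int)))


def mean_exposed_workers(exposed_range: tuple[float, float]) -> int:
    """Midpoint of an exposed-worker range, rounded to the nearest hundred."""
    lo, hi = exposed_range
    if lo < 0 or hi < lo:
        raise ValueError("range must satisfy 0 <= low <= high")
    return int(round_half_away((lo + hi) / 2.0 / 100.0) * 100)


def excess_cases(n_exposed: int, risk_percent: float) -> int:
    """Expected excess cases among ``n_exposed`` workers at the given risk."""
    if n_exposed < 0:
        raise ValueError("worker count must be nonnegative")
    if risk_percent < 0:
        raise ValueError("risk must be nonnegative")
    return int(round_half_away(n_exposed * risk_percent / 100.0))


def task_split_scenario(
    n_total: int, splits: Sequence[tuple[float, str, float]]
) -> dict[str, int]:
    """Apportion a sector's workers across tasks with analyte-specific risks.

    ``splits`` is a sequence of (fraction of workers, analyte, risk %); the
    fractions must sum to at most 1.  Returns per-analyte case counts plus
    their sum under the key ``"combined"``.
    """
    total_fraction = sum(f for f, _, _ in splits)
    if total_fraction > 1 + 1e-12:
        raise ValueError(f"task fractions sum to {total_fraction:.3f} > 1")
    out: dict[str, int] = {}
    for fraction, analyte, risk in splits:
        out[analyte] = excess_cases(int(round_half_away(n_total * fraction)), risk)
    out["combined"] = sum(out.values())
    return out


def project_annual_cases(cases_per_year: float, years: float) -> float:
    """Total cases over a horizon from a constant annual incidence."""
    if cases_per_year < 0 or years < 0:
        raise ValueError("inputs must be nonnegative")
    return cases_per_year * years


def run_hia(
    workforce: Mapping[str, int],
    reconstructions: Mapping[tuple[str, str], ReconstructionResult | None],
    curve: DoseResponseCurve,
    interpolator: Callable | None = None,
) -> tuple[list[SectorHIA], list[tuple[str, str, str]]]:
    """Compute excess risk and cases for every sector/analyte reconstruction.

    ``reconstructions`` maps (sector, analyte) to a result, or to ``None``
    for pairs explicitly excluded from assessment (too few quantifiable
    measurements); exclusions are returned separately with a reason.  Case
    counts use the unrounded mean risk; the stored risk is the same unrounded
    value (round for display).
    """
    interp = interpolator or build_spline(curve)
    results: list[SectorHIA] = []
    exclusions: list[tuple[str, str, str]] = []
    for (sector, analyte), recon in sorted(reconstructions.items()):
        if recon is None:
            exclusions.append(
                (sector, analyte, "excluded: too few measurements above LOQ")
            )
            continue
        if sector not in workforce:
            raise KeyError(f"no workforce record for sector {sector!r}")
        n_exposed = int(workforce[sector])
        risk = mean_excess_risk(recon.draws, interp)
        results.append(
            SectorHIA(
                sector=sector,
                analyte=analyte,
                excess_risk=risk,
                excess_cases=excess_cases(n_exposed, risk),
                n_exposed=n_exposed,
            )
        )
    return results, exclusions


def hia_table(results: Sequence[SectorHIA]) -> pd.DataFrame:
    """Tabulate HIA results with display rounding (risk to one decimal)."""
    return pd.DataFrame(
        {
            "sector": [r.sector for r in results],
            "analyte": [r.analyte for r in results],
            "n_exposed": [r.n_exposed for r in results],
            "excess_risk_percent": [round_half_away(r.excess_risk, 1) for r in results],
            "excess_cases": [r.excess_cases for r in results],
        }
    )
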