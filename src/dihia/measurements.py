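"""Measurement records, censoring rules, unit conversions and summaries.

Air measurements are in ug/m3 (converted to ug NCO/m3 for comparability);
urinary diamine measurements are in ug/L, optionally accompanied by the
sample's creatinine in g/L.  Values below the limit of quantitation (LOQ)
are censored; for statistics and reconstruction they are substituted with
LOQ/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_MATRICES = ("air", "urine")

#: default quantile convention: linear interpolation between order statistics
#: at plotting positions (k-1)/(n-1), so min and max are the 0th and 100th
#: percentiles and the inverse CDF spans the observed range.
DEFAULT_QUANTILE_METHOD = "linear"


@dataclass(frozen=True)
class Measurement:
    """One air or urine observation.

    ``value`` is the reported concentration (ug/m3 for air, ug/L for urine),
    ``loq`` the limit of quantitation in the same units, and ``below_loq``
    marks a censored record whose raw value must not be used downstream
    without substitution.
    """

    analyte: str
    matrix: str
    value: float
    loq: float
    below_loq: bool = False
    sector: str = ""
    creatinine: float | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.matrix not in VALID_MATRICES:
            raise ValueError(f"matrix must be one of {VALID_MATRICES}, got {self.matrix!r}")
        if self.value < 0:
            raise ValueError(f"{self.analyte}: value must be nonnegative")
        if self.creatinine is not None and self.creatinine <= 0:
            raise ValueError(f"{self.analyte}: creatinine must be positive")

    @property
    def default_unit(self) -> str:
        return "ug/m3" if self.matrix == "air" else "ug/L"


@dataclass(frozen=True)
class SummaryStats:
    """GM / P50 / P95 / max summary of one analyte-sector group."""

    n: int
    n_geq_loq: int
    gm: float
    p50: float
    p95: float
    max: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_geq_loq <= self.n:
            raise ValueError("n_geq_loq must lie in [0, n]")
        if not (self.p50 <= self.p95 <= self.max) and not any(
            math.isnan(x) for x in (self.p50, self.p95, self.max)
        ):
            raise ValueError("quantiles must be ordered p50 <= p95 <= max")

    @property
    def pct_geq_loq(self) -> float:
        return round_half_away(100.0 * self.n_geq_loq / self.n, 1)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (5 rounds up in magnitude)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def substitute_below_loq(records: Sequence[Measurement]) -> list[Measurement]:
    """Replace censored values with LOQ/2, leaving order and the rest intact.

    Idempotent: substituted records remain flagged ``below_loq`` but already
    carry LOQ/2, so a second pass changes nothing.
    """
    out = []
    for i, m in enumerate(records):
        if m.below_loq:
            if not m.loq or m.loq <= 0:
                raise ValueError(
                    f"record {i} ({m.analyte}, sector={m.sector!r}) is censored "
                    f"but has non-positive LOQ {m.loq!r}"
                )
            out.append(replace(m, value=m.loq / 2.0))
        else:
            out.append(m)
    return out


def convert_creatinine_units(conc_per_g_creat: float, creatinine: float) -> float:
    """Convert ug analyte / g creatinine to ug/L using the sample creatinine (g/L)."""
    if creatinine <= 0:
        raise ValueError("creatinine concentration must be positive")
    return conc_per_g_creat * creatinine


def convert_to_per_g_creatinine(conc_per_l: float, creatinine: float) -> float:
    """Inverse of :func:`convert_creatinine_units` (ug/L -> ug/g creatinine)."""
    if creatinine <= 0:
        raise ValueError("creatinine concentration must be positive")
    return conc_per_l / creatinine


def exceedance_stats(values: Iterable[float], threshold: float) -> tuple[int, float]:
    """Count values strictly above an exposure limit.

    Returns ``(count, percent)``, the percentage rounded half away from zero
    to one decimal place.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute exceedance of an empty sample")
    count = int(np.sum(arr > threshold))
    return count, round_half_away(100.0 * count / arr.size, 1)


def quantile(values: Sequence[float], p, method: str = DEFAULT_QUANTILE_METHOD):
    """Empirical quantile with the package-wide convention.

    ``method`` is passed to :func:`numpy.quantile`; the default ``"linear"``
    interpolates between order statistics at positions (k-1)/(n-1).
    """
    return np.quantile(np.asarray(values, dtype=float), p, method=method)


def summarize(
    records: Sequence[Measurement], method: str = DEFAULT_QUANTILE_METHOD
) -> SummaryStats:
    """Summary statistics of a (LOQ-substituted) group of measurements.

    Censored records must already carry their LOQ/2 substitute; the geometric
    mean is undefined otherwise (and for zero values generally).
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty group")
    vals = np.array([m.value for m in records], dtype=float)
    if np.any(vals <= 0):
        raise ValueError(
            "geometric mean undefined: non-positive value present "
            "(did you run substitute_below_loq first?)"
        )
    return SummaryStats(
        n=len(records),
        n_geq_loq=int(sum(not m.below_loq for m in records)),
        gm=float(np.exp(np.mean(np.log(vals)))),
        p50=float(quantile(vals, 0.5, method)),
        p95=float(quantile(vals, 0.95, method)),
        max=float(vals.max()),
    )


# ---------------------------------------------------------------------------
# CSV IO

_COLUMNS = ["analyte", "matrix", "value", "unit", "loq", "below_loq", "sector", "creatinine"]
_EXPECTED_UNITS = {"air": "ug/m3", "urine": "ug/L"}


def read_measurements(path) -> list[Measurement]:
    """Read a measurement table (CSV) into records.

    The header must contain at least analyte, matrix, value, unit and loq.
    The declared unit must match the matrix (air: ug/m3, urine: ug/L).
    Malformed rows are reported with their line number.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, expected header with columns {_COLUMNS[:5]}")
    missing = [c for c in ("analyte", "matrix", "value", "unit", "loq") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        matrix = str(row["matrix"])
        unit = str(row["unit"])
        if _EXPECTED_UNITS.get(matrix) != unit:
            raise ValueError(
                f"{path}: line {line}: unit {unit!r} does not match matrix "
                f"{matrix!r} (expected {_EXPECTED_UNITS.get(matrix)!r})"
            )
        creat = row.get("creatinine")
        if creat is not None and (pd.isna(creat) or matrix == "air"):
            creat = None
        below = row.get("below_loq", False)
        below = False if pd.isna(below) else bool(below)
        try:
            records.append(
                Measurement(
                    analyte=str(row["analyte"]),
                    matrix=matrix,
                    value=float(row["value"]),
                    loq=float(row["loq"]),
                    below_loq=below,
                    sector=("" if pd.isna(row.get("sector", "")) else str(row.get("sector", ""))),
                    creatinine=None if creat is None else float(creat),
                    unit=unit,
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: line {line}: {err}") from err
    return records


def write_measurements(records: Sequence[Measurement], path) -> None:
    """Write records as CSV such that ``read_measurements`` round-trips."""
    rows = []
    for m in records:
        rows.append(
            {
                "analyte": m.analyte,
                "matrix": m.matrix,
                "value": m.value,
                "unit": m.unit or m.default_unit,
                "loq": m.loq,
                "below_loq": m.below_loq,
                "sector": m.sector,
                "creatinine": m.creatinine,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
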