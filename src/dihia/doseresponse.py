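"""Excess-risk dose-response for bronchial hyperresponsiveness (BHR).

The regulatory risk-assessment committee published the relation between
working-life air NCO exposure and excess BHR risk as a table of risk bands:

    0.1%  < 0.025        ug NCO/m3
    0.5%  0.027 - 0.040
    1%    0.055 - 0.070
    2%    0.12  - 0.19
    3%    0.22  - 0.33
    4%    0.40  - 0.48
    5%    > 0.67

Two evaluation modes are provided: a direct band lookup, and a monotone
(shape-preserving cubic) spline through the band midpoints anchored at
(0, 0), which integrates smoothly over a whole exposure distribution.
Evaluation is capped at 7.5% excess risk so that exposures far above the
highest reported band never extrapolate beyond it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

DEFAULT_CAP = 7.5  # % excess risk


@dataclass(frozen=True)
class DoseResponseCurve:
    """Risk bands (risk %, exposure range in ug NCO/m3) plus the cap.

    ``bands`` are (risk, low, high) with ``high = inf`` for the open top
    band; ``knots`` are (exposure, risk) pairs at the band midpoints (the
    open band contributes its lower bound) with a (0, 0) anchor.
    """

    bands: tuple[tuple[float, float, float], ...]
    cap: float = DEFAULT_CAP
    knots: tuple[tuple[float, float], ...] = field(init=False)

    def __post_init__(self) -> None:
        risks = [b[0] for b in self.bands]
        if any(r2 <= r1 for r1, r2 in zip(risks, risks[1:])):
            raise ValueError("band risks must be strictly increasing")
        for (_, lo1, hi1), (_, lo2, _) in zip(self.bands, self.bands[1:]):
            if lo2 < hi1 or lo1 > lo2:
                raise ValueError("exposure ranges must be non-overlapping and increasing")
        if self.cap < max(risks):
            raise ValueError("cap must not be below the highest band risk")
        knots = [(0.0, 0.0)]
        for risk, lo, hi in self.bands:
            x = lo if math.isinf(hi) else 0.5 * (lo + hi)
            knots.append((x, risk))
        object.__setattr__(self, "knots", tuple(knots))


def load_rac_curve(cap: float = DEFAULT_CAP) -> DoseResponseCurve:
    """Load the packaged excess-risk band table."""
    with resources.files("dihia.data").joinpath("rac_excess_risk.csv").open() as fh:
        df = pd.read_csv(fh)
    bands = tuple(
        (
            float(r.risk_percent),
            float(r.exposure_low),
            math.inf if pd.isna(r.exposure_high) else float(r.exposure_high),
        )
        for r in df.itertuples()
    )
    return DoseResponseCurve(bands=bands, cap=cap)


def lookup_rac_band(exposure: float, curve: DoseResponseCurve) -> float:
    """Risk (%) of the band containing ``exposure``.

    Below the lowest band the lowest risk applies; in a gap between bands the
    lower band's risk applies; above the top band's lower bound the highest
    tabulated risk applies.
    """
    if exposure < 0:
        raise ValueError("exposure must be nonnegative")
    risk = curve.bands[0][0]
    for band_risk, lo, hi in curve.bands:
        if exposure >= lo:
            risk = band_risk
        if lo <= exposure <= hi:
            return band_risk
    return risk


def build_spline(curve: DoseResponseCurve):
    """Monotone interpolator over the band-midpoint knots, capped.

    Within the knot range a shape-preserving cubic (PCHIP) passes exactly
    through every knot; above the last knot the risk continues linearly with
    the final PCHIP slope until it hits the cap, then stays flat.  Returns a
    vectorised callable with values in [0, cap].
    """
    x = np.array([k[0] for k in curve.knots])
    y = np.array([k[1] for k in curve.knots])
    if np.any(np.diff(x) <= 0) or np.any(np.diff(y) < 0):
        raise ValueError("knots must be strictly increasing in exposure and nondecreasing in risk")
    pchip = PchipInterpolator(x, y, extrapolate=False)
    x_last, y_last = x[-1], y[-1]
    slope = float(pchip.derivative()(x_last))
    if slope <= 0:  # fall back to the secant of the last two knots
        slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
    cap = curve.cap

    def evaluate(exposure):
        e = np.asarray(exposure, dtype=float)
        out = np.where(
            e <= x_last,
            pchip(np.clip(e, x[0], x_last)),
            y_last + slope * (e - x_last),
        )
        out = np.clip(out, 0.0, cap)
        return float(out) if np.isscalar(exposure) else out

    return evaluate


def mean_excess_risk(draws, interpolator) -> float:
    """Average capped excess risk (%) over reconstructed exposure draws."""
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise ValueError("draws must be nonempty")
    return float(np.mean(interpolator(arr)))
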