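"""One-compartment linear toxicokinetics with an exact piecewise solution.

The body burden B of absorbed diisocyanate-derived diamine obeys

    dB/dt = R - k B        during exposure windows (R = intake rate)
    dB/dt = -k B           otherwise,

with k = ln 2 / half-life and R = absorbed_fraction * ventilation_rate *
c_air.  Both phases have closed forms, so the burden at the end of any
work-rest schedule is computed exactly by composing

    exposure of length T:  B -> R/k (1 - e^{-kT}) + B e^{-kT}
    rest of length T:      B -> B e^{-kT}

over shifts, nights and weekends -- no numerical ODE integration.  The
urinary diamine concentration at sampling is the steady excretion rate
divided by urine flow:

    u = urinary_excretion_fraction * k * B / urine_flow        [ug/L]

Everything is linear in c_air, the property all reconstruction logic relies
on: the model is evaluated once at unit concentration and scaled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ExposureScenario:
    """Work schedule assumed for exposure reconstruction.

    Defaults: 12 weeks of exposure, five days a week, eight hours a day,
    urine sampled post-shift on the last working day, no respiratory
    protection assumed.
    """

    weeks: int = 12
    days_per_week: int = 5
    hours_per_day: float = 8.0
    rpe_assumed: bool = False

    def __post_init__(self) -> None:
        if self.weeks < 1 or self.days_per_week < 1 or self.hours_per_day <= 0:
            raise ValueError("scenario durations must be positive")
        if self.days_per_week > 7 or self.hours_per_day > 24:
            raise ValueError("scenario does not fit in a calendar week")


@dataclass(frozen=True)
class KineticParameters:
    """Linear kinetic parameters for one diisocyanate species.

    Units: ventilation_rate m3/h, elimination_half_life h, urine_flow L/h;
    absorbed_fraction and urinary_excretion_fraction are proportions;
    error_gsd is the geometric standard deviation of the lognormal
    observation error around the model prediction.
    """

    absorbed_fraction: float
    ventilation_rate: float
    elimination_half_life: float
    urinary_excretion_fraction: float
    urine_flow: float
    error_gsd: float = 1.5

    def __post_init__(self) -> None:
        for f in (
            "absorbed_fraction",
            "ventilation_rate",
            "elimination_half_life",
            "urinary_excretion_fraction",
            "urine_flow",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"kinetic parameter {f} must be positive")
        if self.absorbed_fraction > 1 or self.urinary_excretion_fraction > 1:
            raise ValueError("fractions must not exceed 1")
        if self.error_gsd <= 1:
            raise ValueError("error_gsd must be > 1")

    @property
    def elimination_rate(self) -> float:
        """First-order elimination rate constant, 1/h."""
        return math.log(2.0) / self.elimination_half_life


def _burden_at_sampling(scenario: ExposureScenario, params: KineticParameters) -> float:
    """Body burden per unit air concentration at the end of the last shift."""
    k = params.elimination_rate
    rate_per_unit = params.absorbed_fraction * params.ventilation_rate  # R at c_air = 1
    h = scenario.hours_per_day
    night = 24.0 - h
    # gap from end of the last shift of a week to the start of the next week's
    # first shift
    weekend = night + 24.0 * (7 - scenario.days_per_week)

    decay_shift = math.exp(-k * h)
    gain_shift = rate_per_unit / k * (1.0 - decay_shift)
    decay_night = math.exp(-k * night)
    decay_weekend = math.exp(-k * weekend)

    b = 0.0
    for week in range(scenario.weeks):
        for day in range(scenario.days_per_week):
            b = gain_shift + b * decay_shift
            last = week == scenario.weeks - 1 and day == scenario.days_per_week - 1
            if last:
                return b  # sampled post-shift, before any further decay
            b *= decay_weekend if day == scenario.days_per_week - 1 else decay_night
    raise AssertionError("unreachable")


def kinetic_forward(
    c_air: float, scenario: ExposureScenario, params: KineticParameters
) -> float:
    """Urinary diamine concentration (ug/L) predicted for a constant shift-time
    air concentration ``c_air`` (ug NCO/m3), sampled post-shift on the last
    working day of the scenario."""
    if c_air < 0:
        raise ValueError("air concentration must be nonnegative")
    k = params.elimination_rate
    burden = c_air * _burden_at_sampling(scenario, params)
    return params.urinary_excretion_fraction * k * burden / params.urine_flow


def unit_response(scenario: ExposureScenario, params: KineticParameters) -> float:
    """Urinary level per unit air concentration: ``kinetic_forward(1, ...)``.

    Because the kinetics are linear this single number characterises the
    forward model, and inversion of a noise-free observation is ``u / A``.
    """
    return kinetic_forward(1.0, scenario, params)
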