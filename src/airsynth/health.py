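"""PM2.5-attributable mortality under a pluggable exposure-response curve.

Converts long-term PM2.5 exposure scenarios into attributable fractions and
premature-death counts: ``AF = 1 - 1/RR(c)`` and ``deaths = AF * D`` for
baseline annual deaths ``D``. The default relative-risk curve is log-linear
above a counterfactual threshold, ``RR = exp(beta * max(0, c - c0))``; any
alternative curve (e.g. a tabulated integrated exposure-response) can be
supplied as a callable ``c -> RR``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "HealthParams",
    "HealthImpact",
    "relative_risk",
    "attributable_deaths",
    "avoided_deaths",
]


@dataclass
class HealthParams:
    """Exposure-response and population inputs.

    beta : per-(μg m⁻³) log relative risk (default 0.0076, a widely used
        all-cause long-term PM2.5 slope of ~8% excess risk per 10 μg m⁻³).
    c0 : counterfactual concentration below which no excess risk accrues.
    baseline_deaths : annual deaths in the exposed population.
    rr_curve : optional callable overriding the log-linear default.
    """

    beta: float = 0.0076
    c0: float = 5.0
    baseline_deaths: float = 0.0
    rr_curve: Callable[[float], float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.beta < 0 or self.c0 < 0 or self.baseline_deaths < 0:
            raise ValueError("beta, c0 and baseline_deaths must be >= 0")


@dataclass
class HealthImpact:
    af: float
    deaths: float
    concentration: float


def relative_risk(c, params: HealthParams):
    """Relative risk at concentration ``c`` (μg m⁻³); always >= 1."""
    c = np.asarray(c, dtype=float)
    if (c < 0).any():
        raise ValueError("concentrations must be >= 0")
    if params.rr_curve is not None:
        rr = np.vectorize(params.rr_curve, otypes=[float])(c)
        if (rr < 1).any():
            raise ValueError("rr_curve returned RR < 1")
    else:
        rr = np.exp(params.beta * np.maximum(0.0, c - params.c0))
    return rr if rr.shape else float(rr)


def attributable_deaths(c_scenario: float, params: HealthParams) -> HealthImpact:
    """Attributable fraction and deaths for one exposure scenario."""
    rr = relative_risk(c_scenario, params)
    af = 1.0 - 1.0 / rr
    return HealthImpact(
        af=float(af),
        deaths=float(af * params.baseline_deaths),
        concentration=float(c_scenario),
    )


def avoided_deaths(deaths_baseline_year: float, deaths_current_year: float) -> float:
    """Premature deaths avoided relative to a named baseline year."""
    if deaths_baseline_year < 0 or deaths_current_year < 0:
        raise ValueError("death counts must be >= 0")
    return deaths_baseline_year - deaths_current_year
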