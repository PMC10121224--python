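"""Curve-quality classification for fitted concentration-response curves.

A well-behaved activation curve (i) starts near zero at low concentration,
(ii) rises with concentration by a meaningful amplitude, (iii) has its
inflection (AC50) inside the tested concentration range, and (iv) reaches a
plateau by the top tested concentration.  These qualitative requirements are
made operational with explicit numeric thresholds (all configurable):

==============  =============================================  =========
tag             check                                          default
==============  =============================================  =========
BASELINE        \\|A0\\| <= baseline_tolerance                   20 %
MONOTONE        Ainf - A0 >= amplitude_threshold (rising)      20 %
INFLECTION      log AC50 inside the tested log-range           —
PLATEAU         \\|A(c_max) - Ainf\\| <= plateau_tolerance       10 %
FIT_QUALITY     r^2 >= min_r2                                  0.7
DATA            >= 4 distinct concentrations and converged     —
==============  =============================================  =========

All pass -> ACTIVE_FULL.  Curves failing only the plateau and/or having an
above-range inflection -> ACTIVE_PARTIAL (real activity, incompletely
sampled).  Amplitude below threshold, including flat or falling curves, ->
INACTIVE.  Anything else -> INCONCLUSIVE, with the failed tags recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .hill import MIN_DISTINCT_CONC, HillFit, hill_response


class CurveClassValue(str, Enum):
    ACTIVE_FULL = "ACTIVE_FULL"
    ACTIVE_PARTIAL = "ACTIVE_PARTIAL"
    INCONCLUSIVE = "INCONCLUSIVE"
    INACTIVE = "INACTIVE"


@dataclass(frozen=True)
class CurveClass:
    value: CurveClassValue
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.value == CurveClassValue.ACTIVE_FULL and self.reasons:
            raise ValueError("ACTIVE_FULL implies no failed criteria")

    @property
    def is_active(self) -> bool:
        return self.value in (
            CurveClassValue.ACTIVE_FULL,
            CurveClassValue.ACTIVE_PARTIAL,
        )


@dataclass(frozen=True)
class ClassifyThresholds:
    baseline_tolerance: float = 20.0  # % units on A0
    amplitude_threshold: float = 20.0  # % units on Ainf - A0
    plateau_tolerance: float = 10.0  # % units at the top concentration
    min_r2: float = 0.7

    def validate(self) -> None:
        if self.baseline_tolerance < 0 or self.plateau_tolerance < 0:
            raise ValueError("tolerances must be >= 0")
        if self.amplitude_threshold < 0:
            raise ValueError("amplitude_threshold must be >= 0")
        if not (0 <= self.min_r2 <= 1):
            raise ValueError("min_r2 must be in [0, 1]")


def classify_curve(
    fit: HillFit,
    points: Sequence[tuple[float, float]],
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> CurveClass:
    """Assign a deterministic curve class to an attempted fit."""
    thresholds.validate()
    conc = np.array([p[0] for p in points], dtype=float)

    if (
        not fit.converged
        or fit.params is None
        or len(np.unique(conc)) < MIN_DISTINCT_CONC
    ):
        return CurveClass(CurveClassValue.INCONCLUSIVE, ("DATA",))

    p = fit.params
    log_lo, log_hi = float(np.log10(conc.min())), float(np.log10(conc.max()))
    amplitude = p.ainf - p.a0

    reasons: list[str] = []
    if abs(p.a0) > thresholds.baseline_tolerance:
        reasons.append("BASELINE")
    if amplitude < thresholds.amplitude_threshold:
        reasons.append("MONOTONE")
    above_range = p.log_ac50 > log_hi
    if not (log_lo <= p.log_ac50 <= log_hi):
        reasons.append("INFLECTION")
    top = float(hill_response(p, conc.max()))
    if abs(top - p.ainf) > thresholds.plateau_tolerance:
        reasons.append("PLATEAU")
    if fit.r2 < thresholds.min_r2:
        reasons.append("FIT_QUALITY")

    if not reasons:
        return CurveClass(CurveClassValue.ACTIVE_FULL)
    if "MONOTONE" in reasons and amplitude < thresholds.amplitude_threshold:
        # flat, weak, or falling response: no usable activation signal
        return CurveClass(CurveClassValue.INACTIVE, tuple(reasons))
    partial_ok = set(reasons) <= {"PLATEAU", "INFLECTION"} and (
        "INFLECTION" not in reasons or above_range
    )
    if partial_ok:
        return CurveClass(CurveClassValue.ACTIVE_PARTIAL, tuple(reasons))
    return CurveClass(CurveClassValue.INCONCLUSIVE, tuple(reasons))
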