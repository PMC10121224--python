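"""Hit triage: combine per-compound fits into a ranked candidate list.

A desirable compound has high efficacy (large fitted Ainf, small efficacy
AC50), low toxicity, and low autofluorescence.  The latter two are judged as
selectivity ratios

    ratio_tox   = AC50_toxicity     / AC50_efficacy  >> 1
    ratio_fluor = AC50_fluorescence / AC50_efficacy  >> 1

where a counter-curve with no usable activity contributes a ratio of +inf
(no measurable liability inside the tested range).  The ">> 1" requirement
is operationalized as a configurable minimum ratio, default 10 (the
conventional selectivity-index margin; a permissive preset of 3 exists).
Toxicity is checked before autofluorescence, mirroring a funnel that first
drops toxic compounds and then artifact false-positives.  Hits are ranked
by fitted efficacy amplitude (descending), then potency (ascending AC50),
then compound id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import ClassifyThresholds, CurveClass, CurveClassValue
from .errors import ScreenError
from .hill import HillFit

VERDICTS = ("HIT", "TOXIC", "AUTOFLUORESCENT", "INACTIVE", "INCONCLUSIVE")


@dataclass(frozen=True)
class TriageConfig:
    min_ratio: float = 10.0  # selectivity margin implementing ">> 1"
    min_ainf_efficacy: float = 30.0  # % of the WT-RD16 window
    amplitude_threshold: float = 20.0  # counter-curve activity floor (classify)

    def validate(self) -> None:
        if self.min_ratio < 1:
            raise ValueError("min_ratio must be >= 1")
        if self.min_ainf_efficacy < 0:
            raise ValueError("min_ainf_efficacy must be >= 0")

    @classmethod
    def permissive(cls) -> "TriageConfig":
        return cls(min_ratio=3.0)


@dataclass(frozen=True)
class TriageVerdict:
    compound_id: str
    ratio_tox: float  # AC50_tox / AC50_eff, +inf when toxicity inactive
    ratio_fluor: float  # AC50_fluor / AC50_eff, +inf when fluorescence inactive
    ainf_efficacy: float
    ac50_efficacy: float
    efficacy_class: CurveClass | None
    verdict: str

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict == "HIT" and not (
            self.efficacy_class and self.efficacy_class.is_active
        ):
            raise ValueError("HIT requires an active efficacy curve class")

    @property
    def rank_key(self):
        return (-self.ainf_efficacy, self.ac50_efficacy, self.compound_id)


def _counter_ratio(fit: HillFit | None, eff_ac50: float) -> float:
    """Selectivity ratio for a toxicity/fluorescence counter-curve.

    Curves that are absent, unconverged, flat (amplitude below threshold),
    or poorly fit carry no usable liability estimate and contribute +inf
    (treated as passing).  A credible liability curve counts even when
    incomplete — an AC50 below the tested range, a missing plateau, or a
    shifted baseline still demonstrates the liability (if anything, a
    below-range AC50 means the liability is more potent than anything
    tested), so only MONOTONE, FIT_QUALITY, and DATA failures disqualify.
    """
    if fit is None or not fit.converged or fit.params is None:
        return math.inf
    cc = fit.curve_class
    if cc is not None and not cc.is_active:
        disqualifying = {"MONOTONE", "FIT_QUALITY", "DATA"}
        if disqualifying & set(cc.reasons):
            return math.inf
    return (10.0 ** fit.params.log_ac50) / eff_ac50


def triage_compound(
    fits: Mapping[str, HillFit | None],
    config: TriageConfig = TriageConfig(),
) -> TriageVerdict:
    """Decide one compound from its EFFICACY / TOXICITY / FLUORESCENCE fits.

    Each fit is expected to carry its curve_class (see
    :func:`organoscreen.classify.classify_curve`).
    """
    config.validate()
    eff = fits.get("EFFICACY")
    cid = next(
        (f.compound_id for f in fits.values() if f is not None), ""
    )

    def verdict(v, ratio_tox=math.inf, ratio_fluor=math.inf, ainf=math.nan, ac50=math.nan, cc=None):
        return TriageVerdict(
            compound_id=cid,
            ratio_tox=ratio_tox,
            ratio_fluor=ratio_fluor,
            ainf_efficacy=ainf,
            ac50_efficacy=ac50,
            efficacy_class=cc,
            verdict=v,
        )

    if eff is None or not eff.converged or eff.params is None:
        return verdict("INCONCLUSIVE")
    cc = eff.curve_class
    if cc is None:
        raise ScreenError("efficacy fit must be classified before triage")
    if cc.value == CurveClassValue.INACTIVE:
        return verdict("INACTIVE", cc=cc)
    if cc.value == CurveClassValue.INCONCLUSIVE:
        return verdict("INCONCLUSIVE", cc=cc)

    ainf = eff.params.ainf
    eff_ac50 = 10.0 ** eff.params.log_ac50
    ratio_tox = _counter_ratio(fits.get("TOXICITY"), eff_ac50)
    ratio_fluor = _counter_ratio(fits.get("FLUORESCENCE"), eff_ac50)

    if ainf < config.min_ainf_efficacy:
        v = "INACTIVE"
    elif ratio_tox < config.min_ratio:
        v = "TOXIC"
    elif ratio_fluor < config.min_ratio:
        v = "AUTOFLUORESCENT"
    else:
        v = "HIT"
    return verdict(v, ratio_tox, ratio_fluor, ainf, eff_ac50, cc)


def triage_campaign(
    fits: list[HillFit],
    config: TriageConfig = TriageConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triage every compound; return (verdict table, ranked hit list).

    Verdict rows are ordered by compound id; the hit list is ordered by
    fitted efficacy amplitude (desc), AC50 (asc), compound id.
    """
    grouped: dict[str, dict[str, HillFit]] = {}
    for f in fits:
        d = grouped.setdefault(f.compound_id, {})
        if f.score_type in d:
            raise ScreenError(
                f"compound {f.compound_id!r}: duplicate {f.score_type} fit"
            )
        d[f.score_type] = f

    verdicts = [triage_compound(d, config) for _, d in sorted(grouped.items())]
    table = pd.DataFrame(
        {
            "compound_id": [v.compound_id for v in verdicts],
            "ratio_tox": [v.ratio_tox for v in verdicts],
            "ratio_fluor": [v.ratio_fluor for v in verdicts],
            "ainf_efficacy": [v.ainf_efficacy for v in verdicts],
            "ac50_efficacy": [v.ac50_efficacy for v in verdicts],
            "efficacy_class": [
                v.efficacy_class.value.value if v.efficacy_class else ""
                for v in verdicts
            ],
            "verdict": [v.verdict for v in verdicts],
        }
    )
    hits = [v for v in verdicts if v.verdict == "HIT"]
    hits.sort(key=lambda v: v.rank_key)
    ranked = pd.DataFrame(
        {
            "rank": np.arange(1, len(hits) + 1),
            "compound_id": [v.compound_id for v in hits],
            "ainf_efficacy": [v.ainf_efficacy for v in hits],
            "ac50_efficacy": [v.ac50_efficacy for v in hits],
            "ratio_tox": [v.ratio_tox for v in hits],
            "ratio_fluor": [v.ratio_fluor for v in hits],
        }
    )
    return table, ranked
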