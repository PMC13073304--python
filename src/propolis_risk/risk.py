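"""Deterministic oral-exposure and risk computation.

Average daily dose (ADD, mg per kg body weight per day) from a
concentration C (ppm) under a scenario:

    ADD = C * IngR * EF * ED / (BW * AT_days)

With the averaging time matched to the exposure duration (AT = 365 * ED)
the ED cancels and ADD = C * IngR * EF / (BW * 365); with a lifetime
averaging time, AT = 365 * life_expectancy.

Hazard quotient HQ = ADD / RfD, flagged as a potential concern when
strictly above 1. Carcinogenic risk is characterized from the lifetime
ADD and the slope factor; the conventional multiplicative form
CR = ADD * SF is the default (see ``carcinogenic_risk`` for the
alternative quotient form), and CR is banded against the usual
1e-6 .. 1e-3 screening levels.
"""

from __future__ import annotations

import enum
import math
from typing import Mapping, Sequence

from .io_datamodel import (
    ATRule,
    Element,
    ExposureScenario,
    Policy,
    RiskResult,
    SampleRecord,
    ToxParams,
    DEFAULT_TOX,
    substitute_censored,
)

__all__ = [
    "CRFormula",
    "HQ_LABELS",
    "CR_LABELS",
    "average_daily_dose",
    "hazard_quotient",
    "classify_hq",
    "carcinogenic_risk",
    "classify_cr",
    "assess_dataset",
]


class CRFormula(str, enum.Enum):
    MULTIPLY = "multiply"  # CR = ADD * SF (conventional; default)
    DIVIDE = "divide"  # CR = ADD / SF (literal alternative)


HQ_LABELS = ("no_concern", "potential_risk")
CR_LABELS = ("very_low", "above_screening", "low", "moderate", "substantial")


def average_daily_dose(c: float, scenario: ExposureScenario) -> float:
    """ADD in mg/kg_bw/day from a concentration ``c`` in ppm."""
    if not math.isfinite(c) or c < 0:
        raise ValueError(f"concentration must be finite and >= 0, got {c}")
    return c * scenario.ingr * scenario.ef * scenario.ed / (scenario.bw * scenario.at_days)


def classify_hq(hq: float) -> str:
    if hq < 0:
        raise ValueError("HQ must be nonnegative")
    return "potential_risk" if hq > 1.0 else "no_concern"


def hazard_quotient(add: float, tox: ToxParams) -> tuple[float, str]:
    """HQ = ADD / RfD, plus its concern label (potential risk iff HQ > 1)."""
    if add < 0:
        raise ValueError("ADD must be nonnegative")
    if tox.rfd is None or not tox.rfd > 0:
        raise ValueError(f"{tox.element}: missing or invalid RfD")
    hq = add / tox.rfd
    return hq, classify_hq(hq)


def carcinogenic_risk(
    add_lifetime: float,
    tox: ToxParams,
    formula: CRFormula = CRFormula.MULTIPLY,
) -> float:
    """Carcinogenic risk from a lifetime-averaged ADD and a slope factor.

    The default multiplicative characterization (CR = ADD * SF) is the
    standard dose-times-potency form; ``formula="divide"`` computes the
    literal quotient ADD / SF instead. Elements without a slope factor
    (Mn) are non-carcinogenic here and raise an error.
    """
    if add_lifetime < 0:
        raise ValueError("lifetime ADD must be nonnegative")
    if tox.sf is None:
        raise ValueError(f"{tox.element} has no slope factor (non-carcinogenic element)")
    if formula is CRFormula.MULTIPLY:
        return add_lifetime * tox.sf
    return add_lifetime / tox.sf


def classify_cr(cr: float) -> str:
    """Band a carcinogenic risk value.

    Partition of [0, inf): very_low below 1e-6, above_screening in
    [1e-6, 1e-5), low in [1e-5, 1e-4), moderate in [1e-4, 1e-3),
    substantial at or above 1e-3. Exactly one label for every
    nonnegative value.
    """
    if cr < 0:
        raise ValueError("CR must be nonnegative")
    if cr >= 1e-3:
        return "substantial"
    if cr >= 1e-4:
        return "moderate"
    if cr >= 1e-5:
        return "low"
    if cr >= 1e-6:
        return "above_screening"
    return "very_low"


def assess_dataset(
    samples: Sequence[SampleRecord],
    scenario: ExposureScenario = ExposureScenario(),
    tox: Mapping[Element, ToxParams] = DEFAULT_TOX,
    policy: Policy = Policy.ZERO,
    formula: CRFormula = CRFormula.MULTIPLY,
) -> list[RiskResult]:
    """One RiskResult per sample x element.

    Censored cells are substituted per ``policy`` (default zero: risk is
    not invented for non-detects) before the dose computation. The
    non-carcinogenic dose uses the scenario with its averaging time
    matched to the exposure duration; the carcinogenic dose uses the
    lifetime averaging time. Elements without a slope factor carry HQ
    only.
    """
    nc = scenario.with_at_rule(ATRule.MATCH_ED)
    life = scenario.with_at_rule(ATRule.LIFETIME)
    results: list[RiskResult] = []
    for sample in samples:
        for elem in Element:
            c = substitute_censored(sample[elem], policy)
            t = tox[elem]
            add_nc = average_daily_dose(c, nc)
            hq, hq_label = hazard_quotient(add_nc, t)
            if t.sf is None:
                results.append(
                    RiskResult(sample.sample_id, elem, add_nc, hq, hq_label)
                )
            else:
                add_car = average_daily_dose(c, life)
                cr = carcinogenic_risk(add_car, t, formula)
                results.append(
                    RiskResult(
                        sample.sample_id,
                        elem,
                        add_nc,
                        hq,
                        hq_label,
                        add_car=add_car,
                        cr=cr,
                        cr_label=classify_cr(cr),
                    )
                )
    return results
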