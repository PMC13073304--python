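"""Detection-frequency summaries and screening against regulatory standards.

Three standards ship with the package as YAML data files and can be loaded
by name: ``efsa_2020_640`` (Cd 0.1 ppm, Pb 1 ppm, As must be absent, Mn
daily-intake bound 3 mg/day), ``iram_inta_15935`` (Pb 10 ppm, As 2 ppm)
and ``nrag_1135`` (Pb 2 ppm, As 1 ppm).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import yaml

from .io_datamodel import (
    Censor,
    Element,
    LimitRule,
    RegulatoryStandard,
    SampleRecord,
)

__all__ = [
    "Rounding",
    "Verdict",
    "MnIntakeCheck",
    "available_standards",
    "load_standard",
    "detection_frequency",
    "screen_sample",
    "screen_dataset",
    "mn_intake_check",
]


class Rounding(str, enum.Enum):
    TWO_DP = "two_dp"
    INTEGER = "integer"


class Verdict(str, enum.Enum):
    PASS = "pass"
    EXCEED = "exceed"
    NOT_REGULATED = "not_regulated"


def available_standards() -> list[str]:
    root = resources.files("propolis_risk.data.standards")
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir() if p.name.endswith(".yaml"))


def load_standard(name: str) -> RegulatoryStandard:
    """Load a packaged standard by name, or a YAML file by path."""
    root = resources.files("propolis_risk.data.standards")
    res = root / f"{name}.yaml"
    if res.is_file():
        raw = yaml.safe_load(res.read_text(encoding="utf-8"))
    else:
        with open(name, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    rules: dict[Element, LimitRule] = {}
    for key, limit in (raw.get("limits") or {}).items():
        elem = Element(key)
        if isinstance(limit, str):
            if limit.lower() != "absent":
                raise ValueError(f"{raw['name']}: unknown rule {limit!r} for {elem}")
            rules[elem] = LimitRule(elem, mpl_ppm=None)
        else:
            rules[elem] = LimitRule(elem, mpl_ppm=float(limit))
    bounds = {
        Element(k): float(v) for k, v in (raw.get("daily_intake_bounds_mg") or {}).items()
    }
    return RegulatoryStandard(
        name=raw["name"],
        rules=rules,
        daily_intake_bounds_mg=bounds,
        description=raw.get("description", ""),
    )


def detection_frequency(
    samples: Sequence[SampleRecord],
    element: Element,
    rounding: Rounding = Rounding.TWO_DP,
) -> float:
    """Percentage of samples in which ``element`` is quantified."""
    if not samples:
        raise ValueError("detection_frequency requires a nonempty sample list")
    n_quant = sum(1 for s in samples if s[element].censor is Censor.QUANTIFIED)
    pct = 100.0 * n_quant / len(samples)
    if rounding is Rounding.TWO_DP:
        return round(pct, 2)
    return float(round(pct))


def screen_sample(
    sample: SampleRecord, standard: RegulatoryStandard
) -> dict[Element, Verdict]:
    """Screen one sample against a standard, element by element.

    Numeric ceilings use a strict comparator: a quantified value exceeds
    only when it is greater than the limit. Censored measurements never
    exceed a numeric limit. An absence rule is violated by any quantified
    detection. Elements without a rule are ``not_regulated``.
    """
    verdicts: dict[Element, Verdict] = {}
    for elem in Element:
        rule = standard.rules.get(elem)
        if rule is None:
            verdicts[elem] = Verdict.NOT_REGULATED
            continue
        m = sample[elem]
        if rule.is_absence_rule:
            exceed = m.censor is Censor.QUANTIFIED
        else:
            exceed = m.censor is Censor.QUANTIFIED and m.value > rule.mpl_ppm
        verdicts[elem] = Verdict.EXCEED if exceed else Verdict.PASS
    return verdicts


def screen_dataset(
    samples: Sequence[SampleRecord], standard: RegulatoryStandard
) -> dict[str, dict[Element, Verdict]]:
    return {s.sample_id: screen_sample(s, standard) for s in samples}


@dataclass(frozen=True)
class MnIntakeCheck:
    intake_mg_day: float
    bound_mg_day: float

    @property
    def exceeds(self) -> bool:
        return self.intake_mg_day > self.bound_mg_day


def mn_intake_check(c_mn: float, ingr: float, bound: float = 3.0) -> MnIntakeCheck:
    """Daily Mn intake from a concentration (ppm) and ingestion rate (kg/day).

    mg/kg x kg/day = mg/day; the bound is exceeded only by a strictly
    greater intake.
    """
    if c_mn < 0 or ingr <= 0 or bound <= 0:
        raise ValueError("mn_intake_check requires c_mn >= 0 and positive ingr/bound")
    return MnIntakeCheck(intake_mg_day=c_mn * ingr, bound_mg_day=bound)
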