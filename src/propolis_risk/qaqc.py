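"""Acceptance evaluation of method quality parameters.

A measurement method is accepted per element when its spike/CRM recovery
falls inside a tolerance band (default 80-120 %, endpoints inclusive) and
its replicate precision (RSD) does not exceed a ceiling (default 15 %).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .io_datamodel import Censor, Element, QCRecord, SampleRecord

__all__ = ["QCVerdict", "evaluate_qc", "censoring_summary"]


@dataclass(frozen=True)
class QCVerdict:
    element: Element
    recovery_ok: bool
    precision_ok: bool

    @property
    def overall_ok(self) -> bool:
        return self.recovery_ok and self.precision_ok


def evaluate_qc(
    qc: QCRecord,
    recovery_band: tuple[float, float] = (80.0, 120.0),
    rsd_max: float = 15.0,
) -> QCVerdict:
    """Accept or reject one element's quality parameters.

    Both checks are inclusive at their boundaries: recovery exactly at a
    band endpoint and RSD exactly at the ceiling both pass.
    """
    lo, hi = recovery_band
    if lo > hi:
        raise ValueError(f"recovery band inverted: {recovery_band}")
    return QCVerdict(
        element=qc.element,
        recovery_ok=lo <= qc.recovery_pct <= hi,
        precision_ok=qc.rsd_pct <= rsd_max,
    )


def censoring_summary(samples: Sequence[SampleRecord]) -> dict[Element, dict[str, int]]:
    """Per-element counts of quantified / below-LOQ / below-LOD measurements.

    The three counts always sum to the number of samples for each element.
    """
    if not samples:
        raise ValueError("censoring_summary requires a nonempty sample list")
    summary: dict[Element, dict[str, int]] = {}
    for elem in Element:
        counts = Counter(s[elem].censor for s in samples)
        summary[elem] = {
            Censor.QUANTIFIED.value: counts.get(Censor.QUANTIFIED, 0),
            Censor.BELOW_LOQ.value: counts.get(Censor.BELOW_LOQ, 0),
            Censor.BELOW_LOD.value: counts.get(Censor.BELOW_LOD, 0),
        }
    return summary
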