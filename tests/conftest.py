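from __future__ import annotations

import numpy as np
import pytest

from propolis_risk import (
    Censor,
    DEFAULT_QC,
    DETECTION_LIMITS,
    Element,
    Measurement,
    SampleRecord,
    build_paper_fixture,
)

ELEMENTS = (Element.AS, Element.CD, Element.PB, Element.MN)


def make_records(matrix, ids=None, site="testsite"):
    """SampleRecords from an (n x 4) array of quantified concentrations
    in canonical element order. Values must sit at or above each LOQ."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    ids = ids or [f"S{i + 1:02d}" for i in range(n)]
    records = []
    for sid, row in zip(ids, matrix):
        measurements = {}
        for elem, value in zip(ELEMENTS, row):
            lod, loq = DETECTION_LIMITS[elem]
            measurements[elem] = Measurement(
                elem, Censor.QUANTIFIED, lod, loq, float(value)
            )
        records.append(SampleRecord(sid, site, measurements))
    return records


@pytest.fixture
def fixture_samples():
    return build_paper_fixture(seed=1)


@pytest.fixture
def default_qc():
    return list(DEFAULT_QC)
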