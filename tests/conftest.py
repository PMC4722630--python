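import datetime as dt

import pytest

from radsize import Measurement, MeasurementFinding, packaged_kb


@pytest.fixture(scope="session")
def kb():
    """Packaged anatomy graph + specification set (read-only)."""
    return packaged_kb()


@pytest.fixture(scope="session")
def anatomy(kb):
    return kb[0]


@pytest.fixture(scope="session")
def specs(kb):
    return kb[1]


def make_finding(entity, measurements, kind="anatomical_structure", fid="f1", exam="e1", date=None):
    return MeasurementFinding(
        finding_id=fid,
        patient_id="p1",
        exam_id=exam,
        exam_date=date or dt.date(2015, 1, 15),
        entity=entity,
        entity_kind=kind,
        measurements=measurements,
    )


@pytest.fixture()
def mk():
    return make_finding


def mm(value, quality=None):
    return Measurement(value, "mm", quality)


def cm(value, quality=None):
    return Measurement(value, "cm", quality)
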