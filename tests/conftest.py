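import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from limbasym import AsymmetryRecord, ElementMeasurement, Landmark, TaxonTraitSample

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


TWO_POINT_DOC = """\
<!DOCTYPE PickedPoints>
<PickedPoints>
 <DocumentData>
  <DateTime time="12:00" date="2022-01-01"/>
  <User name="digitizer"/>
 </DocumentData>
 <point x="0" y="0" z="0" active="1" name="pelvis_L_ant"/>
 <point x="3" y="4" z="0" active="1" name="pelvis_L_post"/>
</PickedPoints>
"""


@pytest.fixture
def two_point_doc() -> str:
    """Minimal picked-points document: the left pelvis of one specimen."""
    return TWO_POINT_DOC


@pytest.fixture
def pelvis_landmarks() -> list[Landmark]:
    """Both pelvis sides: each side a 3-4-5 pair, so both lengths are 5.00 mm."""
    return [
        Landmark("pelvis_L_ant", 0.0, 0.0, 0.0),
        Landmark("pelvis_L_post", 3.0, 4.0, 0.0),
        Landmark("pelvis_R_ant", 10.0, 0.0, 0.0),
        Landmark("pelvis_R_post", 13.0, 4.0, 0.0),
    ]


def make_record(
    left: float,
    right: float,
    specimen_id: str = "s1",
    taxon: str = "t",
    element: str = "pelvis",
    **kwargs,
) -> AsymmetryRecord:
    return AsymmetryRecord.from_measurement(
        ElementMeasurement(
            taxon=taxon,
            specimen_id=specimen_id,
            element=element,
            left_length=left,
            right_length=right,
            **kwargs,
        )
    )


def make_sample(pairs, taxon="t", element="pelvis") -> TaxonTraitSample:
    records = [
        make_record(l, r, specimen_id=f"s{i}", taxon=taxon, element=element)
        for i, (l, r) in enumerate(pairs)
    ]
    return TaxonTraitSample(taxon=taxon, element=element, records=records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220714)
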