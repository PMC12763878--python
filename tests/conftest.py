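import numpy as np
import pytest

from ltfassay import quantitation as qt
from ltfassay.crosswell_response import SpecimenRecord
from ltfassay.quantitation import AnalytePanel, AnalyteSpec, Phase, Sample, WellSeries


@pytest.fixture
def small_panel():
    return AnalytePanel(
        [
            AnalyteSpec("IFNg", lloq=10.0, uloq=10000.0),
            AnalyteSpec("CXCL10", lloq=10.0, uloq=10000.0),
            AnalyteSpec("IL-1Ra", lloq=10.0, uloq=10000.0),
        ]
    )


@pytest.fixture
def wide_panel():
    return qt.default_panel()


@pytest.fixture
def sequential_schedule():
    return [Phase(0.0, 20.0, "IgG"), Phase(20.0, 48.0, "ICI")]


def make_well(
    specimen="S001",
    well="W1",
    design="sequential",
    schedule=None,
    samples=(),
):
    if schedule is None:
        schedule = [Phase(0.0, 20.0, "IgG"), Phase(20.0, 48.0, "ICI")]
    return WellSeries(
        specimen_id=specimen,
        well_id=well,
        design=design,
        schedule=schedule,
        samples=[Sample(*s) if isinstance(s, tuple) else s for s in samples],
    )


@pytest.fixture
def responder_specimen():
    return SpecimenRecord(
        "S001", "lung", "positive", n_replicates=1, design="sequential",
        truth={"responder": True, "effect_theta": 3.0,
               "responsive_analytes": ["IFNg", "CXCL10"]},
    )


@pytest.fixture
def nonresponder_specimen():
    return SpecimenRecord(
        "S002", "lung", "negative", n_replicates=1, design="sequential",
        truth={"responder": False, "effect_theta": 3.0,
               "responsive_analytes": ["IFNg", "CXCL10"]},
    )
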