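"""Shared fixtures: a default synthetic cohort, its normalized view, the
shipped summary-table transcriptions, and a small aseg.stats text."""

import pytest

from morphorep.io_tables import etiv_normalize, load_fixture_summary
from morphorep.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def cohort():
    """Default study-sized cohort (29 HC / 49 IBS), raw mm^3 volumes."""
    return generate(SimConfig(seed=11)).table


@pytest.fixture(scope="session")
def normalized(cohort):
    return etiv_normalize(cohort)


@pytest.fixture(scope="session")
def skrobisz():
    return load_fixture_summary("skrobisz")


@pytest.fixture(scope="session")
def bergen():
    return load_fixture_summary("bergen")


ASEG_TEXT = """\
# Title Segmentation Statistics
# Measure BrainSeg, BrainSegVol, Brain Segmentation Volume, 1180000.000000, mm^3
# Measure Cortex, CortexVol, Total cortical gray matter volume, 450000.500000, mm^3
# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total Intracranial Volume, 1500000.000000, mm^3
# ColHeaders Index SegId NVoxels Volume_mm3 StructName
  1   10  7500  7500.0 Left-Thalamus-Proper
  2   17  4300  4300.5 Left-Hippocampus
  3   53  4400  4400.0 Right-Hippocampus
"""


@pytest.fixture()
def aseg_text():
    return ASEG_TEXT
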