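import numpy as np
import pandas as pd
import pytest

from lc3screen.config import LarvaConfig
from lc3screen.io import ImageStack
from lc3screen.synthetic import make_larva_stack


@pytest.fixture(scope="session")
def default_stack():
    """One default-condition larva stack with its ground truth."""
    return make_larva_stack(seed=42)


@pytest.fixture(scope="session")
def clean_stack():
    """A noise-free larva stack: the exact-recovery oracle substrate."""
    return make_larva_stack(seed=7, read_noise_sd=0.0, shot_noise=False)


@pytest.fixture()
def larva_config():
    return LarvaConfig()


@pytest.fixture()
def platemap_frame():
    """A minimal valid plate map: one vehicle well, one treated well, both phases."""
    rows = []
    for phase in ("pre_nh4cl", "post_nh4cl"):
        rows.append(dict(plate="P1", well="A01", compound="DMSO", dose_um=0.0,
                         phase=phase, role="vehicle", toxic=False, notes=""))
        rows.append(dict(plate="P1", well="B01", compound="thymol", dose_um=50.0,
                         phase=phase, role="treatment", toxic=False, notes=""))
    return pd.DataFrame(rows)


def make_results_records(plate, well, phase, values, start_larva=0, excluded=None, reason=""):
    """Helper: relative_puncta_area records for one group."""
    recs = []
    for i, v in enumerate(values):
        recs.append(dict(plate=plate, well=well, larva=start_larva + i, phase=phase,
                         metric="relative_puncta_area", value=v, units="dimensionless",
                         excluded=bool(excluded[i]) if excluded else False,
                         exclusion_reason=reason if excluded and excluded[i] else ""))
    return recs


@pytest.fixture()
def tiny_well_image():
    """A 2D noise-free image with a bright elongated body for mask tests."""
    img = np.full((200, 400), 10.0)
    yy, xx = np.mgrid[0:200, 0:400]
    body = ((xx - 200) / 140.0) ** 2 + ((yy - 100) / 50.0) ** 2 <= 1.0
    img[body] += 90.0
    return img, body
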