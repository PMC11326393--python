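import numpy as np
import pytest

from nichequant.geometry import TumorMask
from nichequant.synth import NicheDisc, TissueSpec, generate_tissue


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_disc_spec(seed=0, width=4000.0, disc_center=(1500.0, 1500.0),
                   disc_radius=564.19, mhc2=36.0, tcf1cd8=20.0,
                   background=None):
    """One planted 1-mm² niche disc in a square tumor."""
    background = background or {
        "other": 100.0, "CD4+": 30.0, "CD8+": 50.0, "MHC-II+": 2.0,
        "TCF1+CD8+": 0.3,
    }
    return TissueSpec(
        width_um=width,
        height_um=width,
        tumor_mask=TumorMask.rectangle(width, width),
        background_density=background,
        niche_specs=[NicheDisc(disc_center, disc_radius, mhc2, tcf1cd8)],
        seed=seed,
    )


@pytest.fixture
def disc_spec():
    return make_disc_spec()


@pytest.fixture
def disc_tissue(disc_spec):
    cells, mask, truth = generate_tissue(disc_spec)
    return disc_spec, cells, mask, truth
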