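import numpy as np
import pandas as pd
import pytest

import renimap.synthetic as rs
from renimap.gating import load_default_tree


@pytest.fixture(scope="session")
def tree():
    return load_default_tree()


@pytest.fixture(scope="session")
def full_panel():
    """All gating-tree leaf classes that the default generator plants."""
    return list(rs.DEFAULT_CLASSES) + list(rs.EXTRA_PANEL_CLASSES)


@pytest.fixture(scope="session")
def noisy_biopsy(full_panel):
    """One default-noise biopsy on a 2 mm^2 field (1 um/px coordinates)."""
    spec = rs.default_spec(image_shape=(1400, 1400), pixel_size=1.0,
                           niche_specs=(), n_glomeruli=2, n_tubules=4)
    nuclei, tub, glom, cells, truth = rs.generate_biopsy(spec, 5)
    return spec, nuclei, tub, glom, cells, truth
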