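import numpy as np
import pytest

from ifd import synthetic_data as sd


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture()
def toy_complex():
    """Three qualifying H-bond sites, one over-distance, plus one salt
    bridge each side of its cutoff."""
    structure, manifest = sd.make_toy_complex(
        hbond_geometries=[(2.9, 10.0), (3.0, 25.0), (2.8, 5.0), (3.6, 5.0)],
        salt_bridge_distances=[3.8, 4.1],
    )
    return structure, manifest
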