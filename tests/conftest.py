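"""Shared fixtures: rendered synthetic cysts reused across test modules."""

import numpy as np
import pytest

from fusomekit import synthetic_data as sd
from fusomekit import topology as tp


@pytest.fixture(scope="session")
def canonical_renders():
    """Noise-free renders of the canonical 2-, 4-, 8-, 16-cell female cysts."""
    out = {}
    for n in (2, 4, 8, 16):
        tree = tp.canonical_max_branched(n)
        cfg = sd.RenderConfig(
            tree=tree,
            cell_volumes_um3=tuple(sd.model_cell_volumes(n)),
            seed=1,
        )
        out[n] = sd.render_cyst(cfg)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20230223)
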