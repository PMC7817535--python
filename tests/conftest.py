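import numpy as np
import pandas as pd
import pytest

import treeace as t
from treeace.pedigree import additive_matrix


@pytest.fixture(scope="session")
def small_trial():
    """4-replicate (12-block) trial with assigned families: 36x12 grid."""
    params = t.TrialDesignParams(n_replicates=4, replicate_arrangement=(2, 2))
    layout = t.generate_layout(params)
    trees = t.assign_families(layout, params, seed=11)
    return params, layout, trees


@pytest.fixture(scope="session")
def small_pedigree(small_trial):
    _, _, trees = small_trial
    groups = [trees.loc[trees["family"] == f, "tree_id"].tolist()
              for f in range(1, 97)]
    return t.simulate_pedigree(96, "half_sib", 0, offspring_ids=groups)


@pytest.fixture(scope="session")
def small_amat(small_pedigree):
    return additive_matrix(small_pedigree)


@pytest.fixture(scope="session")
def tiny_trial():
    """Six 3x3 blocks (2 reps), 21 families of which 3 controls: 54 trees."""
    params = t.TrialDesignParams(n_replicates=2, iblocks_per_replicate=3,
                                 block_rows=3, block_cols=3, n_families=21,
                                 n_controls=3, replicate_arrangement=(1, 2),
                                 buffer_width=6.4)
    layout = t.generate_layout(params)
    trees = t.assign_families(layout, params, seed=5)
    groups = [trees.loc[trees["family"] == f, "tree_id"].tolist()
              for f in range(1, 22)]
    ped = t.simulate_pedigree(21, "half_sib", 0, offspring_ids=groups)
    return params, layout, trees, ped


def cone_chm(radius=4.0, height=10.0, cell=0.25, pad=1.0):
    """Analytic cone CHM centred in the raster; apex = height at the centre."""
    half = radius + pad
    n = int(np.ceil(2 * half / cell))
    xs = (np.arange(n) + 0.5) * cell - half
    d = np.hypot(xs[None, :], xs[:, None])
    vals = np.clip(height * (1 - d / radius), 0, None)
    return t.CHMRaster(values=vals, cell_size=cell, origin=(-half, half))


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("det", derandomize=True, deadline=None)
_hyp_settings.load_profile("det")
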