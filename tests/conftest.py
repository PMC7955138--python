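import numpy as np
import pytest

import morphoquant as mq


def disc(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


@pytest.fixture(scope="session")
def small_acinus_timelapse():
    params = mq.AcinusSimParams(n_acini=8, n_frames=24, growth_rate=0.4, seed=11)
    return params, mq.generate_acinus_timelapse(params)


@pytest.fixture(scope="session")
def invasive_acinus_timelapse():
    params = mq.AcinusSimParams(
        n_acini=8, n_frames=24, growth_rate=0.4, protrusion_rate=0.6, seed=12
    )
    return params, mq.generate_acinus_timelapse(params)


@pytest.fixture(scope="session")
def mixed_cell_scene():
    params = mq.CellSceneParams(
        n_cells=24, class_proportions=(0.5, 0.25, 0.25), peripheral_enrichment=2.0, seed=7
    )
    return params, mq.generate_cell_scene(params)


@pytest.fixture(scope="session")
def half_overlap_spot_scene():
    params = mq.SpotSceneParams(true_overlap_fraction=0.5, seed=5)
    return params, mq.generate_spot_scene(params)
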