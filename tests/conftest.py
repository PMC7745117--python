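import numpy as np
import pytest

import uavpheno as u
from uavpheno.synthetic_field import draw_training_regions


@pytest.fixture(scope="session")
def small_trial():
    """A 10-genotype x 2-rep trial rendered at 2 cm GSD, fully simulated."""
    layout = u.generate_trial_layout(10, 2, seed=1, block_size=5)
    params = u.default_genetic_params(10, 2, seed=2)
    truth = u.simulate_ground_truth(layout, params)
    render = u.render_mosaic(layout, truth,
                             u.default_render_params(seed=3, gsd=0.02))
    return {"layout": layout, "params": params, "truth": truth,
            "render": render}


@pytest.fixture(scope="session")
def small_classified(small_trial):
    """Signatures, classified raster, and joined plot table for small_trial."""
    render = small_trial["render"]
    layout = small_trial["layout"]
    regions = draw_training_regions(render.latent, seed=4)
    sig = u.build_signatures(render.mosaic, regions)
    classified = u.classify_mlc(render.mosaic, sig)
    zones = u.rasterize_zones(layout.polygons(), render.mosaic.grid)
    areas = u.tabulate_area(zones, classified)
    table = u.join_attributes(areas, layout)
    return {"signatures": sig, "classified": classified, "zones": zones,
            "table": table}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
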