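import numpy as np
import pytest

import canopyphot as cp


@pytest.fixture(scope="session")
def default_field():
    """A default synthetic field: truth, layout, scene and ground-truth masks."""
    layout = cp.synth.design_layout(3, 15)
    truth = cp.synth.generate_truth(3, 15, seed=11)
    scene, veg, shadow = cp.synth.render_scene(layout, truth, seed=12)
    return {"truth": truth, "layout": layout, "scene": scene, "veg": veg, "shadow": shadow}


@pytest.fixture(scope="session")
def pipeline_result():
    """One full end-to-end run on the default 5-treatment, 3-replicate field
    (225 plants); shared across tests because it is the expensive fixture."""
    cfg = cp.pipeline.PipelineConfig(seed=1)
    return cp.pipeline.run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
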