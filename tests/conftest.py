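import numpy as np
import pytest

from mitospread import SceneSpec

# A resolvable imaging regime used by image-based fixtures: particles sparse
# and small enough that segmentation can separate every one. The measured
# control regime (1.2/μm, 4.3 μm²) is geometrically unresolvable — see the
# generator docs — so image-pipeline tests demonstrate correctness here.
DEMO_SCENE = dict(pattern="uniform", density_per_um=0.4, area_mean_um2=1.0,
                  area_sd_um2=0.2, elongation=2.0, psf_sigma_px=0.8,
                  noise_sd=60.0)

# Sparser still, for degraded-rendering (blur + 4x downsample) comparisons.
SPARSE_SCENE = {**DEMO_SCENE, "density_per_um": 0.2}


@pytest.fixture
def demo_spec():
    return SceneSpec(**DEMO_SCENE, seed=11)


@pytest.fixture
def straight_trace():
    from mitospread import AxonTrace
    return AxonTrace(np.array([[80.0, 40.0], [80.0, 1060.0]]),
                     pixel_size_um=0.2)
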