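import numpy as np
import pytest

from bacsize.reference import population_models
from bacsize.rng import substream
from bacsize.synth import SceneSpec, place_cells, render_scene, sample_population


def make_scene(
    n_cells=20,
    condition_index=3,
    image_shape_px=(800, 800),
    seed=11,
    **scene_kwargs,
):
    """Render one field of reference-model cells with ground truth."""
    model = population_models()[condition_index]
    shapes = sample_population(model, n_cells, substream(seed, "sample"))
    placed = place_cells(
        shapes, image_shape_px, scene_kwargs.get("pixel_size_um", 0.065),
        substream(seed, "place"),
    )
    spec = SceneSpec(
        cells=tuple(placed),
        image_shape_px=image_shape_px,
        rng_seed=seed,
        **scene_kwargs,
    )
    raster, truth = render_scene(spec)
    return spec, raster, truth


@pytest.fixture(scope="session")
def clean_scene():
    """20 glucose-model cells, no noise: exact count recovery territory."""
    return make_scene(n_cells=20, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_halo_scene():
    """40 glucose-model cells with default halo, blur and noise."""
    return make_scene(n_cells=40, image_shape_px=(1000, 1000), seed=23)
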