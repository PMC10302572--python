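"""Synthetic population sampling and scene rendering against analytic truth."""

import numpy as np
import pytest

from bacsize.geometry import CellShape, projected_area, spherocylinder_volume
from bacsize.reference import population_models
from bacsize.rng import substream
from bacsize.synth import (
    PopulationModel,
    SceneSpec,
    SynthError,
    generate_dataset,
    place_cells,
    render_scene,
    sample_population,
)

GLUTAMINE = PopulationModel(
    condition_name="glutamine",
    length_mean_um=2.11,
    length_sd_um=0.54,
    width_mean_um=0.55,
    width_sd_um=0.05,
)


def test_sample_means_converge_to_model_means():
    cells = sample_population(GLUTAMINE, 10000, rng_seed=0)
    L = np.array([c.length_um for c in cells])
    W = np.array([c.width_um for c in cells])
    assert L.mean() == pytest.approx(2.11, abs=0.02)
    assert W.mean() == pytest.approx(0.55, abs=0.002)
    assert np.all(L >= W)
    assert np.all(W > 0)


def test_zero_sd_gives_identical_cells():
    model = PopulationModel("fixed", 2.0, 0.0, 0.6, 0.0)
    cells = sample_population(model, 50, rng_seed=1)
    assert all(c.length_um == 2.0 and c.width_um == 0.6 for c in cells)


def test_sampling_is_deterministic_under_seed():
    a = sample_population(GLUTAMINE, 200, rng_seed=42)
    b = sample_population(GLUTAMINE, 200, rng_seed=42)
    assert [(c.length_um, c.width_um) for c in a] == [
        (c.length_um, c.width_um) for c in b
    ]


def test_misconfigured_model_rejected():
    # mean length far below mean width: almost every draw violates L >= W
    bad = PopulationModel("bad", 0.5, 0.01, 0.6, 0.01)
    with pytest.raises(SynthError):
        sample_population(bad, 100, rng_seed=0)


def test_sampled_mean_volume_matches_direct_sampling_oracle():
    cells = sample_population(GLUTAMINE, 20000, rng_seed=3)
    vols = np.array([c.volume_um3 for c in cells])
    oracle_cells = sample_population(GLUTAMINE, 20000, rng_seed=999)
    oracle = np.array(
        [spherocylinder_volume(c.length_um, c.width_um) for c in oracle_cells]
    )
    se = np.sqrt(vols.var() / len(vols) + oracle.var() / len(oracle))
    assert abs(vols.mean() - oracle.mean()) < 3 * se


def _single_cell_spec(**kwargs):
    cell = CellShape(2.73, 0.79, center_xy=(10.0, 9.0), orientation_rad=0.6)
    defaults = dict(
        cells=(cell,),
        image_shape_px=(300, 300),
        blur_sigma_px=0.0,
        noise_sd=0.0,
        halo_amplitude=0.0,
    )
    defaults.update(kwargs)
    return SceneSpec(**defaults)


def test_rendered_footprint_area_matches_stadium_formula():
    spec = _single_cell_spec()
    raster, truth = render_scene(spec)
    mid = 0.5 * (spec.background_level + spec.cell_level)
    px_area = spec.pixel_size_um**2
    measured = (raster < mid).sum() * px_area
    perimeter = 2 * (2.73 - 0.79) + np.pi * 0.79
    assert abs(measured - projected_area(2.73, 0.79)) < perimeter * spec.pixel_size_um
    assert truth.loc[0, "area_um2"] == pytest.approx(projected_area(2.73, 0.79))


def test_empty_scene_is_uniform_background():
    spec = SceneSpec(cells=(), image_shape_px=(50, 50), noise_sd=0.0, blur_sigma_px=0.0)
    raster, truth = render_scene(spec)
    assert truth.empty
    assert np.all(raster == int(spec.background_level))


def test_rendering_is_bit_deterministic():
    spec = _single_cell_spec(noise_sd=120.0, blur_sigma_px=1.0, halo_amplitude=1500.0)
    r1, _ = render_scene(spec)
    r2, _ = render_scene(spec)
    assert np.array_equal(r1, r2)


def test_rendering_is_translation_equivariant():
    """Shifting a cell by whole pixels shifts its footprint identically."""
    px = 0.065
    shift_px = 7
    a = _single_cell_spec()
    cell = a.cells[0]
    from dataclasses import replace

    moved = CellShape(
        cell.length_um,
        cell.width_um,
        center_xy=(cell.center_xy[0] + shift_px * px, cell.center_xy[1]),
        orientation_rad=cell.orientation_rad,
    )
    b = _single_cell_spec(cells=(moved,))
    ra, _ = render_scene(a)
    rb, _ = render_scene(b)
    assert np.array_equal(ra[:, : ra.shape[1] - shift_px], rb[:, shift_px:])


def test_cells_darker_than_background_enforced():
    with pytest.raises(ValueError):
        SceneSpec(cells=(), background_level=1000.0, cell_level=2000.0)


def test_generate_dataset_counts_and_determinism(tmp_path):
    models = population_models()[:2]
    m1 = generate_dataset(models, 30, tmp_path / "a", rng_seed=5, cells_per_image=15,
                          image_shape_px=(700, 700))
    m2 = generate_dataset(models, 30, tmp_path / "b", rng_seed=5, cells_per_image=15,
                          image_shape_px=(700, 700))
    assert m1.drop(columns=[]).equals(m2)
    for model in models:
        truth = (tmp_path / "a" / f"{model.condition_name}_truth.csv").read_text()
        truth_b = (tmp_path / "b" / f"{model.condition_name}_truth.csv").read_text()
        assert truth == truth_b
        assert truth.count("\n") == 31  # header + 30 cells
    assert (tmp_path / "a" / "glutamine_000.tif").exists()


def test_generate_dataset_requires_models(tmp_path):
    with pytest.raises(ValueError):
        generate_dataset([], 10, tmp_path)


def test_placement_fails_when_cell_cannot_fit():
    big = [CellShape(30.0, 1.0)]
    with pytest.raises(SynthError):
        place_cells(big, (100, 100), 0.065, substream(0, "p"))
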