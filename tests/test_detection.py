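"""Pixel classification, component extraction and field densitometry."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree
from shapely.geometry import box

from immunocontext.detection import (FieldSpec, PixelClassParams,
                                     classify_pixels, detect_cells,
                                     field_density)
from immunocontext.errors import ConfigError, GeometryError
from immunocontext.cells import make_cell_table, empty_cell_table
from immunocontext.synthetic import (LABEL_BACKGROUND, LABEL_NUCLEUS,
                                     LABEL_RED, SceneConfig,
                                     generate_tissue_scene, render_ihc_image)


def test_pure_white_is_background():
    img = np.full((50, 50, 3), 255, dtype=np.uint8)
    mask = classify_pixels(img, 0.5)
    assert (mask == LABEL_BACKGROUND).all()


def test_non_rgb_rejected():
    with pytest.raises(ConfigError):
        classify_pixels(np.zeros((10, 10), dtype=np.uint8), 0.5)


def test_noise_free_classification_matches_truth(sparse_scene):
    render = render_ihc_image(sparse_scene, 0.5, noise_sd=0.0)
    mask = classify_pixels(render.image, 0.5)
    red, truth_red = mask == LABEL_RED, render.truth_mask == LABEL_RED
    iou = (red & truth_red).sum() / (red | truth_red).sum()
    assert iou == 1.0
    assert (mask == render.truth_mask).all()


def test_noisy_classification_accuracy(sparse_scene):
    render = render_ihc_image(sparse_scene, 0.5, noise_sd=10.0, seed=1)
    mask = classify_pixels(render.image, 0.5)
    assert (mask == render.truth_mask).mean() >= 0.98


def test_blank_mask_yields_no_cells():
    cells = detect_cells(np.zeros((100, 100), dtype=np.uint8), 0.5)
    assert len(cells) == 0


def test_detected_centroids_match_ground_truth(sparse_scene):
    render = render_ihc_image(sparse_scene, 0.5, noise_sd=0.0)
    mask = classify_pixels(render.image, 0.5)
    cells = detect_cells(mask, 0.5, marker="CD8")
    truth = sparse_scene.cells
    for marker in ("CD8", "NEG"):
        det = cells[cells["marker"] == marker][["x_um", "y_um"]].to_numpy()
        ref = truth[truth["marker"] == ("CD8" if marker == "CD8" else "NEG")]
        ref = ref[["x_um", "y_um"]].to_numpy()
        assert len(det) == len(ref)
        d, _ = cKDTree(ref).query(det)
        assert d.max() < 2.0


def test_small_component_filtered():
    mask = np.zeros((100, 100), dtype=np.uint8)
    mask[50, 50] = LABEL_RED  # a single pixel: 0.25 um^2 at 0.5 um/px
    assert len(detect_cells(mask, 0.5)) == 0
    # a large background smear is filtered by the max-area bound
    mask2 = np.zeros((100, 100), dtype=np.uint8)
    mask2[10:90, 10:90] = LABEL_RED  # 1600 um^2 > 400
    assert len(detect_cells(mask2, 0.5)) == 0


def test_scale_equivariance(sparse_scene):
    a = detect_cells(classify_pixels(
        render_ihc_image(sparse_scene, 0.5).image, 0.5), 0.5, marker="CD8")
    b = detect_cells(classify_pixels(
        render_ihc_image(sparse_scene, 0.25).image, 0.25), 0.25, marker="CD8")
    a_pos = a[a["marker"] == "CD8"][["x_um", "y_um"]].to_numpy()
    b_pos = b[b["marker"] == "CD8"][["x_um", "y_um"]].to_numpy()
    assert len(a_pos) == len(b_pos)
    d, _ = cKDTree(b_pos).query(a_pos)
    assert d.max() < 1.0


# -- field densitometry ----------------------------------------------------

def test_five_fields_of_ten_cells_give_10000_per_mm2():
    # five tight clusters of 10 positives, far apart: hotspot fields catch
    # one cluster each -> mean count 10 / 1e-3 mm^2 = 10,000 cells/mm^2
    rng = np.random.default_rng(0)
    centers = [(100, 100), (300, 100), (500, 100), (100, 300), (300, 300)]
    xs, ys = [], []
    for cx, cy in centers:
        xs.extend(cx + rng.uniform(-5, 5, 10))
        ys.extend(cy + rng.uniform(-5, 5, 10))
    cells = make_cell_table(xs, ys, ["CD8"] * 50)
    region = box(0, 0, 600, 400)
    res = field_density(cells, region, FieldSpec(placement="hotspot"))
    assert sorted(res.counts.tolist()) == [10] * 5
    assert res.density_per_mm2 == pytest.approx(10_000.0)


def test_zero_positive_cells_density_zero():
    res = field_density(empty_cell_table(), box(0, 0, 500, 500), FieldSpec())
    assert res.density_per_mm2 == 0.0
    assert len(res.counts) == 5


def test_region_too_small_raises():
    with pytest.raises(GeometryError):
        field_density(empty_cell_table(), box(0, 0, 20, 20), FieldSpec())


def test_hotspot_density_at_least_random():
    cfg = SceneConfig(field_width_um=400, field_height_um=400,
                      margin_radius_um=150, lambda_in={"CD8": 1000.0},
                      lambda_out={"CD8": 1000.0}, seed=9)
    cells = generate_tissue_scene(cfg).cells
    region = box(0, 0, 400, 400)
    hot = field_density(cells, region, FieldSpec(placement="hotspot"))
    rnd = field_density(cells, region, FieldSpec(placement="random", seed=3))
    assert hot.density_per_mm2 >= rnd.density_per_mm2


def test_random_placement_density_unbiased():
    # uniform 2000 cells/mm^2: mean density over 200 seeded scenes must sit
    # within 4 SD of the Poisson expectation for the pooled field counts
    total, n_fields = 0, 0
    for seed in range(200):
        cfg = SceneConfig(field_width_um=300, field_height_um=300,
                          margin_radius_um=100, lambda_in={"CD8": 2000.0},
                          lambda_out={"CD8": 2000.0}, seed=seed)
        cells = generate_tissue_scene(cfg).cells
        res = field_density(cells, box(0, 0, 300, 300),
                            FieldSpec(placement="random", seed=seed))
        total += res.counts.sum()
        n_fields += len(res.counts)
    expected = 2000.0 * 1e-3 * n_fields
    assert abs(total - expected) < 4 * math.sqrt(expected)


def test_field_spec_validation():
    with pytest.raises(ConfigError):
        FieldSpec(n_fields=0)
    with pytest.raises(ConfigError):
        FieldSpec(placement="spiral")
    with pytest.raises(ConfigError):
        PixelClassParams(min_cell_area_um2=500, max_cell_area_um2=400)
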