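"""Scene generator: Poisson statistics, determinism, rendering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from immunocontext.errors import ConfigError, RenderError
from immunocontext.synthetic import (BACKGROUND_RGB, LABEL_RED, Scene,
                                     SceneConfig, generate_tissue_scene,
                                     render_ihc_image, thin_min_spacing)


def test_all_zero_intensities_give_empty_scene():
    cfg = SceneConfig(lambda_in=0.0, lambda_out=0.0, seed=1)
    scene = generate_tissue_scene(cfg)
    assert len(scene.cells) == 0


def test_negative_intensity_rejected():
    with pytest.raises(ConfigError):
        SceneConfig(lambda_in={"CD8": -5.0})
    with pytest.raises(ConfigError):
        SceneConfig(lambda_out={"CD8": math.nan})


def test_determinism_same_seed():
    cfg = SceneConfig(seed=7)
    a = generate_tissue_scene(cfg)
    b = generate_tissue_scene(cfg)
    pd.testing.assert_frame_equal(a.cells, b.cells)


def test_intratumoral_count_matches_poisson_mean():
    # circle radius 1000 um, lambda_in(CD8) = 500 /mm^2, slope 0:
    # expected count = 500 * pi * 1 mm^2 ~ 1571, SD ~ 40
    cfg = SceneConfig(field_width_um=2500, field_height_um=2500,
                      margin_radius_um=1000,
                      lambda_in={"CD8": 500.0},
                      lambda_out={"CD8": 0.0}, seed=123)
    expected = 500.0 * math.pi * 1.0
    scene = generate_tissue_scene(cfg)
    n = (scene.cells["marker"] == "CD8").sum()
    assert abs(n - expected) < 4 * math.sqrt(expected)
    # Monte-Carlo over 200 seeds: the mean must be much tighter
    counts = []
    for seed in range(200):
        s = generate_tissue_scene(
            SceneConfig(field_width_um=800, field_height_um=800,
                        margin_radius_um=300, lambda_in={"CD8": 500.0},
                        lambda_out={"CD8": 0.0}, seed=seed))
        counts.append(len(s.cells))
    mu = 500.0 * math.pi * 0.3**2
    se = math.sqrt(mu / 200)
    assert abs(np.mean(counts) - mu) < 4 * se


def test_gradient_shifts_cells_toward_margin():
    # positive slope raises intensity with distance outside the margin
    cfg = SceneConfig(field_width_um=1200, field_height_um=1200,
                      margin_radius_um=300,
                      lambda_in={"CD8": 0.0}, lambda_out={"CD8": 200.0},
                      gradient_slope={"CD8": 2.0}, seed=5)
    scene = generate_tissue_scene(cfg)
    d = scene.geometry.signed_distance(scene.cells["x_um"].to_numpy(),
                                       scene.cells["y_um"].to_numpy())
    assert (d > 0).all()
    # clamping: with a steep negative slope no cell survives far outside
    cfg2 = SceneConfig(field_width_um=1200, field_height_um=1200,
                       margin_radius_um=300,
                       lambda_in={"CD8": 0.0}, lambda_out={"CD8": 200.0},
                       gradient_slope={"CD8": -2.0}, seed=5)
    d2 = generate_tissue_scene(cfg2)
    dd = d2.geometry.signed_distance(d2.cells["x_um"].to_numpy(),
                                     d2.cells["y_um"].to_numpy())
    assert (dd <= 100.0 + 1e-9).all()  # intensity hits 0 at d = 100


def test_min_spacing_thinning_enforced():
    cfg = SceneConfig(field_width_um=500, field_height_um=500,
                      lambda_in=800.0, lambda_out=800.0,
                      min_spacing_um=10.0, seed=2)
    scene = generate_tissue_scene(cfg)
    xy = scene.cells[["x_um", "y_um"]].to_numpy()
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=2)
    assert d[:, 1].min() >= 10.0


def _flood_fill_components(binary):
    """Oracle: count 8-connected components by BFS flood fill."""
    visited = np.zeros_like(binary, dtype=bool)
    h, w = binary.shape
    n = 0
    for i in range(h):
        for j in range(w):
            if binary[i, j] and not visited[i, j]:
                n += 1
                stack = [(i, j)]
                visited[i, j] = True
                while stack:
                    a, b = stack.pop()
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            p, q = a + da, b + db
                            if (0 <= p < h and 0 <= q < w and binary[p, q]
                                    and not visited[p, q]):
                                visited[p, q] = True
                                stack.append((p, q))
    return n


def test_render_positive_components_match_flood_fill(sparse_scene):
    render = render_ihc_image(sparse_scene, um_per_pixel=1.0, noise_sd=0.0)
    n_pos = (sparse_scene.cells["marker"] != "NEG").sum()
    assert _flood_fill_components(render.truth_mask == LABEL_RED) == n_pos


def test_render_dimensions_and_empty_scene():
    cfg = SceneConfig(field_width_um=1000, field_height_um=1000,
                      lambda_in=0.0, lambda_out=0.0, seed=0)
    scene = generate_tissue_scene(cfg)
    render = render_ihc_image(scene, um_per_pixel=0.5, noise_sd=0.0)
    assert render.image.shape == (2000, 2000, 3)
    assert (render.image == np.array(BACKGROUND_RGB, dtype=np.uint8)).all()


def test_render_rejects_subpixel_nuclei(sparse_scene):
    with pytest.raises(RenderError):
        render_ihc_image(sparse_scene, um_per_pixel=5.0, nucleus_radius_um=3.0)


def test_render_noise_deterministic(sparse_scene):
    a = render_ihc_image(sparse_scene, 1.0, noise_sd=10, seed=4)
    b = render_ihc_image(sparse_scene, 1.0, noise_sd=10, seed=4)
    assert (a.image == b.image).all()
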