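import numpy as np
import pytest

from immunocontext.geometry import circle_margin
from immunocontext.synthetic import SceneConfig, generate_tissue_scene


@pytest.fixture(scope="session")
def circle_geom():
    """Circle of radius 400 um centered in a 1 mm^2 field."""
    return circle_margin((500.0, 500.0), 400.0, (0, 0, 1000, 1000))


@pytest.fixture(scope="session")
def flat_scene():
    """Uniform-intensity scene: lambda_in = lambda_out, zero gradient."""
    cfg = SceneConfig(
        field_width_um=1000, field_height_um=1000, margin_radius_um=400,
        lambda_in={"CD8": 500, "CD163": 500, "NEG": 800},
        lambda_out={"CD8": 500, "CD163": 500, "NEG": 800},
        seed=42)
    return generate_tissue_scene(cfg)


@pytest.fixture(scope="session")
def sparse_scene():
    """Small scene with hard-core spacing, usable for overlap-free renders."""
    cfg = SceneConfig(
        field_width_um=400, field_height_um=400, margin_radius_um=150,
        lambda_in={"CD8": 300, "CD163": 0, "NEG": 400},
        lambda_out={"CD8": 500, "CD163": 0, "NEG": 400},
        min_spacing_um=9.0, seed=11)
    return generate_tissue_scene(cfg)
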