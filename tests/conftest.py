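import numpy as np
import pytest

from ringsift.config import PipelineConfig
from ringsift.pipeline import detect_and_describe
from ringsift.synthetic import make_texture, make_two_plane_scene, make_warp_pair


@pytest.fixture(scope="session")
def texture256():
    return make_texture(256, 256, seed=1)


@pytest.fixture(scope="session")
def texture_features(texture256):
    """Detected + described features of the reference texture (expensive)."""
    return detect_and_describe(texture256, PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def warp_fixture(texture256):
    """A representative warp pair: 20-degree rotation, scale 1.1, mild blur."""
    return make_warp_pair(texture256, rotation_deg=20.0, scale=1.1, blur_sigma=1.0)


@pytest.fixture(scope="session")
def matched_pair(warp_fixture):
    """Full pipeline result on the warp fixture."""
    from ringsift.pipeline import match_images

    cfg = PipelineConfig(seed=1)
    feat_a, feat_b, res = match_images(warp_fixture.image_a, warp_fixture.image_b, cfg)
    return feat_a, feat_b, res


@pytest.fixture(scope="session")
def plane_scene():
    return make_two_plane_scene(seed=0, n_cameras=3)


@pytest.fixture(scope="session")
def scene_pngs(plane_scene, tmp_path_factory):
    """The two-plane scene rendered to PNG files plus a K file."""
    import json

    from PIL import Image

    d = tmp_path_factory.mktemp("scene")
    paths = []
    for i, im in enumerate(plane_scene.images):
        p = d / f"view{i}.png"
        Image.fromarray(np.round(im.pixels).astype(np.uint8)).save(p)
        paths.append(p)
    kfile = d / "K.json"
    kfile.write_text(json.dumps({"K": plane_scene.K.K.tolist()}))
    return paths, kfile
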