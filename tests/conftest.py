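import numpy as np
import pytest

import jawcyst as jc


@pytest.fixture(scope="session")
def small_scene_config():
    """Quarter-size scene: same topology, much faster to rasterize."""
    return jc.SceneConfig(width=256, height=128, lesion_size_range=(16, 30))


@pytest.fixture(scope="session")
def small_scene(small_scene_config):
    return jc.generate_scene(small_scene_config, seed=11)


@pytest.fixture(scope="session")
def planted_dataset(small_scene_config):
    """Noise-free feature matrix with the planted class rule
    (odontogenic iff any tooth-overlap feature > 0), n=200."""
    cfg = jc.ExperimentConfig(
        n_scenes=200,
        positive_fraction=1.0,
        scene=small_scene_config,
        noise=jc.NoiseConfig.noise_free(),
        seed=101,
    )
    _, samples = jc.build_dataset(cfg)
    X = np.array([s.features_annotated.values for s in samples])
    y = np.array([s.label for s in samples], dtype=object)
    return X, y


def rule_classifier(X: np.ndarray) -> np.ndarray:
    """The generator's planted rule, applied directly to feature rows."""
    tooth_block = X[:, len(jc.REGION_KEYS):]
    return np.where(
        tooth_block.max(axis=1) > 0, jc.ODONTOGENIC, jc.NON_ODONTOGENIC
    ).astype(object)


def pixel_iou(a: jc.BoundingBox, b: jc.BoundingBox, width: int, height: int) -> float:
    """Brute-force IoU by rasterizing both boxes on a pixel grid."""
    ga = np.zeros((height, width), dtype=bool)
    gb = np.zeros((height, width), dtype=bool)
    ga[a.y:a.y2, a.x:a.x2] = True
    gb[b.y:b.y2, b.x:b.x2] = True
    return (ga & gb).sum() / (ga | gb).sum()
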