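import numpy as np
import pytest

from stomaseg.synth import SceneSpec, generate_scene, scene_batch


@pytest.fixture(scope="session")
def small_scene():
    """One default synthetic scene used across modules."""
    return generate_scene(SceneSpec(seed=5))


@pytest.fixture(scope="session")
def cluster_scenes():
    """Scenes with a 50/50 mix of single and clustered stomata."""
    spec = SceneSpec(height=384, width=384, n_stomata=6, cluster_fraction=0.5)
    return scene_batch(spec, 10, seed=77)


@pytest.fixture(scope="session")
def trained_segmenter():
    """A small segmenter trained briefly on a handful of scenes.

    Good enough for contrast/serialization properties; the full
    benchmark lives in the acceptance tests.
    """
    from stomaseg.segmenter import StomaSegmenter

    spec = SceneSpec(height=224, width=224, n_stomata=3)
    scenes = scene_batch(spec, 6, seed=42)
    seg = StomaSegmenter(epochs=6, random_state=13)
    seg.fit(
        [s.image for s in scenes[:4]],
        [s.truth_mask for s in scenes[:4]],
        [s.image for s in scenes[4:]],
        [s.truth_mask for s in scenes[4:]],
    )
    return seg, scenes


def random_mask(seed: int, shape=(64, 64), p=0.3) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.random(shape) < p
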