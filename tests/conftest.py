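import numpy as np
import pytest
from hypothesis import settings

from gauzeloss import experiments, regression as reg, synthetic as syn

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def trained_detector():
    """A modest tile classifier shared across detection/regression tests."""
    clf, hist, images, labels = experiments.train_detector(
        seed=0, n_scenes=15, epochs=6)
    return clf, hist, images, labels


@pytest.fixture(scope="session")
def scene():
    return syn.generate_scene(syn.SceneParams(seed=3))


@pytest.fixture(scope="session")
def small_training(trained_detector):
    """Features for 80 scenes plus a trained P-W CS model and test split."""
    clf = trained_detector[0]
    params = syn.sample_scene_params(80, seed=11)
    scenes = [syn.generate_scene(p, gauze_id=f"g{i:04d}")
              for i, p in enumerate(params)]
    feats = reg.extract_features(scenes, clf)
    split = syn.assign_splits(feats.y, (3, 1, 1), seed=11)
    tr, va, te = (feats.subset(np.flatnonzero(split == s))
                  for s in ("train", "val", "test"))
    cfg = reg.RegressionConfig(variant="pwcs", epochs=20, seed=11)
    model, history = reg.train_regressor(reg.build_model(cfg), tr, va)
    return {"model": model, "history": history, "train": tr, "val": va,
            "test": te, "config": cfg}
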