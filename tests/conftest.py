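import numpy as np
import pytest

from fixmap import AOISchema, ArrayFrames, FixationRecord
from fixmap.fewshot import FewShotReconstructionClassifier, LabeledPool, TrainConfig


@pytest.fixture
def schema():
    return AOISchema(("A", "B", "C"), "BG")


@pytest.fixture
def gray_frames():
    """Three 40×60 frames of distinct constant gray levels."""
    return ArrayFrames([np.full((40, 60, 3), g, dtype=np.uint8) for g in (50, 128, 200)])


def fix(i=0, x=0.5, y=0.5, frame=0, ts=None, dur=300.0, phase=None):
    return FixationRecord(fixation_id=i, start_ts=float(i if ts is None else ts),
                          duration_ms=dur, norm_x=x, norm_y=y,
                          frame_index=frame, phase=phase)


@pytest.fixture
def fix_factory():
    return fix


def tiny_classifier(schema, seed=0, **overrides):
    """A small, fast classifier configuration shared across tests."""
    defaults = dict(patch_size=16, channels=(8, 16), strides=(2, 2),
                    epochs=2, shots=2, queries=2, seed=seed)
    defaults.update(overrides)
    return FewShotReconstructionClassifier(schema, TrainConfig(**defaults))


@pytest.fixture
def color_pool(schema):
    """Solid-color 16×16 patches, 4 per class: a trivially separable pool."""
    rng = np.random.default_rng(7)
    colors = {"A": (220, 40, 40), "B": (40, 220, 40), "C": (40, 40, 220)}
    pool = LabeledPool(schema)
    for name, c in colors.items():
        for _ in range(4):
            patch = np.clip(rng.normal(c, 6, size=(16, 16, 3)), 0, 255).astype(np.uint8)
            pool.add(name, patch)
    pool.mark_fitted()
    return pool
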