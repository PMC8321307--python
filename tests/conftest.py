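import math

import numpy as np
import pytest

from fallwatch.classifier import train_posture_model
from fallwatch.descriptor import feature_vector
from fallwatch.synthetic import posture_dataset


def random_blob(rng: np.random.Generator, shape=(64, 64), n_parts=3) -> np.ndarray:
    """Random union of filled ellipses: a generic non-convex test silhouette."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    cx0, cy0 = rng.uniform(0.3 * w, 0.7 * w), rng.uniform(0.3 * h, 0.7 * h)
    for _ in range(rng.integers(1, n_parts + 1)):
        cx = np.clip(cx0 + rng.uniform(-0.15 * w, 0.15 * w), 2, w - 3)
        cy = np.clip(cy0 + rng.uniform(-0.15 * h, 0.15 * h), 2, h - 3)
        rx = rng.uniform(2, 0.2 * w)
        ry = rng.uniform(2, 0.2 * h)
        phi = rng.uniform(0, math.pi)
        xr = (xx - cx) * math.cos(phi) + (yy - cy) * math.sin(phi)
        yr = -(xx - cx) * math.sin(phi) + (yy - cy) * math.cos(phi)
        mask |= (xr / rx) ** 2 + (yr / ry) ** 2 <= 1.0
    if not mask.any():
        mask[h // 2, w // 2] = True
    # Keep the blob off the frame border so reference points stay exterior.
    mask[0, :] = mask[-1, :] = False
    mask[:, 0] = mask[:, -1] = False
    if not mask.any():
        mask[h // 2, w // 2] = True
    return mask


@pytest.fixture(scope="session")
def posture_model():
    """Small posture SVM shared by pipeline-level tests (150 samples/class)."""
    masks, labels = posture_dataset(150, seed=11)
    X = np.stack([feature_vector(m) for m in masks])
    return train_posture_model(X, labels)
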