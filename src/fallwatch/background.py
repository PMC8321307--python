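"""Reference-frame background model and subtraction.

The person extractor needs an image of the empty scene (the "reference
frame") both to find moving foreground and to test candidate shadow pixels
against.  We model the background as the per-pixel, per-channel median of the
first ``n_train`` frames together with a per-pixel color tolerance derived
from the training spread, and mark a pixel as foreground when its Euclidean
RGB distance to the reference exceeds that tolerance.  By default the model
is trained on the first 50 frames of a sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BackgroundModel", "build_background_model", "subtract_background"]

DEFAULT_N_TRAIN = 50
#: Tolerance floor in 8-bit gray levels; absorbs sensor noise and JPEG ripple.
DEFAULT_TOLERANCE_FLOOR = 10.0
#: Multiplier on the per-pixel training standard deviation.
SPREAD_FACTOR = 4.0


@dataclass
class BackgroundModel:
    reference_image: np.ndarray  # (H, W, 3) uint8, the modeled empty scene
    per_pixel_tolerance: np.ndarray  # (H, W) float, RGB distance threshold
    n_train: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.reference_image.shape[:2]


def build_background_model(
    frames,
    n_train: int = DEFAULT_N_TRAIN,
    tolerance_floor: float = DEFAULT_TOLERANCE_FLOOR,
) -> BackgroundModel:
    """Fit the median-reference background model on the first ``n_train`` frames.

    Parameters
    ----------
    frames
        Ordered sequence of (H, W, 3) uint8 RGB frames with uniform shape.
    n_train
        Number of leading frames used for training (>= 1).
    tolerance_floor
        Minimum per-pixel tolerance in gray levels; the fitted tolerance is
        ``tolerance_floor + SPREAD_FACTOR * std`` where ``std`` is the largest
        per-channel standard deviation observed at that pixel.
    """
    frames = list(frames)
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    if len(frames) < n_train:
        raise ValueError(
            f"insufficient training frames: got {len(frames)}, need {n_train}"
        )
    shape = frames[0].shape
    for i, f in enumerate(frames[:n_train]):
        if f.shape != shape:
            raise ValueError(f"dimension mismatch at frame {i}: {f.shape} != {shape}")
    stack = np.stack([np.asarray(f, dtype=np.float64) for f in frames[:n_train]])
    reference = np.median(stack, axis=0)
    spread = stack.std(axis=0).max(axis=-1)  # worst channel per pixel
    tolerance = tolerance_floor + SPREAD_FACTOR * spread
    return BackgroundModel(
        reference_image=np.clip(np.rint(reference), 0, 255).astype(np.uint8),
        per_pixel_tolerance=tolerance,
        n_train=n_train,
    )


def subtract_background(model: BackgroundModel, frame: np.ndarray) -> np.ndarray:
    """Raw foreground mask: True where the frame departs from the reference.

    A pixel is foreground iff the Euclidean distance between its RGB color
    and the reference color exceeds the per-pixel tolerance.
    """
    frame = np.asarray(frame)
    if frame.shape != model.reference_image.shape:
        raise ValueError(
            f"dimension mismatch: frame {frame.shape} vs model "
            f"{model.reference_image.shape}"
        )
    diff = frame.astype(np.float64) - model.reference_image.astype(np.float64)
    dist = np.sqrt((diff * diff).sum(axis=-1))
    return dist > model.per_pixel_tolerance
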