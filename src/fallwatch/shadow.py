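"""Shadow detection: chromaticity pixel test plus blob-level gradient refinement.

Cast shadows darken the background without changing its chromaticity, while a
real object replaces it.  Detection therefore runs in two stages:

1. *Pixel test* (HSV): a pixel is a shadow candidate when the current/
   reference ratio of the normalized value channel lies in ``[alpha, beta]``
   and the hue and saturation stay within ``tau_h`` / ``tau_s`` of the
   reference.  Hue is treated circularly with period 256.
2. *Blob refinement* (gradient-direction correlation): candidates are grouped
   into 8-connected blobs; within a blob, pixels with a significant Sobel
   gradient in both frames vote on whether the two gradient directions agree
   (angle difference below ``tau_a``).  A blob whose agreeing fraction ``C_B``
   reaches ``tau_c`` is confirmed shadow — the background texture shows
   through — otherwise it is handed back to the foreground.  Blobs with no
   textured pixel at all are kept as shadow: the chromaticity test already
   flagged them and there is no gradient evidence to overturn it.

HSV frames are float arrays with H in [0, 256) (circular), S in [0, 255] and
V either raw [0, 255] or, after :func:`normalize_value_channel`, in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

__all__ = [
    "ShadowParams",
    "rgb_to_hsv",
    "normalize_value_channel",
    "detect_shadow_pixels",
    "refine_shadow_blobs",
    "remove_shadows",
]

#: 3x3 structuring element: 8-connectivity for all blob labeling.
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ShadowParams:
    """Thresholds of the two-stage shadow test (defaults are the tuned values)."""

    alpha: float = 0.21  # lower bound on the V ratio: darker than this is object
    beta: float = 0.99  # upper bound on the V ratio: must actually darken
    tau_h: float = 93.0  # max circular hue difference (8-bit hue scale)
    tau_s: float = 76.0  # max saturation difference (8-bit scale)
    tau_m: float = 6.0  # min Sobel magnitude (8-bit V scale) to count as textured
    tau_a: float = pi / 10  # max gradient-direction difference for agreement (rad)
    tau_c: float = 0.2  # min agreeing fraction C_B for a blob to stay shadow

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < self.beta < 1):
            raise ValueError("require 0 <= alpha < beta < 1")
        if not (0 <= self.tau_c <= 1):
            raise ValueError("tau_c must lie in [0, 1]")
        if not (0 <= self.tau_a <= pi):
            raise ValueError("tau_a must lie in [0, pi]")


def rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) uint8 RGB image to float HSV on 8-bit-like scales.

    Hue is scaled to [0, 256) so that circular differences have period 256;
    saturation and value to [0, 255].
    """
    hsv = rgb2hsv(np.asarray(rgb, dtype=np.uint8))
    out = np.empty_like(hsv)
    out[..., 0] = hsv[..., 0] * 256.0
    out[..., 1] = hsv[..., 1] * 255.0
    out[..., 2] = hsv[..., 2] * 255.0
    return out


def normalize_value_channel(hsv: np.ndarray) -> np.ndarray:
    """Min–max rescale the V channel to [0, 1]; H and S pass through.

    Stretching V improves the contrast between shadow and non-shadow regions
    before the ratio test.  A constant V channel maps to all zeros (declared
    degenerate rule).
    """
    out = np.array(hsv, dtype=np.float64, copy=True)
    v = out[..., 2]
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        out[..., 2] = 0.0
    else:
        out[..., 2] = (v - vmin) / (vmax - vmin)
    return out


def circular_hue_difference(h1: np.ndarray, h2: np.ndarray, period: float = 256.0) -> np.ndarray:
    d = np.abs(np.asarray(h1, dtype=np.float64) - np.asarray(h2, dtype=np.float64))
    return np.minimum(d, period - d)


def detect_shadow_pixels(
    frame_hsv: np.ndarray, reference_hsv: np.ndarray, params: ShadowParams | None = None
) -> np.ndarray:
    """Stage-1 chromaticity test; returns a boolean candidate-shadow mask.

    Both inputs must be HSV with the V channel already normalized.  Pixels
    where the reference V is zero cannot form a ratio and are never shadow.
    """
    params = params or ShadowParams()
    F, R = np.asarray(frame_hsv), np.asarray(reference_hsv)
    if F.shape != R.shape:
        raise ValueError(f"dimension mismatch: {F.shape} vs {R.shape}")
    rv = R[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rv > 0, F[..., 2] / np.where(rv > 0, rv, 1.0), np.nan)
    ratio_ok = (ratio >= params.alpha) & (ratio <= params.beta)
    sat_ok = np.abs(F[..., 1] - R[..., 1]) <= params.tau_s
    hue_ok = circular_hue_difference(F[..., 0], R[..., 0]) <= params.tau_h
    return ratio_ok & sat_ok & hue_ok & (rv > 0)


def _sobel_gradients(v_channel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3x3 Sobel gradients of a [0,1] value channel, on the 0–255 scale."""
    v = np.asarray(v_channel, dtype=np.float64) * 255.0
    gx = ndimage.sobel(v, axis=1, mode="nearest")
    gy = ndimage.sobel(v, axis=0, mode="nearest")
    return gx, gy


def refine_shadow_blobs(
    candidates: np.ndarray,
    frame_hsv: np.ndarray,
    reference_hsv: np.ndarray,
    params: ShadowParams | None = None,
) -> np.ndarray:
    """Stage-2 gradient refinement; returns the confirmed-shadow mask.

    For each 8-connected candidate blob, pixels whose Sobel magnitude reaches
    ``tau_m`` in *both* frames compare gradient directions via the normalized
    dot product; the blob survives as shadow iff the fraction of agreeing
    pixels ``C_B`` is at least ``tau_c`` (or the blob is entirely
    textureless).  The output is always a subset of ``candidates``.
    """
    params = params or ShadowParams()
    candidates = np.asarray(candidates, dtype=bool)
    if not (candidates.shape == frame_hsv.shape[:2] == reference_hsv.shape[:2]):
        raise ValueError("dimension mismatch between candidates and frames")
    labels, n_blobs = ndimage.label(candidates, structure=EIGHT_CONNECTED)
    if n_blobs == 0:
        return np.zeros_like(candidates)

    gxF, gyF = _sobel_gradients(frame_hsv[..., 2])
    gxR, gyR = _sobel_gradients(reference_hsv[..., 2])
    magF = np.hypot(gxF, gyF)
    magR = np.hypot(gxR, gyR)
    qualifies = candidates & (magF >= params.tau_m) & (magR >= params.tau_m)

    dot = gxF * gxR + gyF * gyR
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.where(qualifies, dot / np.where(qualifies, magF * magR, 1.0), 0.0)
    dtheta = np.arccos(np.clip(cosang, -1.0, 1.0))
    agrees = qualifies & (params.tau_a - dtheta > 0)

    n_qual = np.bincount(labels[qualifies], minlength=n_blobs + 1)
    n_agree = np.bincount(labels[agrees], minlength=n_blobs + 1)
    # Textureless blobs (no qualifying pixel) stay shadow; otherwise C_B >= tau_c.
    with np.errstate(divide="ignore", invalid="ignore"):
        c_b = np.where(n_qual > 0, n_agree / np.maximum(n_qual, 1), np.nan)
    confirmed = np.where(n_qual > 0, c_b >= params.tau_c, True)
    confirmed[0] = False  # background label
    return confirmed[labels] & candidates


def remove_shadows(
    foreground: np.ndarray,
    frame_hsv: np.ndarray,
    reference_hsv: np.ndarray,
    params: ShadowParams | None = None,
) -> np.ndarray:
    """Run both shadow stages inside a foreground mask and strip confirmed shadow."""
    candidates = detect_shadow_pixels(frame_hsv, reference_hsv, params) & foreground
    confirmed = refine_shadow_blobs(candidates, frame_hsv, reference_hsv, params)
    return foreground & ~confirmed
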