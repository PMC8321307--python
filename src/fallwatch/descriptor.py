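"""Angular projection-histogram posture descriptor.

The silhouette's bounding box is viewed from two external reference points:
``Ph`` above the box on its center column (at the top image row) and ``Pv``
beside the box on its center row (at the right image border).  From each
point the box subtends a fan of angles which is split into ``N`` equal
sectors; a silhouette pixel therefore falls into one horizontal sector ``i``
(seen from Ph) and one vertical sector ``l`` (seen from Pv).  Counting pixels
per (i, l) cell gives an N x N projection histogram psi; dividing by the
pixel count M makes it size-invariant.  The classifier input appends three
global quantities — the two fan extents theta_V, theta_H and their ratio —
giving a feature vector of length N^2 + 3 (103 for the default N = 10).

Angles are measured as signed deviations from the axis through the reference
point and the box center; the fan extent is the max-minus-min of the four
box-corner angles, so every pixel of the box receives a valid sector.  For a
square box this extent reduces to the closed form 2*arctan(side / (2*D))
with D the reference-point-to-box distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BoundingBox, mask_bbox

__all__ = [
    "ReferencePoints",
    "PartitionGeometry",
    "compute_reference_points",
    "compute_partition_angles",
    "project_histogram",
    "normalize_histogram",
    "feature_vector",
    "FEATURE_N_DEFAULT",
]

FEATURE_N_DEFAULT = 10


@dataclass(frozen=True)
class ReferencePoints:
    """External viewpoints: ``ph`` above the shape, ``pv`` beside it (x, y)."""

    ph: tuple[float, float]
    pv: tuple[float, float]


@dataclass(frozen=True)
class PartitionGeometry:
    """Fan extents and sector steps of the two angular partitions.

    ``theta_h`` is the fan from Ph (indexes columns of psi), ``theta_v`` the
    fan from Pv.  ``h_min``/``v_min`` are the smallest corner angles, i.e.
    the lower edges of the fans in the signed-deviation measure.
    """

    theta_h: float
    theta_v: float
    delta_h: float
    delta_v: float
    d_h: float
    d_v: float
    h_min: float
    v_min: float


def compute_reference_points(
    bbox: BoundingBox, frame_width: int, frame_height: int
) -> ReferencePoints:
    """Place Ph on the box's center column at the top row and Pv on the box's
    center row at the right border.

    If the box touches the frame edge so that the nominal point would land
    inside it, the point is pushed one pixel outside the box instead.
    """
    xc, yc = bbox.center
    ph_y = 0.0
    if bbox.y0 <= ph_y:
        ph_y = float(bbox.y0 - 1)
    pv_x = float(frame_width - 1)
    if pv_x <= bbox.x1:  # on or inside the box edge: push strictly outside
        pv_x = float(bbox.x1 + 1)
    return ReferencePoints(ph=(xc, ph_y), pv=(pv_x, yc))


def _h_angle(x, y, ph: tuple[float, float]):
    """Signed deviation from the vertical axis through Ph (negative left)."""
    return np.arctan2(np.asarray(x, float) - ph[0], np.asarray(y, float) - ph[1])


def _v_angle(x, y, pv: tuple[float, float]):
    """Signed deviation from the horizontal axis through Pv (negative up)."""
    return np.arctan2(np.asarray(y, float) - pv[1], pv[0] - np.asarray(x, float))


def compute_partition_angles(
    bbox: BoundingBox, refs: ReferencePoints, n: int = FEATURE_N_DEFAULT
) -> PartitionGeometry:
    """Fan extents that exactly cover the box, from the four corner angles."""
    if n < 2:
        raise ValueError("need at least 2 partitions")
    d_h = bbox.distance_to_point(*refs.ph)
    d_v = bbox.distance_to_point(*refs.pv)
    if d_h == 0 or d_v == 0:
        raise ValueError("reference points must lie outside the bounding box")
    corners = bbox.corners()
    ah = _h_angle(corners[:, 0], corners[:, 1], refs.ph)
    av = _v_angle(corners[:, 0], corners[:, 1], refs.pv)
    theta_h = float(ah.max() - ah.min())
    theta_v = float(av.max() - av.min())
    return PartitionGeometry(
        theta_h=theta_h,
        theta_v=theta_v,
        delta_h=theta_h / n,
        delta_v=theta_v / n,
        d_h=d_h,
        d_v=d_v,
        h_min=float(ah.min()),
        v_min=float(av.min()),
    )


def project_histogram(
    mask: np.ndarray,
    bbox: BoundingBox,
    geometry: PartitionGeometry,
    refs: ReferencePoints,
    n: int = FEATURE_N_DEFAULT,
) -> np.ndarray:
    """Bin every silhouette pixel into the N x N sector grid (integer counts).

    Pixel centers (x + 0.5, y + 0.5) are used so that mirror and scale
    relations hold at the rasterization level.  Sector indices are computed
    with floor against the fan's lower edge and clamped to [0, N-1]; ties on
    a sector boundary go to the higher index.  The result satisfies
    ``psi.sum() == mask.sum()``.
    """
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if xs.size == 0:
        raise ValueError("empty silhouette")
    px = xs + 0.5
    py = ys + 0.5
    ah = _h_angle(px, py, refs.ph)
    av = _v_angle(px, py, refs.pv)
    i = np.clip(np.floor((ah - geometry.h_min) / geometry.delta_h).astype(int), 0, n - 1)
    l = np.clip(np.floor((av - geometry.v_min) / geometry.delta_v).astype(int), 0, n - 1)
    psi = np.zeros((n, n), dtype=np.int64)
    np.add.at(psi, (i, l), 1)
    return psi


def normalize_histogram(psi: np.ndarray) -> np.ndarray:
    """Divide by the pixel count M so the histogram sums to 1."""
    m = int(psi.sum())
    if m == 0:
        raise ValueError("empty silhouette")
    return psi.astype(np.float64) / m


def feature_vector(
    mask: np.ndarray,
    frame_dims: tuple[int, int] | None = None,
    n: int = FEATURE_N_DEFAULT,
) -> np.ndarray:
    """Full descriptor of one silhouette: [psi-hat row-major, theta_v, theta_h, ratio].

    ``frame_dims`` is (width, height); it defaults to the mask's own shape.
    The histogram block is flattened row-major (horizontal index i outer,
    vertical index l inner).  Length is ``n*n + 3``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty silhouette")
    if frame_dims is None:
        frame_dims = (mask.shape[1], mask.shape[0])
    bbox = mask_bbox(mask)
    refs = compute_reference_points(bbox, frame_dims[0], frame_dims[1])
    geom = compute_partition_angles(bbox, refs, n)
    psi_hat = normalize_histogram(project_histogram(mask, bbox, geom, refs, n))
    return np.concatenate(
        [psi_hat.ravel(), [geom.theta_v, geom.theta_h, geom.theta_h / geom.theta_v]]
    )
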