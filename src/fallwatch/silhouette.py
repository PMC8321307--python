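"""Person-blob selection and the per-frame silhouette extraction chain.

After background subtraction and shadow removal the foreground still holds
several blobs (body parts split by occlusion, residual noise, displaced
furniture).  Selection proceeds in three steps: drop blobs below a minimum
area, merge the survivors into clusters by single-linkage under a
rectangle-distance threshold, and pick the cluster that scores highest on
``motion / (1 + d_prev)`` — favouring clusters with many freshly-changed
pixels close to the person's previous position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .background import BackgroundModel, subtract_background
from .geometry import BoundingBox, mask_bbox, rectangle_distance
from .shadow import EIGHT_CONNECTED, ShadowParams, normalize_value_channel, remove_shadows, rgb_to_hsv

__all__ = ["PersonState", "extract_person_blob", "SilhouetteExtractor"]

MIN_BLOB_AREA = 50  # pixels; smaller blobs are segmentation noise
MERGE_DISTANCE = 50.0  # pixels; blobs closer than this belong to one object


@dataclass
class PersonState:
    """Where the person was last seen: tight box plus silhouette mask."""

    bbox: BoundingBox
    mask: np.ndarray


def extract_person_blob(
    foreground: np.ndarray,
    prev_state: PersonState | None = None,
    prev_frame_mask: np.ndarray | None = None,
    min_blob_area: int = MIN_BLOB_AREA,
    merge_distance: float = MERGE_DISTANCE,
) -> tuple[np.ndarray, BoundingBox]:
    """Isolate the person cluster from a cleaned foreground mask.

    Parameters
    ----------
    foreground
        Boolean foreground mask after shadow removal.
    prev_state
        Person box/mask from the previous frame (None on the first frame).
    prev_frame_mask
        Full foreground mask of the previous frame, used for the
        changed-pixel motion score (None on the first frame -> motion 1).

    Returns
    -------
    (mask, bbox)
        The selected cluster's pixel union and its tight bounding box.
    """
    foreground = np.asarray(foreground, dtype=bool)
    labels, n_blobs = ndimage.label(foreground, structure=EIGHT_CONNECTED)
    if n_blobs == 0:
        raise ValueError("no person detected: empty foreground")
    areas = np.bincount(labels.ravel(), minlength=n_blobs + 1)
    keep = np.nonzero(areas[1:] >= min_blob_area)[0] + 1
    if keep.size == 0:
        raise ValueError("no person detected: all blobs below minimum area")

    slices = ndimage.find_objects(labels)
    boxes = {}
    for lab in keep:
        sy, sx = slices[lab - 1]
        boxes[lab] = BoundingBox(sx.start, sy.start, sx.stop - sx.start, sy.stop - sy.start)

    # Single-linkage clustering: blobs within merge_distance share a cluster.
    idx = {lab: i for i, lab in enumerate(keep)}
    rows, cols = [], []
    for a_pos, a in enumerate(keep):
        for b in keep[a_pos + 1 :]:
            if rectangle_distance(boxes[a], boxes[b]) <= merge_distance:
                rows.append(idx[a])
                cols.append(idx[b])
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(keep.size, keep.size)
    )
    n_clusters, membership = connected_components(adj, directed=False)

    best = None
    for c in range(n_clusters):
        cluster_labels = keep[membership == c]
        cluster_mask = np.isin(labels, cluster_labels)
        ys, xs = np.nonzero(cluster_mask)
        if prev_frame_mask is None:
            motion = 1.0
        else:
            motion = float(np.mean(~np.asarray(prev_frame_mask, dtype=bool)[ys, xs]))
        if prev_state is None:
            d_prev = 0.0
        else:
            cx, cy = float(xs.mean()), float(ys.mean())
            px, py = prev_state.bbox.center
            d_prev = float(np.hypot(cx - px, cy - py))
        score = motion / (1.0 + d_prev)
        # Tie-break: nearer to the previous position, then larger area.
        key = (score, -d_prev, ys.size)
        if best is None or key > best[0]:
            best = (key, cluster_mask)

    mask = best[1]
    return mask, mask_bbox(mask)


class SilhouetteExtractor:
    """Stateful per-frame extraction: subtraction, shadow removal, blob selection.

    Holds the background model plus the previous-frame state needed by the
    motion/distance scoring.  ``process(frame)`` returns ``(mask, bbox)`` or
    ``None`` when no plausible person blob is present.
    """

    def __init__(
        self,
        model: BackgroundModel,
        shadow_params: ShadowParams | None = None,
        min_blob_area: int = MIN_BLOB_AREA,
        merge_distance: float = MERGE_DISTANCE,
    ) -> None:
        self.model = model
        self.shadow_params = shadow_params or ShadowParams()
        self.min_blob_area = min_blob_area
        self.merge_distance = merge_distance
        self._reference_hsv = normalize_value_channel(rgb_to_hsv(model.reference_image))
        self._prev_state: PersonState | None = None
        self._prev_foreground: np.ndarray | None = None

    def process(self, frame: np.ndarray) -> tuple[np.ndarray, BoundingBox] | None:
        raw = subtract_background(self.model, frame)
        frame_hsv = normalize_value_channel(rgb_to_hsv(frame))
        cleaned = remove_shadows(raw, frame_hsv, self._reference_hsv, self.shadow_params)
        try:
            mask, bbox = extract_person_blob(
                cleaned,
                prev_state=self._prev_state,
                prev_frame_mask=self._prev_foreground,
                min_blob_area=self.min_blob_area,
                merge_distance=self.merge_distance,
            )
        except ValueError:
            self._prev_foreground = cleaned
            return None
        self._prev_state = PersonState(bbox=bbox, mask=mask)
        self._prev_foreground = cleaned
        return mask, bbox
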