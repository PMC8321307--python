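"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — per-pixel Python loops, dense
boundary sampling, BFS flood fill — and shares no code path with the
package modules it validates.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def naive_projection_histogram(mask: np.ndarray, n: int, frame_dims=None) -> np.ndarray:
    """Per-pixel double-angle binning with scalar math, recomputed from scratch."""
    ys, xs = np.nonzero(mask)
    h_img, w_img = mask.shape
    if frame_dims is None:
        frame_dims = (w_img, h_img)
    fw, fh = frame_dims
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    xc, yc = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    ph = (xc, 0.0 if y0 > 0 else y0 - 1.0)
    pv = (float(fw - 1) if fw - 1 > x1 else x1 + 1.0, yc)
    corners = [(x0, y0), (x1, y0), (x0, y1), (x1, y1)]
    ah = [math.atan2(cx - ph[0], cy - ph[1]) for cx, cy in corners]
    av = [math.atan2(cy - pv[1], pv[0] - cx) for cx, cy in corners]
    h_min, h_max = min(ah), max(ah)
    v_min, v_max = min(av), max(av)
    dh = (h_max - h_min) / n
    dv = (v_max - v_min) / n
    psi = np.zeros((n, n), dtype=np.int64)
    for x, y in zip(xs, ys):
        a = math.atan2(x + 0.5 - ph[0], y + 0.5 - ph[1])
        b = math.atan2(y + 0.5 - pv[1], pv[0] - (x + 0.5))
        i = min(n - 1, max(0, int(math.floor((a - h_min) / dh))))
        l = min(n - 1, max(0, int(math.floor((b - v_min) / dv))))
        psi[i, l] += 1
    return psi


def boundary_points(x0: float, y0: float, w: float, h: float, per_edge: int = 60) -> np.ndarray:
    """Dense sample of a rectangle's boundary (corners included)."""
    t = np.linspace(0.0, 1.0, per_edge)
    xs = np.concatenate([x0 + t * w, np.full(per_edge, x0 + w), x0 + t * w, np.full(per_edge, x0)])
    ys = np.concatenate([np.full(per_edge, y0), y0 + t * h, np.full(per_edge, y0 + h), y0 + t * h])
    return np.column_stack([xs, ys])


def brute_force_rect_distance(b1, b2, per_edge: int = 60) -> float:
    """Min distance between two rectangles by exhaustive boundary search."""
    if not (b1.x1 < b2.x0 or b2.x1 < b1.x0 or b1.y1 < b2.y0 or b2.y1 < b1.y0):
        return 0.0  # overlap or touch
    p = boundary_points(b1.x0, b1.y0, b1.width, b1.height, per_edge)
    q = boundary_points(b2.x0, b2.y0, b2.width, b2.height, per_edge)
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(-1))
    return float(d.min())


def flood_fill_blobs(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected components by BFS; returns one boolean mask per blob."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    blobs = []
    h, w = mask.shape
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        blob = np.zeros_like(mask)
        queue = deque([(sy, sx)])
        seen[sy, sx] = blob[sy, sx] = True
        while queue:
            y, x = queue.popleft()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = blob[ny, nx] = True
                        queue.append((ny, nx))
        blobs.append(blob)
    return blobs


def sobel_oracle(v01: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3x3 Sobel by explicit shifted sums on an edge-padded 0-255 image."""
    v = np.asarray(v01, dtype=float) * 255.0
    p = np.pad(v, 1, mode="edge")
    c = lambda dy, dx: p[1 + dy : 1 + dy + v.shape[0], 1 + dx : 1 + dx + v.shape[1]]
    gx = (c(-1, 1) + 2 * c(0, 1) + c(1, 1)) - (c(-1, -1) + 2 * c(0, -1) + c(1, -1))
    gy = (c(1, -1) + 2 * c(1, 0) + c(1, 1)) - (c(-1, -1) + 2 * c(-1, 0) + c(-1, 1))
    return gx, gy


def shadow_blob_decisions(
    candidates: np.ndarray,
    frame_hsv: np.ndarray,
    reference_hsv: np.ndarray,
    tau_m: float,
    tau_a: float,
    tau_c: float,
) -> np.ndarray:
    """Recompute the per-blob gradient-correlation verdicts pixel by pixel."""
    gxF, gyF = sobel_oracle(frame_hsv[..., 2])
    gxR, gyR = sobel_oracle(reference_hsv[..., 2])
    confirmed = np.zeros_like(np.asarray(candidates, dtype=bool))
    for blob in flood_fill_blobs(candidates):
        votes = []
        for y, x in zip(*np.nonzero(blob)):
            mf = math.hypot(gxF[y, x], gyF[y, x])
            mr = math.hypot(gxR[y, x], gyR[y, x])
            if mf < tau_m or mr < tau_m:
                continue
            cosang = (gxF[y, x] * gxR[y, x] + gyF[y, x] * gyR[y, x]) / (mf * mr)
            dtheta = math.acos(max(-1.0, min(1.0, cosang)))
            votes.append(1 if tau_a - dtheta > 0 else 0)
        is_shadow = True if not votes else (sum(votes) / len(votes)) >= tau_c
        if is_shadow:
            confirmed |= blob
    return confirmed


def one_vs_rest_counts(pred, truth, label) -> tuple[int, int, int, int]:
    """Brute-force TP/FP/TN/FN recount for one class."""
    tp = fp = tn = fn = 0
    for p, t in zip(pred, truth):
        if t == label and p == label:
            tp += 1
        elif t != label and p == label:
            fp += 1
        elif t == label and p != label:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn
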