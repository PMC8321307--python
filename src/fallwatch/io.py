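"""Readers and writers: frame directories, binary mask PNGs, feature CSVs."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_frames",
    "read_mask",
    "write_mask",
    "write_features_csv",
    "read_features_csv",
]

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def read_frames(dir_path) -> list[np.ndarray]:
    """Load all frames of a directory in lexicographic order as uint8 RGB.

    All frames must share one shape; the first offending file is named in
    the error.
    """
    dir_path = Path(dir_path)
    files = sorted(
        p for p in dir_path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not files:
        raise ValueError(f"no decodable images in {dir_path}")
    frames = []
    shape = None
    for p in files:
        img = np.asarray(iio.imread(p))
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = img[..., :3]
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"dimension mismatch: {p.name} has {img.shape}, expected {shape}"
            )
        frames.append(img.astype(np.uint8))
    return frames


def read_mask(path) -> np.ndarray:
    """Read a single-channel 0/255 PNG as a boolean mask (bit-exact contract)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        if not (img == img[..., :1]).all():
            raise ValueError(f"{path}: mask must be single-channel")
        img = img[..., 0]
    bad = int(((img != 0) & (img != 255)).sum())
    if bad:
        raise ValueError(f"{path}: {bad} pixels are neither 0 nor 255")
    return img == 255


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def feature_columns(n: int) -> list[str]:
    width = len(str(n * n - 1))
    return [f"f{i:0{width}d}" for i in range(n * n)] + ["theta_v", "theta_h", "ratio"]


def write_features_csv(path, features: np.ndarray, labels=None) -> None:
    """One row per silhouette; deterministic 12-significant-digit formatting."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n = int(round((X.shape[1] - 3) ** 0.5))
    if n * n + 3 != X.shape[1]:
        raise ValueError(f"feature width {X.shape[1]} is not N^2+3 for integer N")
    df = pd.DataFrame(X, columns=feature_columns(n))
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=int)
    df.to_csv(path, index=False, float_format="%.12g")


def read_features_csv(path) -> tuple[np.ndarray, np.ndarray | None]:
    df = pd.read_csv(path)
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=float), labels
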