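"""Arrange the 48 corrected features into a 4x4x3 pseudo-RGB image.

Plane 0 holds DE, plane 1 PSD, plane 2 the spatial (EVI/ASI) features.
Within each plane, rows are bands (theta, alpha, beta, gamma, top to
bottom) and columns are channels (FP1, FP2, AF3, AF4) for DE/PSD or
channel pairs for the spatial plane, whose theta row carries the 4 EVI
values and remaining rows the ASI values.  This keeps each band's
cross-channel pattern inside a single row reachable by a 3x3 convolution.
"""

from __future__ import annotations

import numpy as np

from .bands import CHANNELS, DEFAULT_BANDS, PAIRS, FeatureWindow, feature_names

LAYOUT_VERSION = "1"

PLANE_NAMES = ("de", "psd", "spatial")


def build_plane(block) -> np.ndarray:
    """Row-major 4x4 matrix from a 16-vector in canonical band-major order."""
    block = np.asarray(block, dtype=float)
    if block.shape != (16,):
        raise ValueError(f"plane block must have 16 entries, got shape {block.shape}")
    return block.reshape(4, 4)


def stack_pseudo_rgb(de_plane, psd_plane, spatial_plane) -> np.ndarray:
    """Stack three 4x4 planes into a 4x4x3 tensor with plane order (DE, PSD, EVI-ASI)."""
    planes = [np.asarray(p, dtype=float) for p in (de_plane, psd_plane, spatial_plane)]
    for p in planes:
        if p.shape != (4, 4):
            raise ValueError(f"each plane must be 4x4, got {p.shape}")
    return np.stack(planes, axis=-1)


def window_to_image(feature_values) -> np.ndarray:
    """48 canonical feature values -> 4x4x3 pseudo-RGB image."""
    values = np.asarray(feature_values, dtype=float)
    if values.shape != (48,):
        raise ValueError("expected 48 canonical feature values")
    return stack_pseudo_rgb(*(build_plane(values[16 * k:16 * (k + 1)]) for k in range(3)))


def batch_tensors(images) -> np.ndarray:
    """Stack pseudo-RGB images into a (batch, 4, 4, 3) tensor, order preserved."""
    images = list(images)
    if not images:
        raise ValueError("cannot batch zero images")
    batch = np.stack([np.asarray(im, dtype=float) for im in images])
    if batch.shape[1:] != (4, 4, 3):
        raise ValueError(f"expected images of shape (4,4,3), got {batch.shape[1:]}")
    return batch


def layout_map() -> dict[str, tuple[int, int, int]]:
    """Bijection feature name -> (row, col, plane) tensor coordinate."""
    coords = {}
    for flat, name in enumerate(feature_names()):
        plane, rem = divmod(flat, 16)
        row, col = divmod(rem, 4)
        coords[name] = (row, col, plane)
    return coords


def feature_at(image: np.ndarray, name: str) -> float:
    """Read one named feature back out of a pseudo-RGB image."""
    row, col, plane = layout_map()[name]
    return float(image[row, col, plane])


# -- HDF5 persistence ------------------------------------------------------

def save_images(path, images: np.ndarray, labels: np.ndarray) -> None:
    """Persist a batch to HDF5 (datasets ``images`` float32, ``labels`` int)."""
    import h5py

    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if images.shape[0] != labels.shape[0]:
        raise ValueError("images and labels must have the same leading dimension")
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=images)
        f.create_dataset("labels", data=labels)
        f.attrs["layout_version"] = LAYOUT_VERSION


def load_images(path):
    """Load a persisted batch; returns ``(images, labels)``."""
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("layout_version") != LAYOUT_VERSION:
            raise ValueError("unknown pseudo-RGB layout version")
        return f["images"][...], f["labels"][...]
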