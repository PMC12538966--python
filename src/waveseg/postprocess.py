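"""Spatial post-processing of rasterized wave labels.

The temporal segmentation runs independently per grid position, so small
spurious detections (thin strips, isolated specks, twitches of the embryo
proper near the head) survive it.  These operations clean each frame of a
label map (0 = none, 1 = V phase, 2 = D phase); each phase mask is treated
separately and the operations only ever delete labels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["morphological_open_labels", "size_filter", "region_filter"]


def _per_phase(labels: np.ndarray, fn) -> np.ndarray:
    """Apply a binary-mask -> binary-mask function per frame and phase."""
    labels = np.asarray(labels)
    out = np.zeros_like(labels)
    for t in range(labels.shape[0]):
        for phase in (1, 2):
            kept = fn(labels[t] == phase, t)
            out[t][kept] = phase
    return out


def morphological_open_labels(labels: np.ndarray, radius: int) -> np.ndarray:
    """Binary opening of each phase mask at scale ``radius``.

    The structuring element is the square/cube of side 2*radius + 1
    (Chebyshev ball), so segmentations thinner than the element vanish
    while solid blocks are preserved exactly, corners included.  Radius 0
    is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return np.asarray(labels).copy()
    nd = np.asarray(labels).ndim - 1
    selem = np.ones((2 * radius + 1,) * nd, dtype=bool)
    return _per_phase(labels, lambda m, t: ndimage.binary_opening(m, selem))


def size_filter(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` grid cells.

    Face adjacency (4-connectivity in 2D, 6 in 3D); components of exactly
    ``min_size`` cells are kept.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")

    def keep_large(mask: np.ndarray, t: int) -> np.ndarray:
        lab, n = ndimage.label(mask)  # default structure = face adjacency
        if n == 0:
            return mask
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes < min_size)
        return mask & ~np.isin(lab, small[small > 0])

    return _per_phase(labels, keep_large)


def region_filter(labels: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Drop components whose centroid falls inside an exclusion region.

    ``region`` is a binary spatial mask (e.g. around the head of the
    embryo); a component is removed when the rounded mean of its member
    coordinates indexes a region cell.  Components merely overlapping the
    region edge but centered outside are kept.
    """
    region = np.asarray(region).astype(bool)
    first = np.asarray(labels)[0]
    if region.shape != first.shape:
        raise ValueError("region shape must match the label map spatial shape")

    def keep_outside(mask: np.ndarray, t: int) -> np.ndarray:
        lab, n = ndimage.label(mask)
        if n == 0:
            return mask
        out = mask.copy()
        centroids = ndimage.center_of_mass(mask, lab, range(1, n + 1))
        for i, c in enumerate(centroids, start=1):
            idx = tuple(
                int(np.clip(round(ci), 0, s - 1)) for ci, s in zip(c, mask.shape)
            )
            if region[idx]:
                out[lab == i] = False
        return out

    return _per_phase(labels, keep_outside)
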