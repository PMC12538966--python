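"""Secondary descriptors of vector fields and label maps.

Divergence maps are computed by correlating the field with an "expanding
template": a kernel of unit vectors pointing away from its center.  The
scalar response sums the dot products of the template with the vectors
around each node, so positive values mark local expansion and negative
values constriction; the template size sets the spatial scale of the
divergence patterns.  At the grid border the kernel is clipped (partial
sums), which attenuates but never inflates border values.

Kymographs reduce a (t, y, x) stack to a 2D (retained axis, t) plot by
summing over one spatial axis; label maps yield one kymograph per phase.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .piv import VectorFieldSequence

__all__ = [
    "expanding_template",
    "divergence_map",
    "divergence_extrema_track",
    "kymograph",
    "label_kymographs",
]

DEFAULT_KERNEL_SIZE = 17


def expanding_template(size: int, ndim: int = 2) -> np.ndarray:
    """Kernel of unit vectors pointing away from the center.

    Returns shape (size,)*ndim + (ndim,); the center cell is the zero
    vector.  By central antisymmetry the kernel sums to zero.
    """
    if size % 2 == 0 or size < 3:
        raise ValueError("template size must be odd and >= 3")
    axes = [np.arange(size) - size // 2 for _ in range(ndim)]
    offsets = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).astype(float)
    norms = np.linalg.norm(offsets, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        kernel = np.where(norms > 0, offsets / np.where(norms > 0, norms, 1.0), 0.0)
    return kernel


def divergence_map(
    fields: VectorFieldSequence | np.ndarray,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
) -> np.ndarray:
    """Expanding-template divergence D(p,t) = sum_q k(q) . v_{p+q,t}.

    ``fields`` is a VectorFieldSequence (invalid nodes contribute zero) or
    a raw (t, *grid, D) array.  Returns shape (t, *grid).
    """
    if isinstance(fields, VectorFieldSequence):
        vectors = np.where(fields.validity[..., None], fields.vectors, 0.0)
    else:
        vectors = np.asarray(fields, dtype=float)
    grid_shape = vectors.shape[1:-1]
    ndim = vectors.shape[-1]
    if any(kernel_size > n for n in grid_shape):
        raise ValueError("kernel larger than the vector grid")
    kernel = expanding_template(kernel_size, ndim)
    out = np.zeros(vectors.shape[:-1], dtype=float)
    for t in range(vectors.shape[0]):
        for c in range(ndim):
            out[t] += ndimage.correlate(
                vectors[t, ..., c], kernel[..., c], mode="constant", cval=0.0
            )
    return out


def divergence_extrema_track(
    maps: np.ndarray, k: int = 1, kernel_size: int = DEFAULT_KERNEL_SIZE
) -> list[dict[str, list[tuple[int, ...]]]]:
    """Per-frame coordinates of the k strongest divergence minima/maxima.

    A node counts as an extremum only if it is strictly larger (resp.
    smaller) than every other value within one kernel radius, so flat
    fields report nothing; the k extrema of largest absolute response are
    returned per frame, strongest first.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    maps = np.asarray(maps, dtype=float)
    footprint = np.ones((kernel_size,) * (maps.ndim - 1), dtype=bool)
    footprint[(kernel_size // 2,) * (maps.ndim - 1)] = False
    out = []
    for frame in maps:
        neigh_max = ndimage.maximum_filter(frame, footprint=footprint, mode="nearest")
        neigh_min = ndimage.minimum_filter(frame, footprint=footprint, mode="nearest")
        maxima = np.argwhere(frame > neigh_max)
        minima = np.argwhere(frame < neigh_min)
        maxima = sorted(map(tuple, maxima), key=lambda p: -frame[p])[:k]
        minima = sorted(map(tuple, minima), key=lambda p: frame[p])[:k]
        out.append({"minima": minima, "maxima": maxima})
    return out


def _axis_index(axis: int | str, ndim: int) -> int:
    if isinstance(axis, str):
        name = axis.lower()
        if name == "x":
            axis = ndim - 1
        elif name == "y":
            axis = ndim - 2
        else:
            raise ValueError(f"unknown axis name {axis!r}")
    axis = int(axis)
    if not 1 <= axis < ndim:
        raise ValueError("axis must name a spatial axis")
    return axis


def kymograph(
    data: np.ndarray, axis: int | str = "x", reduction: str = "sum"
) -> np.ndarray:
    """Project a (t, *spatial) stack along one spatial axis.

    Returns (retained axis, t).  ``reduction`` is "sum" (summed intensity
    projection) or "mean" for density-style views.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("kymograph expects a (t, y, x) stack")
    ax = _axis_index(axis, data.ndim)
    if reduction == "sum":
        proj = data.sum(axis=ax)
    elif reduction == "mean":
        proj = data.mean(axis=ax)
    else:
        raise ValueError("reduction must be 'sum' or 'mean'")
    return proj.T  # (retained spatial axis, t)


def label_kymographs(
    labels: np.ndarray, axis: int | str = "x", reduction: str = "sum"
) -> dict[str, np.ndarray]:
    """One kymograph per phase of a (t, y, x) label map (1 = V, 2 = D)."""
    labels = np.asarray(labels)
    return {
        "V": kymograph((labels == 1).astype(float), axis, reduction),
        "D": kymograph((labels == 2).astype(float), axis, reduction),
    }
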