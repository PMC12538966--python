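"""Masked particle image velocimetry (PIV) on 2D and 3D image pairs.

Displacements between consecutive frames are estimated per interrogation
window by minimizing a normalized squared-difference score

    NSQ(d) = sum_x (a(x) - b(x+d))^2 / sqrt(sum_x a(x)^2 * sum_x b(x+d)^2)

over a bounded search range, which is more robust to intensity changes than
plain cross-correlation.  The sums over shifted windows are evaluated with
frequency-domain products; windows that fall outside the image are clipped,
never wrapped.  An optional 3-point parabolic fit per axis refines the
integer minimum to sub-pixel precision.

A static binary mask restricts the analysis to a region of interest (for
instance a surface shell of an embryo): grid nodes whose interrogation
window overlaps the mask by less than ``min_mask_fraction`` are flagged
invalid and carry zero vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "ImageSequence",
    "PivConfig",
    "VectorFieldSequence",
    "compute_piv_pair",
    "compute_piv_sequence",
    "average_velocity",
]

_EPS = 1e-12


@dataclass
class ImageSequence:
    """A (t, y, x) or (t, z, y, x) grayscale recording.

    ``pixel_pitch`` is micrometers per pixel per spatial axis and
    ``frame_interval`` minutes per frame; both are metadata carried through
    to outputs and do not affect the pixel-unit PIV computation.
    """

    data: np.ndarray
    pixel_pitch: tuple[float, ...] | None = None
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("image sequence must be (t,y,x) or (t,z,y,x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]


@dataclass
class PivConfig:
    """Interrogation settings.

    ``interrogation_size`` defaults to 32 px/axis in 2D and 24 vx/axis in
    3D; ``grid_step`` defaults to half the interrogation size (50 %
    overlap).  ``search_margin`` bounds the recoverable displacement per
    axis.
    """

    interrogation_size: int | Sequence[int] | None = None
    search_margin: int | Sequence[int] = 10
    grid_step: int | Sequence[int] | None = None
    min_mask_fraction: float = 0.5
    subpixel: bool = True

    def resolve(self, ndim: int) -> tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]:
        """Return per-axis (interrogation, margin, step) for ``ndim`` axes."""
        inter = self.interrogation_size
        if inter is None:
            inter = 32 if ndim == 2 else 24
        inter = _per_axis(inter, ndim)
        margin = _per_axis(self.search_margin, ndim)
        step = self.grid_step
        if step is None:
            step = tuple(i // 2 for i in inter)
        step = _per_axis(step, ndim)
        if any(i < 4 for i in inter):
            raise ValueError("interrogation_size must be >= 4 per axis")
        if any(m < 1 for m in margin):
            raise ValueError("search_margin must be >= 1")
        if any(s < 1 for s in step):
            raise ValueError("grid_step must be >= 1")
        if not 0.0 <= self.min_mask_fraction <= 1.0:
            raise ValueError("min_mask_fraction must be in [0, 1]")
        return inter, margin, step


def _per_axis(value: int | Sequence[int], ndim: int) -> tuple[int, ...]:
    if np.isscalar(value):
        return (int(value),) * ndim
    value = tuple(int(v) for v in value)  # type: ignore[union-attr]
    if len(value) != ndim:
        raise ValueError(f"expected {ndim} per-axis values, got {len(value)}")
    return value


@dataclass
class VectorFieldSequence:
    """Gridded displacement vectors between consecutive frames.

    ``vectors`` has shape (t, *grid_shape, D) with components in spatial
    axis order; ``validity`` has shape (t, *grid_shape).  Invalid nodes
    carry zero vectors.  Node k sits at pixel coordinate
    ``grid_origin + k * grid_step`` per axis.
    """

    vectors: np.ndarray
    validity: np.ndarray
    grid_step: tuple[int, ...]
    grid_origin: tuple[int, ...]
    units: str = "px/frame"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.vectors.ndim < 3:
            raise ValueError("vectors must be (t, *grid, D)")
        if self.vectors.shape[:-1] != self.validity.shape:
            raise ValueError("validity shape must match vectors without components")
        if self.vectors.shape[-1] != self.validity.ndim - 1:
            raise ValueError("component count must equal number of grid axes")
        self.grid_step = tuple(int(s) for s in self.grid_step)
        self.grid_origin = tuple(int(o) for o in self.grid_origin)

    @property
    def n_steps(self) -> int:
        return self.vectors.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.vectors.shape[1:-1]

    @property
    def ndim(self) -> int:
        return self.vectors.shape[-1]

    def magnitudes(self) -> np.ndarray:
        """Per-node speeds, shape (t, *grid)."""
        return np.linalg.norm(self.vectors, axis=-1)

    def node_coordinates(self) -> np.ndarray:
        """Pixel coordinates of grid nodes, shape (*grid, D)."""
        axes = [
            self.grid_origin[a] + np.arange(n) * self.grid_step[a]
            for a, n in enumerate(self.grid_shape)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _grid_layout(
    shape: tuple[int, ...], inter: tuple[int, ...], step: tuple[int, ...]
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Grid shape and origin such that every interrogation window fits."""
    origin = tuple(i // 2 for i in inter)
    counts = []
    for ax, n in enumerate(shape):
        if n < inter[ax]:
            raise ValueError("image smaller than interrogation window")
        counts.append((n - inter[ax]) // step[ax] + 1)
    return tuple(counts), origin


def _nsq_min(
    win_a: np.ndarray, region: np.ndarray, subpixel: bool
) -> tuple[np.ndarray | None, np.ndarray]:
    """Locate the NSQ minimum of ``win_a`` over all placements in ``region``.

    Returns (displacement relative to region origin, score surface), or
    (None, surface) when no placement has signal.
    """
    suma2 = float(np.sum(win_a * win_a))
    flip = win_a[tuple(slice(None, None, -1) for _ in win_a.shape)]
    cross = fftconvolve(region, flip, mode="valid")
    sumb2 = fftconvolve(region * region, np.ones_like(win_a), mode="valid")
    sumb2 = np.maximum(sumb2, 0.0)
    denom = np.sqrt(suma2 * sumb2)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (suma2 - 2.0 * cross + sumb2) / denom
    score[denom <= _EPS * max(suma2, 1.0)] = np.inf
    if not np.any(np.isfinite(score)):
        return None, score
    idx = np.unravel_index(np.argmin(score), score.shape)
    disp = np.asarray(idx, dtype=float)
    if subpixel:
        for ax, i in enumerate(idx):
            if i == 0 or i == score.shape[ax] - 1:
                continue  # peak touches the search border: no refinement
            sel = list(idx)
            sel[ax] = i - 1
            sm = score[tuple(sel)]
            sel[ax] = i + 1
            sp = score[tuple(sel)]
            s0 = score[idx]
            den = sm - 2.0 * s0 + sp
            if np.isfinite(sm) and np.isfinite(sp) and den > _EPS:
                delta = 0.5 * (sm - sp) / den
                if abs(delta) <= 1.0:
                    disp[ax] += delta
    return disp, score


def compute_piv_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    mask: np.ndarray | None,
    cfg: PivConfig,
) -> VectorFieldSequence:
    """PIV between two frames; returns a single-time-step field.

    For each grid node the interrogation window from ``frame_a`` is placed
    at every displacement within ``search_margin`` in ``frame_b`` (clipped
    at the image borders) and the NSQ score minimized.  Nodes with an
    all-zero window, with no feasible placement, or with insufficient mask
    overlap are flagged invalid.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share a shape")
    nd = frame_a.ndim
    if nd not in (2, 3):
        raise ValueError("frames must be 2D or 3D")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != frame_a.shape:
            raise ValueError("mask shape must match the frames")
        mask = mask.astype(bool)
    inter, margin, step = cfg.resolve(nd)
    grid_shape, origin = _grid_layout(frame_a.shape, inter, step)

    vectors = np.zeros(grid_shape + (nd,), dtype=float)
    validity = np.zeros(grid_shape, dtype=bool)

    for node in np.ndindex(*grid_shape):
        starts = [origin[a] - inter[a] // 2 + node[a] * step[a] for a in range(nd)]
        win_sl = tuple(slice(s, s + inter[a]) for a, s in enumerate(starts))
        if mask is not None:
            if mask[win_sl].mean() < cfg.min_mask_fraction:
                continue
        win_a = frame_a[win_sl]
        if not np.any(win_a):
            continue  # all-zero interrogation window
        reg_lo = [max(0, starts[a] - margin[a]) for a in range(nd)]
        reg_hi = [
            min(frame_a.shape[a], starts[a] + inter[a] + margin[a]) for a in range(nd)
        ]
        region = frame_b[tuple(slice(lo, hi) for lo, hi in zip(reg_lo, reg_hi))]
        disp, _ = _nsq_min(win_a, region, cfg.subpixel)
        if disp is None:
            continue
        # index 0 of the score surface corresponds to displacement reg_lo - start
        vectors[node] = disp + np.array(reg_lo) - np.array(starts)
        validity[node] = True

    return VectorFieldSequence(
        vectors=vectors[None],
        validity=validity[None],
        grid_step=step,
        grid_origin=origin,
        units="px/frame" if nd == 2 else "vx/frame",
    )


def compute_piv_sequence(
    images: ImageSequence | np.ndarray,
    mask: np.ndarray | None,
    cfg: PivConfig,
) -> VectorFieldSequence:
    """PIV between each pair of consecutive frames.

    One static mask is used for all time steps so that every field slice
    shares the same grid and the same set of valid coordinates.
    """
    data = images.data if isinstance(images, ImageSequence) else np.asarray(images)
    if data.shape[0] < 2:
        raise ValueError("need at least two frames")
    slices = [
        compute_piv_pair(data[t], data[t + 1], mask, cfg)
        for t in range(data.shape[0] - 1)
    ]
    first = slices[0]
    return VectorFieldSequence(
        vectors=np.concatenate([s.vectors for s in slices], axis=0),
        validity=np.concatenate([s.validity for s in slices], axis=0),
        grid_step=first.grid_step,
        grid_origin=first.grid_origin,
        units=first.units,
    )


def average_velocity(fields: VectorFieldSequence) -> np.ndarray:
    """Mean speed over valid nodes per time step.

    Time steps without a single valid node yield NaN.
    """
    mags = fields.magnitudes()
    out = np.full(fields.n_steps, np.nan)
    for t in range(fields.n_steps):
        valid = fields.validity[t]
        if np.any(valid):
            out[t] = mags[t][valid].mean()
    return out
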