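"""Cylinder-map distortion correction and surface-mask extraction.

Unrolling a closed embryo surface onto a flat cylinder map distorts
lengths: the map renders meridian (pole-to-pole) distances shortened and
circumferential distances elongated toward the poles, while the equator is
distortion-free.  The correction multiplies each PIV vector component by
the true-length/map-length factor of the 10x10-pixel tile containing the
node; angles are not corrected (angular distortion only matters very close
to the poles, which are cropped before analysis).

Axis convention for maps: axis 0 = longitudinal (pole to pole), axis 1 =
latitudinal (around the circumference, periodic).

The surface-mask stage reconstructs a closed shell around a bright
surface-like object in a 3D volume: threshold, bridge gaps up to a scale
``alpha``, fill the interior, and keep a shell of voxels a few layers
inside and outside the outer boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import ball

from .piv import VectorFieldSequence

__all__ = [
    "DistortionGrid",
    "correct_distortion",
    "extract_surface_mask",
    "combine_masks",
]


@dataclass
class DistortionGrid:
    """Per-tile length-correction factors for a cylinder projection.

    ``longitudinal`` and ``latitudinal`` are (rows, cols) arrays of
    positive factors, one per ``tile_size`` x ``tile_size`` pixel tile.
    Multiplying a map-measured displacement component by its factor yields
    the corrected (true surface) length along that direction.
    """

    longitudinal: np.ndarray
    latitudinal: np.ndarray
    tile_size: int = 10

    def __post_init__(self) -> None:
        self.longitudinal = np.asarray(self.longitudinal, dtype=float)
        self.latitudinal = np.asarray(self.latitudinal, dtype=float)
        if self.longitudinal.shape != self.latitudinal.shape:
            raise ValueError("factor grids must share a shape")
        if self.longitudinal.ndim != 2:
            raise ValueError("factor grids must be 2D")
        if np.any(self.longitudinal <= 0) or np.any(self.latitudinal <= 0):
            raise ValueError("distortion factors must be positive")
        if self.tile_size < 1:
            raise ValueError("tile_size must be >= 1")

    def reciprocal(self) -> "DistortionGrid":
        """The exactly inverting grid."""
        return replace(
            self,
            longitudinal=1.0 / self.longitudinal,
            latitudinal=1.0 / self.latitudinal,
        )

    @classmethod
    def from_csv(cls, path, tile_size: int = 10) -> "DistortionGrid":
        df = pd.read_csv(path)
        rows = int(df["tile_row"].max()) + 1
        cols = int(df["tile_col"].max()) + 1
        lon = np.full((rows, cols), np.nan)
        lat = np.full((rows, cols), np.nan)
        lon[df["tile_row"], df["tile_col"]] = df["longitudinal_factor"]
        lat[df["tile_row"], df["tile_col"]] = df["latitudinal_factor"]
        if np.any(np.isnan(lon)) or np.any(np.isnan(lat)):
            raise ValueError("distortion CSV does not cover the full tile grid")
        return cls(lon, lat, tile_size=tile_size)

    def to_csv(self, path) -> None:
        rows, cols = self.longitudinal.shape
        rr, cc = np.meshgrid(range(rows), range(cols), indexing="ij")
        pd.DataFrame(
            {
                "tile_row": rr.ravel(),
                "tile_col": cc.ravel(),
                "longitudinal_factor": self.longitudinal.ravel(),
                "latitudinal_factor": self.latitudinal.ravel(),
            }
        ).to_csv(path, index=False)


def correct_distortion(
    fields: VectorFieldSequence, grid: DistortionGrid
) -> VectorFieldSequence:
    """Correct 2D PIV vector lengths for cylinder-map distortion.

    Each node's component 0 (longitudinal) is multiplied by the
    longitudinal factor and component 1 (latitudinal) by the latitudinal
    factor of the tile containing the node (nearest-tile lookup, matching
    the tile sampling granularity).  Directions per component are
    preserved; the operation is exactly inverted by ``grid.reciprocal()``.
    """
    if fields.ndim != 2:
        raise ValueError("distortion correction applies to 2D fields")
    coords = fields.node_coordinates()  # (*grid, 2) pixel coordinates
    tiles = (coords // grid.tile_size).astype(int)
    rows, cols = grid.longitudinal.shape
    if (
        np.any(tiles[..., 0] < 0)
        or np.any(tiles[..., 0] >= rows)
        or np.any(tiles[..., 1] < 0)
        or np.any(tiles[..., 1] >= cols)
    ):
        raise ValueError("a PIV node lies outside the distortion grid")
    factors = np.stack(
        [
            grid.longitudinal[tiles[..., 0], tiles[..., 1]],
            grid.latitudinal[tiles[..., 0], tiles[..., 1]],
        ],
        axis=-1,
    )
    return replace(fields, vectors=fields.vectors * factors[None])


def extract_surface_mask(
    volume: np.ndarray,
    threshold: float,
    alpha: int = 3,
    shell_in: int = 6,
    shell_out: int = 3,
) -> np.ndarray:
    """Closed shell mask around the outer surface of a bright object.

    Foreground is ``volume >= threshold``; gaps up to roughly ``alpha``
    voxels are bridged by morphological closing at that scale, the
    interior is filled (removing anything inside the outer surface), and
    the result is a shell covering the boundary layer plus ``shell_in``
    voxel layers inward and ``shell_out`` outward (Euclidean distance).
    Only the largest connected shell component is kept.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D")
    fg = volume >= threshold
    if not np.any(fg):
        raise ValueError("empty foreground: no voxel reaches the threshold")
    if alpha > 0:
        pad = alpha + 1
        padded = np.pad(fg, pad)
        padded = ndimage.binary_closing(padded, structure=ball(alpha))
        fg = padded[pad:-pad, pad:-pad, pad:-pad]
    solid = ndimage.binary_fill_holes(fg)
    dist_in = ndimage.distance_transform_edt(solid)
    dist_out = ndimage.distance_transform_edt(~solid)
    shell = (solid & (dist_in <= shell_in + 1)) | (~solid & (dist_out <= shell_out))
    lab, n = ndimage.label(shell)
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        shell = lab == np.argmax(sizes)
    return shell


def combine_masks(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise union of surface masks from different time points,
    yielding one static mask for all frames."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = np.asarray(masks[0]).shape
    out = np.zeros(shape, dtype=bool)
    for m in masks:
        m = np.asarray(m).astype(bool)
        if m.shape != shape:
            raise ValueError("all masks must share a shape")
        out |= m
    return out
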