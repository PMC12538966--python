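"""Synthetic scenes with ground truth for every pipeline stage.

Three generators make the whole toolkit testable without microscopy data:

* :func:`make_wave_field` injects two-phase (V then D) displacement waves
  into a gridded vector field, with per-position ground-truth phase
  labels, optional background flow, and isotropic Gaussian vector noise.
* :func:`make_particle_sequence` renders nuclei-like Gaussian particle
  images advected by a prescribed displacement per frame, for end-to-end
  PIV checks.
* :func:`make_cylinder_distortion` produces the analytic length-distortion
  grid of a sphere-capped cylinder map: the equator is distortion-free,
  the longitudinal (pole-to-pole) correction factor grows toward the poles
  and the latitudinal factor shrinks, mirroring how a cylinder projection
  shortens meridian distances and elongates circumferential ones.

:func:`mini_scene` bundles the default demo conditions: a 100-frame
recording with five pre-rupture waves and one post-rupture wave whose D
direction is rotated, rupture after frame 80.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .cartography import DistortionGrid
from .piv import ImageSequence, VectorFieldSequence
from .segmentation import ReferenceField, WaveParams

__all__ = [
    "SyntheticWaveSpec",
    "SyntheticScene",
    "make_wave_field",
    "make_particle_sequence",
    "make_cylinder_distortion",
    "mini_scene",
    "mini_params",
    "mini_reference",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("direction must be non-zero")
    return v / n


@dataclass
class SyntheticWaveSpec:
    """Ground-truth description of one injected two-phase wave.

    The wave affects every grid cell of ``region`` (a boolean mask, or a
    disk given as ``center``/``radius``): ``v_duration`` frames moving at
    ``v_speed`` along ``v_direction`` starting at ``t_start``, immediately
    followed by ``d_duration`` frames along ``d_direction``.  With
    ``onset_ramp`` > 0 the first frames of each phase ramp linearly up to
    full speed.
    """

    t_start: int
    v_duration: int
    d_duration: int
    v_direction: tuple[float, ...]
    d_direction: tuple[float, ...]
    v_speed: float = 2.0
    d_speed: float = 1.5
    center: tuple[int, ...] | None = None
    radius: float | None = None
    region: np.ndarray | None = None
    onset_ramp: int = 0

    def __post_init__(self) -> None:
        if self.v_duration < 1 or self.d_duration < 1:
            raise ValueError("phase durations must be >= 1 frame")
        if self.v_speed <= 0 or self.d_speed <= 0:
            raise ValueError("phase speeds must be positive")
        if self.region is None and (self.center is None or self.radius is None):
            raise ValueError("specify a region mask or a disk (center, radius)")
        self.v_direction = tuple(_unit(self.v_direction))
        self.d_direction = tuple(_unit(self.d_direction))

    @property
    def t_end(self) -> int:
        """Last affected frame (inclusive)."""
        return self.t_start + self.v_duration + self.d_duration - 1

    def region_mask(self, grid_shape: tuple[int, ...]) -> np.ndarray:
        if self.region is not None:
            mask = np.asarray(self.region).astype(bool)
            if mask.shape != grid_shape:
                raise ValueError("region mask shape must match the grid")
            return mask
        axes = [np.arange(n) for n in grid_shape]
        coords = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        d2 = ((coords - np.asarray(self.center)) ** 2).sum(axis=-1)
        return d2 <= self.radius**2


@dataclass
class SyntheticScene:
    """Generated fields plus the exact truth used to create them."""

    fields: VectorFieldSequence
    truth_labels: np.ndarray
    specs: list[SyntheticWaveSpec]
    seed: int
    images: ImageSequence | None = None


def make_wave_field(
    shape: tuple[int, ...],
    specs: list[SyntheticWaveSpec],
    noise_sigma: float = 0.0,
    background_flow: tuple[float, ...] | None = None,
    seed: int = 0,
) -> SyntheticScene:
    """Vector-field sequence of shape (t, *grid) with injected waves.

    The field is the sum of the background flow, the per-spec phase
    vectors, and isotropic zero-mean Gaussian component noise of scale
    ``noise_sigma``; ``truth_labels`` (uint8, 0/1/2) mark exactly the
    spec'd (region x frame x phase) cells.  Specs overlapping in time at
    a shared position are an error.
    """
    n_frames, grid_shape = int(shape[0]), tuple(shape[1:])
    ndim = len(grid_shape)
    rng = np.random.default_rng(seed)
    vectors = np.zeros((n_frames,) + grid_shape + (ndim,), dtype=float)
    labels = np.zeros((n_frames,) + grid_shape, dtype=np.uint8)
    occupied = np.zeros((n_frames,) + grid_shape, dtype=bool)

    for spec in specs:
        mask = spec.region_mask(grid_shape)
        if spec.t_end >= n_frames or spec.t_start < 0:
            raise ValueError("wave spec exceeds the frame range")
        frames = slice(spec.t_start, spec.t_end + 1)
        if np.any(occupied[frames][:, mask]):
            raise ValueError("wave specs overlap in time at a shared position")
        occupied[frames][:, mask] = True
        for phase, direction, speed, duration, offset in (
            (1, spec.v_direction, spec.v_speed, spec.v_duration, 0),
            (2, spec.d_direction, spec.d_speed, spec.d_duration, spec.v_duration),
        ):
            vec = np.asarray(direction) * speed
            for i in range(duration):
                t = spec.t_start + offset + i
                ramp = 1.0
                if spec.onset_ramp > 0 and i < spec.onset_ramp:
                    ramp = (i + 1) / (spec.onset_ramp + 1)
                vectors[t][mask] += vec * ramp
                labels[t][mask] = phase

    if background_flow is not None:
        vectors += np.asarray(background_flow, dtype=float)
    if noise_sigma > 0:
        vectors += rng.normal(0.0, noise_sigma, size=vectors.shape)

    fields = VectorFieldSequence(
        vectors=vectors,
        validity=np.ones((n_frames,) + grid_shape, dtype=bool),
        grid_step=(1,) * ndim,
        grid_origin=(0,) * ndim,
    )
    return SyntheticScene(fields=fields, truth_labels=labels, specs=list(specs), seed=seed)


def make_particle_sequence(
    shape: tuple[int, ...],
    n_particles: int,
    displacement_field: np.ndarray,
    psf_sigma: float = 2.0,
    photon_noise: float = 0.0,
    seed: int = 0,
    amplitude: float = 100.0,
) -> ImageSequence:
    """Gaussian-spot particle images advected by a prescribed displacement.

    ``shape`` is (t, *spatial); ``displacement_field`` is either one
    D-vector applied every frame step or a (t-1, D) array of per-step
    uniform displacements.  No particles are created or destroyed;
    particles drifting outside the frame simply stop contributing signal.
    ``photon_noise`` adds Gaussian noise with a sqrt-intensity scale
    (Poisson-like), clipped at zero.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    n_frames, spatial = int(shape[0]), tuple(shape[1:])
    ndim = len(spatial)
    disp = np.asarray(displacement_field, dtype=float)
    if disp.ndim == 1:
        disp = np.tile(disp, (n_frames - 1, 1))
    if disp.shape != (n_frames - 1, ndim):
        raise ValueError("displacement_field must be (D,) or (t-1, D)")

    rng = np.random.default_rng(seed)
    positions = rng.uniform(0, 1, size=(n_particles, ndim)) * np.asarray(spatial)

    frames = np.empty((n_frames,) + spatial, dtype=float)
    for t in range(n_frames):
        img = np.zeros(spatial, dtype=float)
        for pos in positions:
            idx = np.floor(pos).astype(int)
            if np.any(idx < 0) or np.any(idx >= spatial):
                continue
            # nearest-cell splat; the PSF blur below spreads it sub-pixel-ly
            # via the fractional weights of a 2-cell bilinear kernel
            _splat(img, pos)
        img = gaussian_filter(img, psf_sigma) * amplitude
        if photon_noise > 0:
            img = img + rng.normal(0.0, 1.0, size=img.shape) * photon_noise * np.sqrt(
                np.maximum(img, 0.0)
            )
            img = np.maximum(img, 0.0)
        frames[t] = img
        if t < n_frames - 1:
            positions = positions + disp[t]
    return ImageSequence(data=frames)


def _splat(img: np.ndarray, pos: np.ndarray) -> None:
    """Bilinear deposit of unit mass at a fractional position."""
    base = np.floor(pos).astype(int)
    frac = pos - base
    for corner in np.ndindex(*(2,) * img.ndim):
        idx = base + np.asarray(corner)
        if np.any(idx < 0) or np.any(idx >= img.shape):
            continue
        w = np.prod(np.where(np.asarray(corner) == 1, frac, 1.0 - frac))
        img[tuple(idx)] += w


def make_cylinder_distortion(
    shape: tuple[int, int],
    cap_fraction: float = 0.25,
    tile_size: int = 10,
) -> DistortionGrid:
    """Analytic distortion grid of a sphere-capped cylinder projection.

    The map has ``shape`` = (height, width) pixels with axis 0 running
    pole to pole.  The central body (a true cylinder) is distortion-free:
    factors exactly (1, 1).  Each cap covers ``cap_fraction`` of the rows
    and samples the axial coordinate of a spherical cap uniformly; at
    polar angle phi from the cap-body junction the true/map length ratio
    is 1/cos(phi) along the meridian (longitudinal) and cos(phi) around
    the circumference (latitudinal), both monotone toward the pole and
    approaching 1 at the junction.
    """
    if not 0.0 < cap_fraction < 0.5:
        raise ValueError("cap_fraction must be in (0, 0.5)")
    height, width = shape
    n_rows = height // tile_size
    n_cols = width // tile_size
    if n_rows < 1 or n_cols < 1:
        raise ValueError("map smaller than one tile")
    cap_px = cap_fraction * height
    lon = np.ones((n_rows, n_cols), dtype=float)
    lat = np.ones((n_rows, n_cols), dtype=float)
    for i in range(n_rows):
        y = (i + 0.5) * tile_size  # tile-center row
        dist_to_pole = min(y, height - y)
        if dist_to_pole >= cap_px:
            continue  # cylindrical body: no distortion
        sin_phi = 1.0 - dist_to_pole / cap_px
        cos_phi = np.sqrt(max(1.0 - sin_phi**2, 1e-12))
        lon[i, :] = 1.0 / cos_phi
        lat[i, :] = cos_phi
    return DistortionGrid(longitudinal=lon, latitudinal=lat, tile_size=tile_size)


# -- demo scene -------------------------------------------------------------

#: grid and timing of the demo recording: 100 time steps on a 32 x 48 node
#: grid; rupture after frame 80 splits the epochs.
MINI_SHAPE = (100, 32, 48)
MINI_RUPTURE_FRAME = 80

_SQ2 = 1.0 / np.sqrt(2.0)
#: posteroventral V direction in (row, col) components: down-left.
MINI_V_DIR = (_SQ2, -_SQ2)
#: pre-rupture D direction: the exact reversal of V.
MINI_D_DIR_PRE = (-_SQ2, _SQ2)
#: post-rupture D direction: rotated to straight dorsal ("up"), 135 deg
#: from V instead of 180.
MINI_D_DIR_POST = (-1.0, 0.0)
MINI_DORSAL_AXIS = (-1.0, 0.0)


def mini_scene(seed: int = 0, noise_sigma: float = 0.2) -> SyntheticScene:
    """The default demo scene: five pre-rupture waves and one after.

    Waves recur every 14 frames with a 4-frame V phase at 2.0 units/frame
    and a 6-frame D phase at 1.5 units/frame over disk-shaped regions
    (radius 9 nodes) that drift slowly along the embryo axis; the
    post-rupture wave starts at frame 86 with its D direction rotated
    from the full reversal to straight dorsal.
    """
    specs = []
    for k in range(5):
        specs.append(
            SyntheticWaveSpec(
                t_start=8 + 14 * k,
                v_duration=4,
                d_duration=6,
                v_direction=MINI_V_DIR,
                d_direction=MINI_D_DIR_PRE,
                v_speed=2.0,
                d_speed=1.5,
                center=(16, 12 + 4 * k),
                radius=9.0,
            )
        )
    specs.append(
        SyntheticWaveSpec(
            t_start=86,
            v_duration=4,
            d_duration=6,
            v_direction=MINI_V_DIR,
            d_direction=MINI_D_DIR_POST,
            v_speed=2.0,
            d_speed=1.5,
            center=(16, 24),
            radius=9.0,
        )
    )
    return make_wave_field(MINI_SHAPE, specs, noise_sigma=noise_sigma, seed=seed)


def mini_params() -> WaveParams:
    """Segmentation thresholds matching the demo scene's lateral geometry."""
    return WaveParams(dorsal_axis=np.asarray(MINI_DORSAL_AXIS))


def mini_reference() -> ReferenceField:
    """Constant reference field along the demo V direction."""
    return ReferenceField.constant(MINI_V_DIR, MINI_SHAPE[1:])
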