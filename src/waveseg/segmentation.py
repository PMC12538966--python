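"""Temporal segmentation of two-phase contraction waves in vector time series.

A contraction wave consists of two consecutive phases of coherent tissue
motion: a V phase moving roughly along an a-priori reference direction r
(posteroventral in the motivating system), followed by a D phase moving in
a clearly different direction with a dorsal component.  At each grid
position of a PIV vector field the algorithm

1. computes a sliding-window direction-similarity signal
   rho(t) = mean over [t-N, t+N] of v_hat(t') . r,
2. pairs each strict local maximum of rho with the next local minimum,
3. tests the pair against angle gates (alignment with r at t_max,
   V/D separation at t_min, optional dorsal half-plane),
4. grows contiguous V and D phase segmentations outward from t_max and
   t_min frame by frame, gated by direction coherence with the running
   phase average and a minimum speed,
5. assigns any small interface gap between the phases, and
6. accepts the wave only if the V phase is fast enough on average and the
   total displacement over both phases is large enough.

All angle thresholds are in degrees and compared through cosines: an
alignment gate reads ``dot > cos(theta)``, a separation gate
``dot < cos(theta_VD)``.  Speed gates are in displacement units per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .piv import VectorFieldSequence

__all__ = [
    "WaveParams",
    "ReferenceField",
    "WaveRecord",
    "direction_similarity",
    "find_candidate_pairs",
    "check_candidate",
    "expand_phase",
    "assign_interface",
    "filter_wave",
    "segment_position",
    "segment_field",
]


@dataclass
class WaveParams:
    """Thresholds of the wave segmentation algorithm.

    theta_r : allowable angular deviation (deg) of the vector at t_max
        around the reference direction.
    theta_V, theta_D : intra-phase coherence angles (deg) used while
        expanding the V and D segmentations.
    theta_VD : minimum angle (deg) between the V and D representative
        vectors.
    M_min : per-frame speed gate during phase expansion.
    M_avg : minimum mean speed of the V phase.
    M_total : minimum total displacement (sum of magnitudes) over V and D.
    window_N : sliding-window half-width (frames) of rho(t).
    max_gap : largest tolerated V/D interface gap (frames).
    enforce_dorsal_halfplane : if on (and ``dorsal_axis`` given), the D
        representative vector must have a positive component along the
        dorsal axis, i.e. lie within (-90 deg, 90 deg) of it.
    """

    theta_r: float = 40.0
    theta_V: float = 60.0
    theta_D: float = 60.0
    theta_VD: float = 30.0
    M_min: float = 0.5
    M_avg: float = 1.0
    M_total: float = 10.0
    window_N: int = 2
    max_gap: int = 2
    enforce_dorsal_halfplane: bool = True
    dorsal_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("theta_r", "theta_V", "theta_D", "theta_VD"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"{name} must be in (0, 180) degrees")
        for name in ("M_min", "M_avg", "M_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.window_N < 1:
            raise ValueError("window_N must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.dorsal_axis is not None:
            self.dorsal_axis = _unit(np.asarray(self.dorsal_axis, dtype=float))


@dataclass
class ReferenceField:
    """Per-position unit reference vectors r_p, shape (*grid, D)."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("reference vectors must be unit-norm")

    @classmethod
    def constant(cls, r: Iterable[float], grid_shape: tuple[int, ...]) -> "ReferenceField":
        r = _unit(np.asarray(tuple(r), dtype=float))
        return cls(np.broadcast_to(r, grid_shape + (r.size,)).copy())

    @classmethod
    def split_columns(
        cls,
        r_left: Iterable[float],
        r_right: Iterable[float],
        split_col: int,
        grid_shape: tuple[int, ...],
    ) -> "ReferenceField":
        """Two mirrored references, e.g. the two lateral sides of a
        cylinder projection, split at a grid column (last axis)."""
        left = _unit(np.asarray(tuple(r_left), dtype=float))
        right = _unit(np.asarray(tuple(r_right), dtype=float))
        out = np.empty(grid_shape + (left.size,), dtype=float)
        out[..., :split_col, :] = left
        out[..., split_col:, :] = right
        return cls(out)


@dataclass
class WaveRecord:
    """One segmented wave at one grid position.

    Frame intervals are inclusive [start, stop] pairs; after interface
    assignment V and D are adjacent and disjoint.
    """

    position: tuple[int, ...] | None
    v_frames: tuple[int, int]
    d_frames: tuple[int, int]
    t_max: int
    t_min: int
    v_avg_vector: np.ndarray
    d_avg_vector: np.ndarray
    mean_speed_v: float
    total_displacement: float

    @property
    def v_duration(self) -> int:
        return self.v_frames[1] - self.v_frames[0] + 1

    @property
    def d_duration(self) -> int:
        return self.d_frames[1] - self.d_frames[0] + 1


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def _unit_rows(series: np.ndarray) -> np.ndarray:
    """Row-wise unit vectors; zero rows stay zero."""
    norms = np.linalg.norm(series, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, series / np.where(norms > 0, norms, 1.0), 0.0)
    return out


def direction_similarity(series: np.ndarray, r: np.ndarray, window_N: int) -> np.ndarray:
    """Sliding-window direction similarity rho(t).

    ``series`` is (T, D).  Each frame contributes the dot product of its
    unit vector with r (zero vectors contribute a zero summand, pulling
    quiescent windows toward zero rather than being undefined); rho(t) is
    the mean over the window [t-N, t+N] clipped to the series bounds.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] == 0:
        raise ValueError("series must be a non-empty (T, D) array")
    if window_N < 1:
        raise ValueError("window_N must be >= 1")
    r = np.asarray(r, dtype=float)
    dots = _unit_rows(series) @ r
    T = dots.shape[0]
    csum = np.concatenate(([0.0], np.cumsum(dots)))
    t = np.arange(T)
    lo = np.maximum(t - window_N, 0)
    hi = np.minimum(t + window_N, T - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def find_candidate_pairs(rho: np.ndarray) -> list[tuple[int, int]]:
    """Pair strict local maxima of rho with the next local minimum.

    Plateaus resolve to their first frame; series endpoints are never
    extrema; a maximum without a following minimum (and any leading
    minimum) is dropped.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 1 or rho.shape[0] < 3:
        raise ValueError("rho must be 1D with length >= 3")
    extrema: list[tuple[int, str]] = []
    prev_dir = 0
    plateau_start = 0
    for i in range(rho.shape[0] - 1):
        d = rho[i + 1] - rho[i]
        if d == 0:
            continue
        cur = 1 if d > 0 else -1
        if prev_dir > 0 and cur < 0:
            extrema.append((plateau_start, "max"))
        elif prev_dir < 0 and cur > 0:
            extrema.append((plateau_start, "min"))
        prev_dir = cur
        plateau_start = i + 1
    pairs: list[tuple[int, int]] = []
    pending_max: int | None = None
    for t, kind in extrema:
        if kind == "max":
            pending_max = t
        elif pending_max is not None:
            pairs.append((pending_max, t))
            pending_max = None
    return pairs


def check_candidate(
    series: np.ndarray,
    t_max: int,
    t_min: int,
    r: np.ndarray,
    params: WaveParams,
) -> tuple[bool, str]:
    """Angle gates on a (t_max, t_min) candidate pair.

    Accepts iff the unit vector at t_max lies within theta_r of r, the
    unit vectors at t_max and t_min are separated by more than theta_VD,
    and (optionally) the t_min vector points into the dorsal half-plane.
    Zero vectors at either frame reject the candidate.
    """
    series = np.asarray(series, dtype=float)
    T = series.shape[0]
    if not (0 <= t_max < T and 0 <= t_min < T):
        raise IndexError("t_max/t_min out of range")
    v_max = series[t_max]
    v_min = series[t_min]
    if np.linalg.norm(v_max) == 0 or np.linalg.norm(v_min) == 0:
        return False, "zero vector at candidate frame"
    v_max = _unit(v_max)
    v_min = _unit(v_min)
    if not v_max @ np.asarray(r, dtype=float) > np.cos(np.radians(params.theta_r)):
        return False, "t_max vector outside theta_r of reference"
    if not v_max @ v_min < np.cos(np.radians(params.theta_VD)):
        return False, "V/D separation below theta_VD"
    if params.enforce_dorsal_halfplane and params.dorsal_axis is not None:
        if not v_min @ params.dorsal_axis > 0:
            return False, "t_min vector outside dorsal half-plane"
    return True, "accepted"


def expand_phase(
    series: np.ndarray,
    seed_t: int,
    theta_phase: float,
    M_min: float,
    bounds: tuple[int, int],
) -> tuple[int, int]:
    """Grow a contiguous phase segmentation outward from ``seed_t``.

    Unvisited frames are tested from nearest to farthest, alternating
    sides (the later frame first at equal distance).  A frame joins iff
    its unit vector has dot product > cos(theta_phase) with the unit mean
    of the vectors already in the set AND its magnitude exceeds M_min.
    Each side closes at its first failing frame or at ``bounds``
    (inclusive).  Returns the inclusive frame interval.
    """
    series = np.asarray(series, dtype=float)
    lo, hi = int(bounds[0]), int(bounds[1])
    if not lo <= seed_t <= hi:
        raise ValueError("seed_t outside bounds")
    if np.linalg.norm(series[seed_t]) == 0:
        raise ValueError("zero vector at seed frame")
    cos_th = np.cos(np.radians(theta_phase))
    vec_sum = series[seed_t].copy()
    start = stop = seed_t
    fwd_open = stop < hi
    bwd_open = start > lo

    def admits(t: int) -> bool:
        v = series[t]
        mag = np.linalg.norm(v)
        if not mag > M_min:
            return False
        norm_sum = np.linalg.norm(vec_sum)
        if norm_sum == 0:
            return False
        return (v / mag) @ (vec_sum / norm_sum) > cos_th

    while fwd_open or bwd_open:
        if fwd_open:
            t = stop + 1
            if admits(t):
                stop = t
                vec_sum += series[t]
                fwd_open = stop < hi
            else:
                fwd_open = False
        if bwd_open:
            t = start - 1
            if admits(t):
                start = t
                vec_sum += series[t]
                bwd_open = start > lo
            else:
                bwd_open = False
    return start, stop


def assign_interface(
    series: np.ndarray,
    v_frames: tuple[int, int],
    d_frames: tuple[int, int],
    max_gap: int = 2,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Attach interface-gap frames between the V and D segmentations.

    With gap g = min(D) - max(V) - 1: g = 0 leaves both unchanged,
    g > max_gap rejects the candidate wave (returns None).  Otherwise the
    gap is split so every frame joins the phase whose average direction it
    matches best (contiguity is kept by choosing the split point with the
    largest summed normalized dot products; ties go to V).
    """
    series = np.asarray(series, dtype=float)
    (v0, v1), (d0, d1) = v_frames, d_frames
    if v1 >= d0:
        raise ValueError("V and D segmentations overlap")
    gap = d0 - v1 - 1
    if gap == 0:
        return (v0, v1), (d0, d1)
    if gap > max_gap:
        return None
    v_avg = series[v0 : v1 + 1].mean(axis=0)
    d_avg = series[d0 : d1 + 1].mean(axis=0)
    v_hat = v_avg / np.linalg.norm(v_avg) if np.linalg.norm(v_avg) else v_avg
    d_hat = d_avg / np.linalg.norm(d_avg) if np.linalg.norm(d_avg) else d_avg
    gap_hats = _unit_rows(series[v1 + 1 : d0])
    to_v = gap_hats @ v_hat
    to_d = gap_hats @ d_hat
    # split s = number of gap frames joining V; score ties resolve to the
    # larger split so an equidistant frame joins V
    best_s, best_score = gap, -np.inf
    for s in range(gap + 1):
        score = to_v[:s].sum() + to_d[s:].sum()
        if score > best_score or (score == best_score and s > best_s):
            best_score, best_s = score, s
    return (v0, v1 + best_s), (v1 + best_s + 1, d1)


def filter_wave(record: WaveRecord, params: WaveParams) -> bool:
    """Speed-based acceptance: mean V speed >= M_avg and the summed
    magnitude over both phases >= M_total."""
    return (
        record.mean_speed_v >= params.M_avg
        and record.total_displacement >= params.M_total
    )


def segment_position(
    series: np.ndarray,
    r: np.ndarray,
    params: WaveParams,
    position: tuple[int, ...] | None = None,
) -> list[WaveRecord]:
    """Full temporal segmentation of one vector time series.

    Candidate (t_max, t_min) pairs are processed in temporal order; each
    accepted wave claims its frames, and later expansions cannot cross
    claimed frames (nor can V cross t_min or D cross the V phase).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2 * params.window_N + 1:
        raise ValueError("series shorter than the sliding window")
    r = _unit(np.asarray(r, dtype=float))
    T = series.shape[0]
    rho = direction_similarity(series, r, params.window_N)
    claimed = np.zeros(T, dtype=bool)
    records: list[WaveRecord] = []

    for t_max, t_min in find_candidate_pairs(rho):
        if claimed[t_max] or claimed[t_min]:
            continue
        ok, _reason = check_candidate(series, t_max, t_min, r, params)
        if not ok:
            continue
        before = np.flatnonzero(claimed[:t_max])
        v_lo = int(before[-1]) + 1 if before.size else 0
        v_bounds = (v_lo, t_min - 1)
        v_frames = expand_phase(series, t_max, params.theta_V, params.M_min, v_bounds)
        after = np.flatnonzero(claimed[t_min + 1 :])
        d_hi = t_min + 1 + int(after[0]) - 1 if after.size else T - 1
        d_bounds = (v_frames[1] + 1, d_hi)
        if np.linalg.norm(series[t_min]) == 0:
            continue
        d_frames = expand_phase(series, t_min, params.theta_D, params.M_min, d_bounds)
        joined = assign_interface(series, v_frames, d_frames, params.max_gap)
        if joined is None:
            continue
        v_frames, d_frames = joined
        v_slice = series[v_frames[0] : v_frames[1] + 1]
        d_slice = series[d_frames[0] : d_frames[1] + 1]
        v_mags = np.linalg.norm(v_slice, axis=-1)
        d_mags = np.linalg.norm(d_slice, axis=-1)
        record = WaveRecord(
            position=position,
            v_frames=v_frames,
            d_frames=d_frames,
            t_max=t_max,
            t_min=t_min,
            v_avg_vector=v_slice.mean(axis=0),
            d_avg_vector=d_slice.mean(axis=0),
            mean_speed_v=float(v_mags.mean()),
            total_displacement=float(v_mags.sum() + d_mags.sum()),
        )
        if not filter_wave(record, params):
            continue
        claimed[v_frames[0] : d_frames[1] + 1] = True
        records.append(record)
    return records


def segment_field(
    fields: VectorFieldSequence,
    refs: ReferenceField,
    params: WaveParams,
) -> tuple[list[WaveRecord], np.ndarray]:
    """Apply ``segment_position`` independently at every grid node.

    Returns the flat list of wave records and a rasterized label map of
    shape (t, *grid) with 0 = none, 1 = V, 2 = D.  Frames flagged invalid
    in the field are treated as zero vectors.
    """
    if refs.vectors.shape != fields.grid_shape + (fields.ndim,):
        raise ValueError("reference field shape must match the vector grid")
    T = fields.n_steps
    labels = np.zeros((T,) + fields.grid_shape, dtype=np.uint8)
    records: list[WaveRecord] = []
    vectors = np.where(fields.validity[..., None], fields.vectors, 0.0)
    for node in np.ndindex(*fields.grid_shape):
        series = vectors[(slice(None),) + node]
        if not np.any(series):
            continue
        for rec in segment_position(series, refs.vectors[node], params, position=node):
            records.append(rec)
            idx = (slice(rec.v_frames[0], rec.v_frames[1] + 1),) + node
            labels[idx] = 1
            idx = (slice(rec.d_frames[0], rec.d_frames[1] + 1),) + node
            labels[idx] = 2
    return records, labels
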