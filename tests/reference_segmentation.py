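"""Plain-loop reference implementation of the wave segmentation rules.

Used only as an independent oracle in tests: every step is written as an
explicit scan over frames, with no shared code or vectorization from the
package implementation.
"""

from __future__ import annotations

import math


def _norm(v):
    return math.sqrt(sum(c * c for c in v))


def _hat(v):
    n = _norm(v)
    if n == 0:
        return [0.0] * len(v)
    return [c / n for c in v]


def _dot(u, v):
    return sum(a * b for a, b in zip(u, v))


def ref_rho(series, r, window_n):
    out = []
    T = len(series)
    for t in range(T):
        lo = max(0, t - window_n)
        hi = min(T - 1, t + window_n)
        total = 0.0
        for tt in range(lo, hi + 1):
            total += _dot(_hat(series[tt]), r)
        out.append(total / (hi - lo + 1))
    return out


def ref_extrema(rho):
    """Strict local extrema, plateau resolved to its first frame."""
    T = len(rho)
    out = []
    for t in range(1, T - 1):
        if rho[t] == rho[t - 1]:
            continue  # not the first frame of its plateau
        left = rho[t - 1]
        # first differing value to the right
        j = t + 1
        while j < T and rho[j] == rho[t]:
            j += 1
        if j == T:
            continue  # plateau runs to the end: not an extremum
        right = rho[j]
        if left < rho[t] and right < rho[t]:
            out.append((t, "max"))
        elif left > rho[t] and right > rho[t]:
            out.append((t, "min"))
    return out


def ref_pairs(rho):
    pairs = []
    pending = None
    for t, kind in ref_extrema(rho):
        if kind == "max":
            pending = t
        elif pending is not None:
            pairs.append((pending, t))
            pending = None
    return pairs


def ref_expand(series, seed_t, theta_deg, m_min, lo, hi):
    cos_th = math.cos(math.radians(theta_deg))
    frames = [seed_t]
    total = list(series[seed_t])

    def ok(t):
        v = series[t]
        mag = _norm(v)
        if not mag > m_min:
            return False
        if _norm(total) == 0:
            return False
        return _dot(_hat(v), _hat(total)) > cos_th

    fwd, bwd = seed_t + 1, seed_t - 1
    fwd_open, bwd_open = fwd <= hi, bwd >= lo
    while fwd_open or bwd_open:
        if fwd_open:
            if ok(fwd):
                frames.append(fwd)
                for i, c in enumerate(series[fwd]):
                    total[i] += c
                fwd += 1
                fwd_open = fwd <= hi
            else:
                fwd_open = False
        if bwd_open:
            if ok(bwd):
                frames.append(bwd)
                for i, c in enumerate(series[bwd]):
                    total[i] += c
                bwd -= 1
                bwd_open = bwd >= lo
            else:
                bwd_open = False
    return min(frames), max(frames)


def ref_segment_position(series, r, params):
    """Accepted waves as (v_start, v_stop, d_start, d_stop) tuples."""
    T = len(series)
    r = _hat(r)
    rho = ref_rho(series, r, params.window_N)
    cos_r = math.cos(math.radians(params.theta_r))
    cos_vd = math.cos(math.radians(params.theta_VD))
    claimed = [False] * T
    waves = []
    for t_max, t_min in ref_pairs(rho):
        if claimed[t_max] or claimed[t_min]:
            continue
        v_max, v_min = series[t_max], series[t_min]
        if _norm(v_max) == 0 or _norm(v_min) == 0:
            continue
        if not _dot(_hat(v_max), r) > cos_r:
            continue
        if not _dot(_hat(v_max), _hat(v_min)) < cos_vd:
            continue
        if params.enforce_dorsal_halfplane and params.dorsal_axis is not None:
            if not _dot(_hat(v_min), list(params.dorsal_axis)) > 0:
                continue
        v_lo = 0
        for t in range(t_max - 1, -1, -1):
            if claimed[t]:
                v_lo = t + 1
                break
        v0, v1 = ref_expand(series, t_max, params.theta_V, params.M_min, v_lo, t_min - 1)
        d_hi = T - 1
        for t in range(t_min + 1, T):
            if claimed[t]:
                d_hi = t - 1
                break
        d0, d1 = ref_expand(series, t_min, params.theta_D, params.M_min, v1 + 1, d_hi)
        gap = d0 - v1 - 1
        if gap > params.max_gap:
            continue
        if gap > 0:
            v_avg = _hat([sum(series[t][i] for t in range(v0, v1 + 1)) for i in range(len(r))])
            d_avg = _hat([sum(series[t][i] for t in range(d0, d1 + 1)) for i in range(len(r))])
            best_s, best_score = gap, None
            for s in range(gap + 1):
                score = 0.0
                for j, t in enumerate(range(v1 + 1, d0)):
                    h = _hat(series[t])
                    score += _dot(h, v_avg) if j < s else _dot(h, d_avg)
                if best_score is None or score > best_score or (score == best_score and s > best_s):
                    best_score, best_s = score, s
            v1 = v1 + best_s
            d0 = v1 + 1
        v_mags = [_norm(series[t]) for t in range(v0, v1 + 1)]
        all_mags = v_mags + [_norm(series[t]) for t in range(d0, d1 + 1)]
        if not sum(v_mags) / len(v_mags) >= params.M_avg:
            continue
        if not sum(all_mags) >= params.M_total:
            continue
        for t in range(v0, d1 + 1):
            claimed[t] = True
        waves.append((v0, v1, d0, d1))
    return waves
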