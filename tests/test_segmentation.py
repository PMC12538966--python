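import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from waveseg.piv import VectorFieldSequence
from waveseg.segmentation import (
    ReferenceField,
    WaveParams,
    assign_interface,
    check_candidate,
    direction_similarity,
    expand_phase,
    filter_wave,
    find_candidate_pairs,
    segment_field,
    segment_position,
)
from conftest import R_LATERAL, canonical_series
from reference_segmentation import ref_segment_position

R = R_LATERAL


def random_alphabet_series(rng, length):
    """Vectors from 8 directions x a few magnitudes (incl. zero)."""
    angles = rng.integers(0, 8, size=length) * (np.pi / 4)
    mags = rng.choice([0.0, 0.3, 0.8, 1.6, 2.6], size=length)
    return np.stack([mags * np.cos(angles), mags * np.sin(angles)], axis=-1)


class TestDirectionSimilarity:
    def test_perfect_alignment_gives_one(self):
        series = np.tile(3.7 * R, (9, 1))
        assert np.allclose(direction_similarity(series, R, 2), 1.0)

    def test_antialignment_gives_minus_one(self):
        series = np.tile(-0.2 * R, (9, 1))
        assert np.allclose(direction_similarity(series, R, 2), -1.0)

    def test_three_term_mean_hand_value(self):
        series = np.stack([R, -R, R])
        rho = direction_similarity(series, R, 1)
        assert rho[1] == pytest.approx(1.0 / 3.0)

    def test_zero_vectors_contribute_zero_summand(self):
        series = np.zeros((7, 2))
        series[3] = 5.0 * R
        rho = direction_similarity(series, R, 1)
        assert rho[3] == pytest.approx(1.0 / 3.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 4))
    def test_bounded_and_magnitude_invariant(self, seed, n):
        rng = np.random.default_rng(seed)
        series = rng.normal(size=(15, 2)) * rng.uniform(0.1, 9.0, size=(15, 1))
        rho = direction_similarity(series, R, n)
        assert np.all(rho >= -1.0 - 1e-12) and np.all(rho <= 1.0 + 1e-12)
        scaled = series * rng.uniform(0.5, 4.0, size=(15, 1))
        assert np.allclose(rho, direction_similarity(scaled, R, n))

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            direction_similarity(np.empty((0, 2)), R, 1)


class TestFindCandidatePairs:
    def test_monotone_series_has_no_pairs(self):
        assert find_candidate_pairs(np.linspace(-1, 1, 8)) == []

    def test_single_bump_and_dip(self):
        assert find_candidate_pairs(np.array([0.0, 1.0, 0.0, -1.0, 0.0])) == [(1, 3)]

    def test_two_bumps_two_pairs_in_order(self):
        rho = np.array([0.0, 0.8, 0.1, -0.7, 0.0, 0.9, 0.2, -0.5, 0.1])
        assert find_candidate_pairs(rho) == [(1, 3), (5, 7)]

    def test_plateau_resolves_to_first_frame(self):
        rho = np.array([0.0, 0.5, 0.5, 0.5, 0.0, -0.5, -0.5, 0.0])
        assert find_candidate_pairs(rho) == [(1, 5)]

    def test_leading_minimum_and_trailing_maximum_dropped(self):
        rho = np.array([0.5, -0.5, 0.0, 0.7, 0.6, 0.9, 0.1])
        # min at 1 has no preceding max; max at 3 pairs with min at 4
        assert find_candidate_pairs(rho) == [(3, 4)]

    def test_matches_bruteforce_extrema_scan(self, rng):
        from reference_segmentation import ref_pairs

        for _ in range(200):
            rho = rng.choice([-1.0, -0.5, 0.0, 0.5, 1.0], size=rng.integers(3, 15))
            assert find_candidate_pairs(rho) == ref_pairs(list(rho))


class TestCheckCandidate:
    def test_opposite_vectors_accepted_with_lateral_thresholds(self, lateral_params):
        series = np.stack([2.0 * R, -2.0 * R])
        ok, reason = check_candidate(series, 0, 1, R, lateral_params)
        assert ok, reason

    def test_reference_deviation_beyond_theta_r_rejected(self, lateral_params):
        c, s = np.cos(np.radians(50)), np.sin(np.radians(50))
        rot = np.array([[c, -s], [s, c]])
        series = np.stack([rot @ R, -R])
        ok, reason = check_candidate(series, 0, 1, R, lateral_params)
        assert not ok and "theta_r" in reason

    def test_small_vd_separation_rejected(self, lateral_params):
        c, s = np.cos(np.radians(10)), np.sin(np.radians(10))
        rot = np.array([[c, -s], [s, c]])
        series = np.stack([R, rot @ R])
        ok, reason = check_candidate(series, 0, 1, R, lateral_params)
        assert not ok and "theta_VD" in reason

    def test_dorsal_halfplane_gate(self, lateral_params):
        # D vector separated 45 deg from R but pointing ventrally
        # (negative component along the dorsal axis)
        d_vec = np.array([0.0, -1.0])
        assert d_vec @ lateral_params.dorsal_axis < 0
        series = np.stack([R, d_vec])
        ok, reason = check_candidate(series, 0, 1, R, lateral_params)
        assert not ok and "dorsal" in reason
        relaxed = WaveParams(dorsal_axis=None)
        ok, _ = check_candidate(series, 0, 1, R, relaxed)
        assert ok

    def test_zero_vector_rejected_and_bad_index_raises(self, lateral_params):
        series = np.stack([R, np.zeros(2)])
        ok, reason = check_candidate(series, 0, 1, R, lateral_params)
        assert not ok and "zero" in reason
        with pytest.raises(IndexError):
            check_candidate(series, 0, 5, R, lateral_params)


class TestExpandPhase:
    def test_uniform_series_fills_bounds(self):
        series = np.tile(2.0 * R, (10, 1))
        assert expand_phase(series, 4, 60.0, 0.5, (0, 9)) == (0, 9)

    def test_magnitude_gate_blocks_neighbours(self):
        series = np.tile(0.3 * R, (9, 1))
        series[4] = 2.0 * R
        assert expand_phase(series, 4, 60.0, 0.5, (0, 8)) == (4, 4)

    def test_rotating_vectors_stop_at_coherence_limit(self):
        # 15 deg per frame; the running mean lags, so the set grows until the
        # next vector deviates > 40 deg from the current average
        step = np.radians(15.0)
        series = np.stack(
            [2.0 * np.array([np.cos(k * step), np.sin(k * step)]) for k in range(12)]
        )
        got = expand_phase(series, 0, 40.0, 0.5, (0, 11))
        # independent step-by-step simulation of the update rule
        total = series[0].copy()
        stop = 0
        for t in range(1, 12):
            avg = total / np.linalg.norm(total)
            v = series[t] / np.linalg.norm(series[t])
            if v @ avg > np.cos(np.radians(40.0)):
                stop = t
                total += series[t]
            else:
                break
        assert got == (0, stop)
        assert 0 < stop < 11

    def test_zero_seed_raises(self):
        with pytest.raises(ValueError):
            expand_phase(np.zeros((5, 2)), 2, 60.0, 0.5, (0, 4))


class TestAssignInterface:
    def _sets(self, series, v, d, max_gap=2):
        return assign_interface(series, v, d, max_gap)

    def test_zero_gap_unchanged(self):
        series = np.tile(R, (10, 1))
        assert self._sets(series, (0, 4), (5, 9)) == ((0, 4), (5, 9))

    def test_gap_frame_joins_closer_phase(self):
        series = np.zeros((7, 2))
        series[0:3] = 2.0 * R
        series[4:7] = -2.0 * R
        c, s = np.cos(np.radians(5)), np.sin(np.radians(5))
        series[3] = np.array([[c, -s], [s, c]]) @ R  # 5 deg from V, 175 from D
        assert self._sets(series, (0, 2), (4, 6)) == ((0, 3), (4, 6))

    def test_equidistant_gap_frame_joins_v(self):
        series = np.zeros((7, 2))
        series[0:3] = [2.0, 0.0]
        series[4:7] = [-2.0, 0.0]
        series[3] = [0.0, 1.0]  # exactly orthogonal to both averages
        assert self._sets(series, (0, 2), (4, 6)) == ((0, 3), (4, 6))

    def test_gap_beyond_max_gap_rejects_wave(self):
        series = np.tile(R, (12, 1))
        assert self._sets(series, (0, 2), (6, 9), max_gap=2) is None

    def test_overlapping_sets_raise(self):
        series = np.tile(R, (8, 1))
        with pytest.raises(ValueError):
            assign_interface(series, (0, 4), (4, 7))


class TestFilterWave:
    def _record(self, mean_speed_v, total):
        from waveseg.segmentation import WaveRecord

        return WaveRecord(None, (0, 2), (3, 5), 1, 4, R, -R, mean_speed_v, total)

    def test_slow_v_phase_rejected(self, lateral_params):
        assert not filter_wave(self._record(0.8, 20.0), lateral_params)

    def test_total_displacement_boundary(self, lateral_params):
        assert filter_wave(self._record(2.0, 10.5), lateral_params)
        assert not filter_wave(self._record(2.0, 9.9), lateral_params)


class TestSegmentPosition:
    def test_all_zero_series_yields_nothing(self, lateral_params):
        assert segment_position(np.zeros((20, 2)), R, lateral_params) == []

    def test_canonical_two_phase_wave(self, lateral_params):
        records = segment_position(canonical_series(), R, lateral_params)
        assert len(records) == 1
        rec = records[0]
        assert rec.v_frames == (10, 14)
        assert rec.d_frames == (15, 19)
        assert rec.t_max in range(10, 15) and rec.t_min in range(15, 20)

    def test_five_repetitions_give_five_waves(self, lateral_params):
        block = canonical_series(length=20, t_v=5)
        series = np.concatenate([block] * 5)
        records = segment_position(series, R, lateral_params)
        assert len(records) == 5
        starts = [r.v_frames[0] for r in records]
        assert starts == [5, 25, 45, 65, 85]

    def test_too_short_series_raises(self, lateral_params):
        with pytest.raises(ValueError):
            segment_position(np.zeros((3, 2)), R, lateral_params)

    def test_matches_bruteforce_oracle_on_random_series(self, rng, lateral_params):
        relaxed = WaveParams(
            M_avg=0.8, M_total=4.0, dorsal_axis=lateral_params.dorsal_axis
        )
        for params in (lateral_params, relaxed):
            for _ in range(150):
                series = random_alphabet_series(rng, int(rng.integers(5, 13)))
                got = [
                    (r.v_frames[0], r.v_frames[1], r.d_frames[0], r.d_frames[1])
                    for r in segment_position(series, R, params)
                ]
                assert got == ref_segment_position([list(v) for v in series], list(R), params)

    def test_enlarging_theta_r_never_loses_waves(self, rng):
        base = dict(M_avg=0.8, M_total=4.0, dorsal_axis=None, enforce_dorsal_halfplane=False)
        for _ in range(40):
            series = random_alphabet_series(rng, 12)
            n_narrow = len(segment_position(series, R, WaveParams(theta_r=25.0, **base)))
            n_wide = len(segment_position(series, R, WaveParams(theta_r=70.0, **base)))
            assert n_wide >= n_narrow

    def test_raising_m_avg_never_adds_waves(self, rng):
        base = dict(M_total=4.0, dorsal_axis=None, enforce_dorsal_halfplane=False)
        for _ in range(40):
            series = random_alphabet_series(rng, 12)
            n_low = len(segment_position(series, R, WaveParams(M_avg=0.5, **base)))
            n_high = len(segment_position(series, R, WaveParams(M_avg=1.5, **base)))
            assert n_high <= n_low

    def test_equivariant_under_global_rotation(self, rng, lateral_params):
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated_params = WaveParams(dorsal_axis=rot @ lateral_params.dorsal_axis)
        for _ in range(30):
            series = random_alphabet_series(rng, 12)
            a = segment_position(series, R, lateral_params)
            b = segment_position(series @ rot.T, rot @ R, rotated_params)
            assert [(r.v_frames, r.d_frames) for r in a] == [
                (r.v_frames, r.d_frames) for r in b
            ]


class TestSegmentField:
    def _fields(self, vectors, validity=None):
        vectors = np.asarray(vectors, dtype=float)
        if validity is None:
            validity = np.ones(vectors.shape[:-1], dtype=bool)
        return VectorFieldSequence(vectors, validity, (1, 1), (0, 0))

    def test_uniform_field_gives_uniform_label_blocks(self, lateral_params):
        series = canonical_series()
        vectors = np.tile(series[:, None, None, :], (1, 4, 5, 1))
        refs = ReferenceField.constant(R, (4, 5))
        records, labels = segment_field(self._fields(vectors), refs, lateral_params)
        assert len(records) == 20
        assert np.all(labels[10:15] == 1)
        assert np.all(labels[15:20] == 2)
        assert np.all(labels[:10] == 0) and np.all(labels[20:] == 0)

    def test_wave_in_disk_stays_in_disk(self, lateral_params):
        series = canonical_series()
        vectors = np.zeros((30, 10, 10, 2))
        yy, xx = np.mgrid[:10, :10]
        disk = (yy - 5) ** 2 + (xx - 5) ** 2 <= 9
        vectors[:, disk, :] = series[:, None, :]
        refs = ReferenceField.constant(R, (10, 10))
        _, labels = segment_field(self._fields(vectors), refs, lateral_params)
        assert np.array_equal(np.any(labels > 0, axis=0), disk)

    def test_all_invalid_field_gives_empty_labels(self, lateral_params):
        vectors = np.ones((20, 4, 4, 2))
        validity = np.zeros((20, 4, 4), dtype=bool)
        refs = ReferenceField.constant(R, (4, 4))
        records, labels = segment_field(
            self._fields(vectors, validity), refs, lateral_params
        )
        assert records == [] and not labels.any()

    def test_reference_shape_mismatch_raises(self, lateral_params):
        refs = ReferenceField.constant(R, (3, 3))
        with pytest.raises(ValueError):
            segment_field(self._fields(np.zeros((20, 4, 4, 2))), refs, lateral_params)
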