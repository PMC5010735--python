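import numpy as np
import pytest
from scipy import stats

from runtumble import segmentation as seg
from runtumble.exceptions import FitError, ValidationError
from runtumble.model import simulate_ensemble
from runtumble.types import (
    RUN,
    TUMBLE,
    ASSeries,
    PhaseAnnotation,
    SimulationParams,
    Trajectory,
)


def _track(displacements, dt=1.5, cell_id="t"):
    """Trajectory from a list of 3D displacement vectors."""
    pos = np.vstack([np.zeros(3), np.cumsum(np.asarray(displacements, float), axis=0)])
    return Trajectory(cell_id, np.arange(len(pos)) * dt, pos)


class TestAlignmentAndSpeed:
    def test_straight_constant_speed_is_fully_aligned(self, straight_track):
        s = seg.compute_alignment_and_speed(straight_track)
        np.testing.assert_allclose(s.A, 1.0)
        np.testing.assert_allclose(s.S, 1.0)

    def test_alternating_reversal_is_antialigned_at_window_one(self):
        disp = [[1, 0, 0], [-1, 0, 0]] * 6
        s = seg.compute_alignment_and_speed(_track(disp), window=1)
        np.testing.assert_allclose(s.A, -1.0)
        # with window 2 the parallel next-nearest neighbours cancel the
        # antiparallel nearest ones for interior frames
        s2 = seg.compute_alignment_and_speed(_track(disp), window=2)
        np.testing.assert_allclose(s2.A[2:-2], 0.0, atol=1e-12)

    def test_matches_bruteforce_reference(self):
        """Independent per-point evaluation of the definition."""
        rng = np.random.default_rng(0)
        traj = _track(rng.normal(size=(99, 3)))
        s = seg.compute_alignment_and_speed(traj, window=2)
        v = np.diff(traj.positions, axis=0)
        speeds = np.linalg.norm(v, axis=1) / 1.5
        for i in rng.choice(len(v), 20, replace=False):
            cosines = []
            for k in range(max(0, i - 2), min(len(v), i + 3)):
                if k == i:
                    continue
                c = v[i] @ v[k] / (np.linalg.norm(v[i]) * np.linalg.norm(v[k]))
                cosines.append(c)
            assert s.A[i] == pytest.approx(np.mean(cosines), abs=1e-12)
            assert s.S[i] == pytest.approx(speeds[i] / speeds.mean(), abs=1e-12)

    def test_zero_displacement_frames_flagged_as_zero(self):
        disp = [[1, 0, 0], [0, 0, 0], [1, 0, 0], [1, 0, 0], [1, 0, 0]]
        s = seg.compute_alignment_and_speed(_track(disp))
        assert s.zero_flag[1]
        assert s.A[1] == 0.0 and s.S[1] == 0.0

    def test_nonuniform_sampling_rejected(self):
        pos = np.arange(18, dtype=float).reshape(6, 3)
        traj = Trajectory("x", [0, 1.5, 3.0, 4.6, 6.0, 7.5], pos)
        with pytest.raises(ValidationError, match="uniform"):
            seg.compute_alignment_and_speed(traj)

    def test_too_short_trajectory_rejected(self):
        traj = _track([[1, 0, 0], [1, 0, 0]])
        with pytest.raises(ValidationError, match="short"):
            seg.compute_alignment_and_speed(traj, window=2)


def _series_from_points(A, S):
    A = np.asarray(A, float)
    return ASSeries(
        cell_id="s",
        times=np.arange(len(A)) * 1.5,
        A=A,
        S=np.asarray(S, float),
        zero_flag=np.zeros(len(A), bool),
        window=2,
    )


class TestDensity:
    def test_unit_mass(self):
        rng = np.random.default_rng(1)
        d = seg.estimate_density(
            _series_from_points(rng.uniform(-1, 1, 2000), rng.uniform(0, 3, 2000))
        )
        assert d.density.sum() * d.bin_area == pytest.approx(1.0, abs=1e-9)

    def test_uniform_sample_is_flat(self):
        rng = np.random.default_rng(2)
        n = 100_000
        d = seg.estimate_density(
            _series_from_points(rng.uniform(-1, 1, n), rng.uniform(0, 3, n)),
            bandwidth=0.0,
        )
        counts = d.density * d.bin_area * n
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, counts.size - 1)
        assert p > 0.01

    def test_two_separated_clusters_give_two_maxima(self):
        rng = np.random.default_rng(3)
        A = np.concatenate(
            [rng.normal(-0.5, 0.05, 3000), rng.normal(0.6, 0.05, 3000)]
        )
        S = np.concatenate(
            [rng.normal(0.5, 0.05, 3000), rng.normal(1.8, 0.05, 3000)]
        )
        d = seg.estimate_density(_series_from_points(A, S))
        from scipy.ndimage import maximum_filter

        local_max = (d.density == maximum_filter(d.density, size=5)) & (
            d.density > 0.1 * d.density.max()
        )
        assert local_max.sum() == 2

    def test_empty_and_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            seg.estimate_density([])
        with pytest.raises(ValidationError):
            seg.estimate_density(
                _series_from_points(np.full(600, 0.3), np.full(600, 1.0))
            )

    def test_few_points_warn(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="pooled"):
            seg.estimate_density(
                _series_from_points(rng.uniform(-1, 1, 50), rng.uniform(0, 3, 50))
            )


class TestMaximumLine:
    def _ridge_density(self, slope=0.5, intercept=0.8, n=40_000, seed=5):
        rng = np.random.default_rng(seed)
        A = rng.uniform(-1, 1, n)
        S = slope * A + intercept + rng.normal(0, 0.1, n)
        return seg.estimate_density(_series_from_points(A, np.clip(S, 0, None)))

    def test_recovers_synthetic_ridge(self):
        d = self._ridge_density()
        slope, intercept = seg.fit_maximum_line(d)
        assert slope == pytest.approx(0.5, abs=0.05)
        assert intercept == pytest.approx(0.8, abs=0.05)

    def test_isotropic_blob_has_flat_maximum_line(self):
        rng = np.random.default_rng(6)
        d = seg.estimate_density(
            _series_from_points(
                rng.normal(0, 0.2, 30_000), rng.normal(1.5, 0.2, 30_000)
            )
        )
        slope, _ = seg.fit_maximum_line(d)
        assert abs(slope) < 0.1

    def test_single_column_mass_is_fit_error(self):
        rng = np.random.default_rng(7)
        A = np.full(5000, 0.3) + rng.normal(0, 0.004, 5000)
        d = seg.estimate_density(
            _series_from_points(A, rng.uniform(0, 3, 5000)), bandwidth=0.0
        )
        with pytest.raises(FitError):
            seg.fit_maximum_line(d)


class TestThreshold:
    def test_bimodal_mixture_valley_recovered(self):
        """Equal mixture of 1D Gaussians at A=0.2 and A=0.8 (sd 0.1):
        the density minimum between the modes sits at A = 0.5."""
        rng = np.random.default_rng(8)
        n = 60_000
        A = np.clip(
            np.concatenate(
                [rng.normal(0.2, 0.1, n // 2), rng.normal(0.8, 0.1, n // 2)]
            ),
            -1.0, 1.0,
        )
        S = 0.5 * A + 0.8 + rng.normal(0, 0.05, n)
        d = seg.estimate_density(_series_from_points(A, S))
        seg.fit_maximum_line(d)
        thr = seg.find_threshold(d)
        assert not d.threshold_fallback
        assert thr == pytest.approx(0.5, abs=0.05)

    def test_unimodal_profile_uses_flagged_fallback(self):
        rng = np.random.default_rng(9)
        A = rng.normal(0.5, 0.15, 30_000)
        S = 0.5 * A + 0.8 + rng.normal(0, 0.05, 30_000)
        d = seg.estimate_density(_series_from_points(np.clip(A, -1, 1), S))
        seg.fit_maximum_line(d)
        with pytest.warns(UserWarning, match="unimodal"):
            thr = seg.find_threshold(d)
        assert d.threshold_fallback
        assert -1 <= thr <= 1


def _manual_density(threshold_A=0.5):
    """Density whose maximum line is S = A and threshold at A=0.5."""
    rng = np.random.default_rng(10)
    A = np.concatenate([rng.normal(0.0, 0.1, 4000), rng.normal(0.9, 0.05, 4000)])
    S = A + 0.5 + rng.normal(0, 0.05, 8000)
    d = seg.estimate_density(_series_from_points(np.clip(A, -1, 1), S))
    seg.fit_maximum_line(d)
    seg.find_threshold(d)
    return d


class TestClassifyPhases:
    def test_all_above_threshold_is_single_run(self, straight_track):
        d = _manual_density()
        ann = seg.classify_phases(straight_track, d)
        assert [s.phase for s in ann.segments] == [RUN]

    def test_all_below_threshold_is_single_tumble(self):
        # headings cycling through 120-degree steps: every pairwise cosine
        # is -0.5, so A = -0.5 at every frame, well below the threshold
        disp = [
            [np.cos(np.radians(h)), np.sin(np.radians(h)), 0.0]
            for h in [0.0, 120.0, 240.0] * 7
        ]
        traj = _track(disp)
        d = _manual_density()
        ann = seg.classify_phases(traj, d)
        assert [s.phase for s in ann.segments] == [TUMBLE]

    def test_segments_tile_trajectory(self, separated_ensemble):
        trajs, _ = separated_ensemble
        dens, anns = seg.segment_ensemble(trajs)
        for t, a in zip(trajs, anns):
            assert a.segments[0].t_start == t.times[0]
            total = sum(s.duration for s in a.segments)
            assert total == pytest.approx(t.times[-1] - t.times[0])
            for s1, s2 in zip(a.segments, a.segments[1:]):
                assert s1.t_end == pytest.approx(s2.t_start)
                assert s1.phase != s2.phase

    def test_ground_truth_recovery_on_separated_states(self, separated_ensemble):
        trajs, truths = separated_ensemble
        _, anns = seg.segment_ensemble(trajs)
        acc = np.mean(
            [seg.label_agreement(t, p) for t, p in zip(truths, anns)]
        )
        assert acc >= 0.90

    def test_recovered_durations_track_generative_means(self):
        """With long, widely separated phases the segmented run durations
        match the generative mean closely; tumble durations carry a
        positive bias of order one frame per phase boundary (the A
        window straddles switches), so only a looser bound holds."""
        p = SimulationParams(
            tau_r=20.0, tau_t=10.0, v_run_mean=4.0, v_run_sd=0.4,
            v_tumble_mean=3.0, v_tumble_sd=0.5, D_theta=0.01,
            sigma_eps=0.6, n_cells=20, seed=42,
        )
        trajs, _ = simulate_ensemble(p, total_time=240.0, seed=42)
        _, anns = seg.segment_ensemble(trajs)
        runs = np.concatenate([a.durations(RUN) for a in anns])
        tums = np.concatenate([a.durations(TUMBLE) for a in anns])
        assert runs.mean() == pytest.approx(p.tau_r, rel=0.15)
        assert tums.mean() == pytest.approx(p.tau_t, rel=0.50)
        assert tums.mean() > p.tau_t  # bias is upward by construction

    def test_deterministic_given_inputs(self, separated_ensemble):
        trajs, _ = separated_ensemble
        d1, a1 = seg.segment_ensemble(trajs)
        d2, a2 = seg.segment_ensemble(trajs)
        assert d1.threshold_A == d2.threshold_A
        for x, y in zip(a1, a2):
            assert (x.labels == y.labels).all()


class TestShortTrackClassifier:
    def _disp(self, headings_deg):
        return [
            [np.cos(np.radians(h)), np.sin(np.radians(h)), 0.0]
            for h in headings_deg
        ]

    def test_straight_track_single_run(self):
        traj = _track(self._disp([0] * 20), dt=1 / 6)
        ann = seg.classify_phases_short(traj)
        assert [s.phase for s in ann.segments] == [RUN]

    def test_sustained_turn_opens_tumble(self):
        headings = [0] * 10 + [90] * 6 + [90] * 10
        traj = _track(self._disp(headings), dt=1 / 6)
        ann = seg.classify_phases_short(traj)
        assert [s.phase for s in ann.segments] == [RUN, TUMBLE, RUN]

    def test_transient_deviation_stays_one_run(self):
        headings = [0] * 10 + [90] * 3 + [0] * 10
        traj = _track(self._disp(headings), dt=1 / 6)
        ann = seg.classify_phases_short(traj)
        assert [s.phase for s in ann.segments] == [RUN]

    def test_too_short_track_rejected(self):
        traj = _track(self._disp([0, 0, 0]), dt=1 / 6)
        with pytest.raises(ValidationError):
            seg.classify_phases_short(traj, persist_frames=5)


class TestPhaseStatistics:
    def _ann(self, traj, labels):
        return PhaseAnnotation(
            traj.cell_id, traj.times, np.asarray(labels, dtype=object)
        )

    def test_duration_ratio_arithmetic(self):
        # 10 min of running then 5 min of tumbling at 2.5-min frames
        disp = [[5, 0, 0]] * 4 + [[0.5, 0, 0]] * 2
        traj = _track(disp, dt=2.5)
        labels = [RUN] * 4 + [TUMBLE] * 3
        s = seg.phase_statistics(traj, self._ann(traj, labels), 2.5)
        assert s.tumble_run_time_ratio == pytest.approx(0.5)
        assert s.mean_run_duration == pytest.approx(10.0)

    def test_inter_run_angle_between_orthogonal_runs(self):
        disp = [[1, 0, 0]] * 4 + [[0.1, 0.1, 0]] * 2 + [[0, 1, 0]] * 4
        traj = _track(disp)
        labels = [RUN] * 4 + [TUMBLE] * 2 + [RUN] * 5
        s = seg.phase_statistics(traj, self._ann(traj, labels))
        assert len(s.inter_run_angles) == 1
        # tumble displacement contaminates the first run's endpoint frame
        assert s.inter_run_angles[0] == pytest.approx(90.0, abs=5.0)

    def test_straight_track_persistence_is_one(self, straight_track):
        labels = [RUN] * len(straight_track)
        s = seg.phase_statistics(straight_track, self._ann(straight_track, labels))
        assert s.persistence == pytest.approx(1.0)
        assert not np.isinf(s.tumble_run_time_ratio)

    def test_no_run_segment_flags_infinite_ratio(self):
        disp = [[0.1, 0, 0]] * 6
        traj = _track(disp)
        s = seg.phase_statistics(traj, self._ann(traj, [TUMBLE] * 7))
        assert np.isinf(s.tumble_run_time_ratio)
        assert len(s.inter_run_angles) == 0

    def test_speed_ratio_pools_by_frame_label(self):
        disp = [[3, 0, 0]] * 3 + [[1, 0, 0]] * 3
        traj = _track(disp, dt=1.5)
        labels = [RUN] * 3 + [TUMBLE] * 4
        s = seg.phase_statistics(traj, self._ann(traj, labels), 1.5)
        assert s.speed_ratio == pytest.approx(3.0)


class TestExponentialFit:
    def test_constant_durations(self):
        mean, ci, cv = seg.fit_exponential_durations([2.0, 2.0, 2.0], seed=0)
        assert mean == pytest.approx(2.0)
        assert cv == 0.0

    def test_large_exponential_sample(self):
        rng = np.random.default_rng(12)
        durs = rng.exponential(5.0, 10_000)
        mean, ci, cv = seg.fit_exponential_durations(durs, seed=0)
        assert mean == pytest.approx(5.0, abs=0.1)
        assert cv == pytest.approx(1.0, abs=0.05)
        assert ci[0] < mean < ci[1]

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            seg.fit_exponential_durations([])
        with pytest.raises(ValidationError):
            seg.fit_exponential_durations([1.0, -2.0, 3.0, 4.0, 5.0])


class TestPersistenceProperties:
    def test_persistence_in_unit_interval_and_collinear_extreme(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            traj = _track(rng.normal(size=(30, 3)))
            assert 0.0 <= traj.persistence <= 1.0

    def test_persistence_increases_with_run_time(self):
        """Longer generative runs produce straighter tracks."""
        taus = np.linspace(1.0, 12.0, 25)
        pers = []
        for i, tr in enumerate(taus):
            p = SimulationParams(
                tau_r=float(tr), tau_t=2.0, sigma_eps=0.5, D_theta=0.05,
                n_cells=6, seed=100 + i,
            )
            trajs, _ = simulate_ensemble(p, total_time=120.0, seed=100 + i)
            pers.append(np.mean([t.persistence for t in trajs]))
        rho, _ = stats.spearmanr(taus, pers)
        assert rho > 0.5
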