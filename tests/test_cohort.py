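import numpy as np
import pytest
from scipy.stats import norm

from dfnc.cohort import (
    GroundTruth,
    Paradigm,
    cohort_behavior_table,
    default_ground_truth,
    make_paradigm,
    sample_state_sequence,
    simulate_behavior,
    simulate_cohort,
    simulate_subject,
    simulate_voxel_mixture,
)
from dfnc.errors import ConformabilityError, DecompositionError, InvalidConfigError


class TestMakeParadigm:
    def test_default_run_structure(self):
        p = make_paradigm()
        task_blocks = [d for kind, d in p.block_specs if kind == "task"]
        assert len(task_blocks) == 8
        assert all(d == 36.0 for d in task_blocks)
        assert p.fixation_duration == 8.0
        assert p.total_duration == 402.0
        assert p.n_volumes == 201

    def test_zero_stimuli_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_paradigm(stimuli_per_block=0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_paradigm(stimulus_duration=-1.0)

    def test_block_duration_sum_oracle(self):
        # 2 stimuli of (2.5 + 0.5) s -> 6 s, frozen from the sum oracle
        p = make_paradigm(n_task_blocks=1, stimuli_per_block=2)
        assert p.task_block_duration == pytest.approx(2 * (2.5 + 0.5))
        assert p.task_block_duration == pytest.approx(6.0)

    def test_onsets_cumulative(self):
        p = make_paradigm()
        onsets = p.onsets()
        # onsets are the cumulative sum of preceding durations
        expected = np.concatenate([[0.0], np.cumsum(onsets["duration"].to_numpy())[:-1]])
        np.testing.assert_allclose(onsets["onset"].to_numpy(), expected)

    def test_boxcar_matches_block_arithmetic(self):
        p = make_paradigm()
        box = p.boxcar("task")
        assert box.sum() * p.tr == pytest.approx(8 * 36.0)


class TestSampleStateSequence:
    def test_identity_matrix_never_switches(self):
        seq = sample_state_sequence(np.eye(3), 500, seed=0)
        assert np.count_nonzero(np.diff(seq)) == 0

    def test_uniform_chain_stationary_frequencies(self):
        # stationary distribution of the uniform 4x4 chain is (1/4, ...)
        P = np.full((4, 4), 0.25)
        seq = sample_state_sequence(P, 100_000, seed=3)
        freqs = np.bincount(seq, minlength=4) / seq.size
        np.testing.assert_allclose(freqs, 0.25, atol=0.01)

    def test_determinism(self):
        P = np.full((2, 2), 0.5)
        a = sample_state_sequence(P, 100, seed=11)
        b = sample_state_sequence(P, 100, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_bad_rows_rejected(self):
        with pytest.raises(InvalidConfigError):
            sample_state_sequence(np.array([[0.5, 0.4], [0.5, 0.5]]), 10, seed=0)


class TestGroundTruth:
    def test_default_is_valid(self):
        gt = default_ground_truth(seed=1)
        assert gt.n_states == 4
        assert gt.n_components == 14
        np.testing.assert_allclose(gt.transition_matrix.sum(axis=1), 1.0)
        for cov in gt.state_covariances:
            np.testing.assert_allclose(np.diag(cov), 1.0)
            assert np.linalg.eigvalsh(cov).min() > 0

    def test_states_well_separated(self):
        # pairwise L1 centroid distance large relative to the edge scale
        from dfnc.windows import vectorize

        gt = default_ground_truth(seed=2)
        edges = vectorize(gt.state_covariances)
        for i in range(4):
            for j in range(i + 1, 4):
                assert np.abs(edges[i] - edges[j]).sum() > 30

    def test_asymmetric_covariance_rejected(self):
        cov = np.eye(3)
        cov[0, 1] = 0.5
        with pytest.raises(InvalidConfigError):
            GroundTruth(
                state_covariances=cov[None], transition_matrix=np.ones((1, 1))
            )

    def test_coupling_out_of_range_rejected(self):
        with pytest.raises(InvalidConfigError):
            default_ground_truth(behavior_coupling=1.5)


class TestSimulateSubject:
    def test_empirical_covariance_oracle(self):
        # single state, no task signal, no noise: sample correlation of a
        # long draw matches the state covariance elementwise
        cov = default_ground_truth(seed=0).state_covariances[:1]
        gt = GroundTruth(
            state_covariances=cov,
            transition_matrix=np.ones((1, 1)),
            task_amplitude=0.0,
            noise_sd=0.0,
        )
        paradigm = Paradigm(
            fixation_duration=8.0,
            block_specs=(("rest", 199_992.0),),
            stimulus_duration=2.5,
            inter_stimulus_interval=0.5,
            stimuli_per_block=12,
            tr=2.0,
        )
        assert paradigm.n_volumes == 100_000
        run = simulate_subject(paradigm, gt, subject_seed=5)
        emp = np.corrcoef(run.data.T)
        assert np.abs(emp - cov[0]).max() < 0.02

    def test_zero_fd_gives_zero_motion(self, paradigm):
        gt = default_ground_truth(seed=0, target_fd=0.0)
        run = simulate_subject(paradigm, gt, subject_seed=1)
        assert np.all(run.motion == 0)

    def test_determinism(self, paradigm, ground_truth):
        a = simulate_subject(paradigm, ground_truth, subject_seed=9)
        b = simulate_subject(paradigm, ground_truth, subject_seed=9)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.motion, b.motion)
        np.testing.assert_array_equal(a.state_labels, b.state_labels)

    def test_non_pd_covariance_names_state(self, paradigm):
        cov = np.stack([np.eye(3), np.full((3, 3), 1.0)])
        np.fill_diagonal(cov[1], 1.0)
        cov[1, 0, 1] = cov[1, 1, 0] = 1.0  # singular
        gt = GroundTruth(
            state_covariances=cov, transition_matrix=np.full((2, 2), 0.5)
        )
        with pytest.raises(DecompositionError, match="state 1"):
            simulate_subject(paradigm, gt, subject_seed=0)

    def test_motion_hits_target_fd(self, paradigm):
        from dfnc.prep import framewise_displacement

        gt = default_ground_truth(seed=0, target_fd=0.04)
        run = simulate_subject(paradigm, gt, subject_seed=2)
        fd = framewise_displacement(run.motion)
        assert fd[1:].mean() == pytest.approx(0.04, rel=1e-6)

    def test_rest_state_pinned_when_locked(self, paradigm):
        gt = default_ground_truth(seed=0, rest_state=3)
        run = simulate_subject(paradigm, gt, subject_seed=4)
        rest_mask = paradigm.boxcar("task") == 0
        assert np.all(run.state_labels[rest_mask] == 3)


class TestSimulateVoxelMixture:
    def test_zero_noise_rank(self, rng):
        maps = rng.standard_normal((3, 50))
        ts = rng.standard_normal((3, 40))
        out = simulate_voxel_mixture(maps, ts, noise_sd=0.0)
        assert np.linalg.matrix_rank(out) <= 3

    def test_outer_product_exact(self, rng):
        m = rng.standard_normal((1, 30))
        tc = np.full((1, 20), 2.5)
        out = simulate_voxel_mixture(m, tc, noise_sd=0.0)
        np.testing.assert_allclose(out, np.outer(m[0], tc[0]))

    def test_pseudoinverse_recovery(self, rng):
        # known 3-source mixture recoverable by least squares
        maps = rng.standard_normal((3, 100))
        ts = rng.standard_normal((3, 60))
        out = simulate_voxel_mixture(maps, ts, noise_sd=0.0)
        recovered = np.linalg.pinv(maps.T) @ out
        np.testing.assert_allclose(recovered, ts, atol=1e-10)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ConformabilityError):
            simulate_voxel_mixture(
                rng.standard_normal((3, 10)), rng.standard_normal((4, 5))
            )


class TestSimulateBehavior:
    def test_null_dprime_converges(self):
        # binomial-rate oracle: hit and false-alarm rates are both Phi(0)
        from dfnc.inference import dprime

        beh = simulate_behavior(0.0, 1_000_000, latents=np.zeros(1), seed=0)
        d = dprime(
            int(beh.hits[0]), int(beh.n_signal_trials[0]),
            int(beh.false_alarms[0]), int(beh.n_noise_trials[0]),
        )
        assert abs(d) < 0.01

    def test_planted_dprime_converges(self):
        # quantile oracle: rates Phi(+-0.75) recover d' = 1.5
        from dfnc.inference import dprime

        beh = simulate_behavior(1.5, 1_000_000, latents=np.zeros(1), seed=1)
        d = dprime(
            int(beh.hits[0]), int(beh.n_signal_trials[0]),
            int(beh.false_alarms[0]), int(beh.n_noise_trials[0]),
        )
        assert abs(d - 1.5) < 0.02

    def test_rates_follow_sdt_model(self):
        beh = simulate_behavior(1.0, 500_000, latents=np.zeros(1), seed=2)
        assert beh.hits[0] / beh.n_signal_trials[0] == pytest.approx(
            norm.cdf(0.5), abs=0.005
        )
        assert beh.false_alarms[0] / beh.n_noise_trials[0] == pytest.approx(
            norm.cdf(-0.5), abs=0.005
        )

    def test_determinism(self):
        a = simulate_behavior(1.0, 100, latents=np.zeros(5), seed=3)
        b = simulate_behavior(1.0, 100, latents=np.zeros(5), seed=3)
        assert a.equals(b)

    def test_invalid_trials(self):
        with pytest.raises(InvalidConfigError):
            simulate_behavior(1.0, 0, seed=0)


class TestCohort:
    def test_end_to_end_determinism(self):
        a = simulate_cohort(n_subjects=3, seed=21)
        b = simulate_cohort(n_subjects=3, seed=21)
        assert a.behavior.equals(b.behavior)
        for ra, rb in zip(a.runs, b.runs):
            np.testing.assert_array_equal(ra.data, rb.data)
            np.testing.assert_array_equal(ra.motion, rb.motion)

    def test_run_bookkeeping(self, small_cohort):
        assert len(small_cohort.runs) == 12  # 6 subjects x 2 tasks
        assert all(r.n_volumes == 201 for r in small_cohort.runs)
        assert all(r.n_components == 14 for r in small_cohort.runs)
        assert len(small_cohort.behavior) == 12

    def test_behavior_table_has_dprime(self, small_cohort):
        beh = cohort_behavior_table(small_cohort)
        assert "d_prime" in beh.columns
        assert np.isfinite(beh["d_prime"]).all()

    def test_dwell_behavior_coupling_mean(self):
        # mean sample correlation across replicate cohorts approaches the
        # configured coupling (fast path: no time series)
        from dfnc.inference import partial_corr_behavior

        rs = []
        for seed in range(150):
            gt = default_ground_truth(seed=0, behavior_coupling=0.58)
            c = simulate_cohort(
                n_subjects=20, ground_truth=gt, seed=seed, timeseries=False
            )
            beh = cohort_behavior_table(c)
            sub = beh[beh.task == "nback"]
            rs.append(
                np.corrcoef(sub["true_dwell_coupled_state"], sub["d_prime"])[0, 1]
            )
        assert np.mean(rs) == pytest.approx(0.58, abs=0.05)
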