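import numpy as np
import pytest
from scipy.signal import fftconvolve

from arrowtime import (
    Paradigm,
    SubjectSeries,
    concatenate_subjects,
    fit_var1,
    hrf_epoch_mask,
    mask_filter,
    regional_aot,
    sliding_window_aot,
    windowed_activity,
    windowed_connectivity,
)
from arrowtime.dynamics import EpochMask, canonical_hrf

TR = 0.72


class TestEpochMask:
    def test_all_zero_paradigm_all_rest(self):
        mask = hrf_epoch_mask(Paradigm(np.zeros(50, dtype=int), TR))
        assert not mask.task.any()

    def test_sustained_task_plateau_matches_convolution_oracle(self):
        values = np.ones(200, dtype=int)
        mask = hrf_epoch_mask(Paradigm(values, TR))
        kernel = canonical_hrf(TR)
        oracle = fftconvolve(values.astype(float), kernel)[:200] > 0.5
        np.testing.assert_array_equal(mask.task, oracle)
        assert mask.task[100:].all()  # interior samples are task

    def test_short_block_onset_is_delayed(self):
        values = np.zeros(120, dtype=int)
        values[10:24] = 1
        mask = hrf_epoch_mask(Paradigm(values, TR))
        kernel = canonical_hrf(TR)
        conv = np.convolve(values.astype(float), kernel)[:120]
        first_crossing = int(np.argmax(conv > 0.5))
        assert mask.task.any()
        assert int(np.argmax(mask.task)) == first_crossing > 10

    def test_invalid_paradigm_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            Paradigm(np.array([0, 2, 1]), TR)
        with pytest.raises(ValueError, match="sampling_period"):
            Paradigm(np.array([0, 1]), 0.0)

    def test_from_onsets(self):
        p = Paradigm.from_onsets([7.2], [7.2], n_time=30, sampling_period=TR)
        assert p.values[10:20].all() and p.values[:10].sum() == 0


class TestMaskFilter:
    def _cohort(self, rng, lengths=(30, 30)):
        subs = [SubjectSeries(rng.normal(size=(2, n))) for n in lengths]
        return concatenate_subjects(subs)

    def test_all_task_mask_is_identity(self, rng):
        c = self._cohort(rng)
        masks = [EpochMask(np.ones(30, bool)) for _ in range(2)]
        out = mask_filter(c, masks, keep="task")
        np.testing.assert_array_equal(out.data, c.data)
        np.testing.assert_array_equal(out.boundaries, c.boundaries)

    def test_all_rest_mask_empties_cohort(self, rng):
        c = self._cohort(rng)
        masks = [EpochMask(np.zeros(30, bool)) for _ in range(2)]
        with pytest.raises(ValueError, match="empty"):
            mask_filter(c, masks, keep="task")

    def test_two_runs_split_and_pair_arithmetic(self, rng):
        c = self._cohort(rng, lengths=(30,))
        flags = np.zeros(30, bool)
        flags[5:15] = True
        flags[20:28] = True
        out = mask_filter(c, [EpochMask(flags)], keep="task")
        assert out.n_subjects == 2  # two sub-blocks
        assert out.n_time == 18
        fit = fit_var1(out, "forward")
        assert fit.used_pairs == out.n_time - 2

    def test_no_pairs_across_removed_gaps(self, rng):
        # Brute-force pair enumeration oracle: pairs must all be consecutive
        # samples inside a retained run.
        c = self._cohort(rng, lengths=(40,))
        flags = np.zeros(40, bool)
        flags[3:10] = True
        flags[15:25] = True
        out = mask_filter(c, [EpochMask(flags)], keep="task")
        runs = [(3, 10), (15, 25)]
        expected_pairs = sum(b - a - 1 for a, b in runs)
        assert fit_var1(out, "forward").used_pairs == expected_pairs
        rebuilt = np.concatenate([c.data[:, a:b] for a, b in runs], axis=1)
        np.testing.assert_array_equal(out.data, rebuilt)

    def test_short_runs_dropped_with_warning(self, rng):
        c = self._cohort(rng, lengths=(20,))
        flags = np.zeros(20, bool)
        flags[2] = True          # singleton run: dropped
        flags[6:12] = True
        with pytest.warns(UserWarning, match="dropped 1"):
            out = mask_filter(c, [EpochMask(flags)], keep="task")
        assert out.n_time == 6

    def test_keep_rest_complements(self, rng):
        c = self._cohort(rng, lengths=(20,))
        flags = np.zeros(20, bool)
        flags[:10] = True
        out = mask_filter(c, [EpochMask(flags)], keep="rest")
        np.testing.assert_array_equal(out.data, c.data[:, 10:])


class TestWindows:
    def _cohort_subjects(self, rng, n_subjects=30, n_time=60, n_regions=3):
        return [
            SubjectSeries(rng.normal(size=(n_regions, n_time)), subject_id=f"s{i}")
            for i in range(n_subjects)
        ]

    def test_window_grid_shared_across_kinds(self, rng):
        subs = self._cohort_subjects(rng)
        W = 12
        courses = [
            sliding_window_aot(subs, W),
            windowed_activity(subs, W),
            windowed_connectivity(subs, W),
        ]
        assert len({c.n_windows for c in courses}) == 1
        assert courses[0].n_windows == 60 - W + 1
        assert all(c.window_width == W and c.stride == 1 for c in courses)

    def test_full_length_window_equals_static_aot(self, rng):
        subs = self._cohort_subjects(rng, n_subjects=8, n_time=40)
        course = sliding_window_aot(subs, window_width=40)
        assert course.n_windows == 1
        cohort = concatenate_subjects(subs)
        static = regional_aot(fit_var1(cohort, "forward"), fit_var1(cohort, "backward"))
        np.testing.assert_allclose(course.values[:, 0], static, atol=1e-10)

    def test_reversal_flips_sign_and_mirrors_axis(self, rng):
        subs = self._cohort_subjects(rng, n_subjects=20, n_time=30)
        rev = [SubjectSeries(s.data[:, ::-1], s.subject_id) for s in subs]
        W = 10
        fwd = sliding_window_aot(subs, W)
        bwd = sliding_window_aot(rev, W)
        np.testing.assert_allclose(bwd.values, -fwd.values[:, ::-1], atol=1e-8)

    def test_activity_constant_series(self):
        subs = [SubjectSeries(np.full((2, 20), 3.5)) for _ in range(4)]
        course = windowed_activity(subs, 5)
        np.testing.assert_allclose(course.values, 3.5)

    def test_activity_impulse_becomes_boxcar(self):
        n_sub, W, T, t0 = 4, 5, 20, 10
        subs = [SubjectSeries(np.zeros((1, T)) + 1e-9 * np.arange(T)) for _ in range(n_sub)]
        subs[0].data[0, t0] += 1.0
        course = windowed_activity(subs, W)
        expected = np.zeros(T - W + 1)
        expected[t0 - W + 1 : t0 + 1] = 1.0 / (n_sub * W)
        np.testing.assert_allclose(course.values[0], expected, atol=1e-7)

    def test_connectivity_perfectly_correlated_pair(self, rng):
        base = rng.normal(size=(1, 30))
        subs = [SubjectSeries(np.vstack([base, base])) for _ in range(3)]
        course = windowed_connectivity(subs, 6)
        np.testing.assert_allclose(course.values, 1.0, atol=1e-10)

    def test_connectivity_anticorrelated_triple_matches_oracle(self, rng):
        subs = []
        for _ in range(5):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            subs.append(SubjectSeries(np.vstack([a, b, -a])))
        W = 10
        course = windowed_connectivity(subs, W)
        # Brute-force oracle at window 0: np.corrcoef on pooled demeaned samples
        pooled = np.concatenate(
            [s.data[:, :W] - s.data[:, :W].mean(1, keepdims=True) for s in subs],
            axis=1,
        )
        corr = np.corrcoef(pooled)
        expected_r0 = corr[0, 1] + corr[0, 2]
        assert course.values[0, 0] == pytest.approx(expected_r0, abs=1e-10)
        assert course.values[0, 0] == pytest.approx(corr[0, 1] - 1, abs=1e-10)

    def test_connectivity_zero_variance_region_warns(self):
        subs = [SubjectSeries(np.vstack([np.full(20, 2.0), np.arange(20.0)]))
                for _ in range(2)]
        with pytest.warns(UserWarning, match="zero-variance"):
            course = windowed_connectivity(subs, 5)
        np.testing.assert_array_equal(course.values[0], 0.0)

    def test_window_size_errors(self, rng):
        subs = self._cohort_subjects(rng, n_subjects=2, n_time=15)
        with pytest.raises(ValueError, match="window width"):
            windowed_activity(subs, 16)
        with pytest.raises(ValueError, match="pooled pairs"):
            sliding_window_aot(subs[:1], 3)
        with pytest.raises(ValueError, match=">= 3"):
            windowed_connectivity(subs, 2)

    def test_mismatched_lengths_rejected(self, rng):
        subs = [SubjectSeries(rng.normal(size=(2, 20))),
                SubjectSeries(rng.normal(size=(2, 25)))]
        with pytest.raises(ValueError, match="same length"):
            windowed_activity(subs, 5)
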