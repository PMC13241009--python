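import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import canaldyn as cd
from canaldyn.latent import brute_force_align, mean_modes


@pytest.fixture(scope="module")
def fitted(small_cohort):
    ts = cd.filter_responsive(small_cohort[0])
    ta = cd.trial_average(ts)
    return ts, ta, cd.fit_latent(ta, 5)


class TestFitLatent:
    def test_loadings_orthonormal(self, fitted):
        _, _, model = fitted
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(5), atol=1e-8
        )

    def test_variance_fractions(self, fitted):
        _, _, model = fitted
        ve = model.variance_explained
        assert np.all(np.diff(ve) <= 1e-12)  # descending
        assert np.all((ve >= 0) & (ve <= 1))
        assert model.all_variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank2_data_has_zero_trailing_variance(self, protocol):
        rng = np.random.default_rng(0)
        patterns = rng.standard_normal((2, protocol.trial_samples))
        data = rng.standard_normal((20, 2)) @ patterns
        model = cd.fit_latent(cd.TrialAverage("r2", data, protocol), 5)
        assert np.allclose(model.variance_explained[2:], 0.0, atol=1e-12)

    def test_k_too_large_rejected(self, protocol):
        data = np.random.default_rng(1).standard_normal((3, protocol.trial_samples))
        with pytest.raises(ValueError):
            cd.fit_latent(cd.TrialAverage("x", data, protocol), 5)

    def test_single_neuron_rejected(self, protocol):
        data = np.ones((1, protocol.trial_samples))
        with pytest.raises(ValueError):
            cd.fit_latent(cd.TrialAverage("x", data, protocol), 5)

    def test_reconstruction_pythagoras(self, fitted):
        """Variance captured by k modes + residual variance = total variance."""
        _, ta, model = fitted
        X = ta.data.T - model.neuron_means
        total = (X**2).sum()
        recon = model.dynamics.T @ model.loadings.T
        resid = ((X - recon) ** 2).sum()
        captured_fraction = 1.0 - resid / total
        assert captured_fraction == pytest.approx(model.variance_explained.sum(), abs=1e-6)


class TestProjection:
    def test_projecting_trial_average_recovers_dynamics(self, fitted):
        _, ta, model = fitted
        ms = cd.project_matrix(ta.data, model)
        np.testing.assert_allclose(ms.modes, model.dynamics, atol=1e-9)

    def test_noiseless_trials_project_to_averaged_dynamics(self, noiseless_cohort):
        ts = cd.filter_responsive(noiseless_cohort[0])
        model = cd.fit_latent(cd.trial_average(ts), 5)
        for t in range(3):
            ms = cd.project_trial(ts, t, model)
            np.testing.assert_allclose(ms.modes, model.dynamics, atol=1e-8)

    def test_noisy_trial_correlates_above_0_9(self, small_cohort):
        """10% trial noise leaves per-trial dynamics highly but imperfectly
        correlated with the trial-averaged dynamics."""
        ts = cd.filter_responsive(small_cohort[0])
        model = cd.fit_latent(cd.trial_average(ts), 5)
        ms = cd.project_trial(ts, 0, model)
        for m in range(5):
            r = np.corrcoef(ms.modes[m], model.dynamics[m])[0, 1]
            assert 0.9 < r < 1.0

    def test_neuron_count_mismatch(self, fitted):
        _, _, model = fitted
        with pytest.raises(ValueError):
            cd.project_matrix(np.zeros((3, 180)), model)


class TestAlignModes:
    def test_identity_on_self(self):
        rng = np.random.default_rng(0)
        ms = cd.ModeSet(rng.standard_normal((5, 80)))
        res = cd.align_modes(ms, ms)
        assert np.array_equal(res.permutation, np.arange(5))
        assert np.array_equal(res.signs, np.ones(5, dtype=int))
        np.testing.assert_allclose(res.per_mode_r, 1.0, atol=1e-12)

    def test_recovers_known_scramble(self):
        rng = np.random.default_rng(1)
        ref = cd.ModeSet(rng.standard_normal((5, 80)))
        scrambled = ref.modes.copy()
        scrambled[[1, 2]] = scrambled[[2, 1]]
        scrambled[4] *= -1
        res = cd.align_modes(cd.ModeSet(scrambled), ref)
        assert list(res.permutation) == [0, 2, 1, 3, 4]
        assert list(res.signs) == [1, 1, 1, 1, -1]
        aligned = cd.apply_alignment(cd.ModeSet(scrambled), res)
        np.testing.assert_allclose(aligned.modes, ref.modes)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            t = cd.ModeSet(rng.standard_normal((5, 40)))
            r = cd.ModeSet(rng.standard_normal((5, 40)))
            fast, slow = cd.align_modes(t, r), brute_force_align(t, r)
            assert fast.score == pytest.approx(slow.score, abs=1e-10)
            np.testing.assert_allclose(
                np.sort(fast.per_mode_r), np.sort(slow.per_mode_r), atol=1e-10
            )

    def test_zero_variance_mode_flagged_not_fatal(self):
        rng = np.random.default_rng(3)
        t = rng.standard_normal((3, 40))
        t[1] = 0.0
        r = cd.ModeSet(rng.standard_normal((3, 40)))
        with pytest.warns(UserWarning):
            res = cd.align_modes(cd.ModeSet(t), r)
        assert res.degenerate.any()
        assert np.all(res.per_mode_r >= 0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_alignment_never_below_identity_score(self, seed):
        rng = np.random.default_rng(seed)
        t = cd.ModeSet(rng.standard_normal((4, 30)))
        r = cd.ModeSet(rng.standard_normal((4, 30)))
        res = cd.align_modes(t, r)
        identity = sum(
            abs(np.corrcoef(t.modes[m], r.modes[m])[0, 1]) for m in range(4)
        )
        assert res.score >= identity - 1e-10


class TestCanonicalOrder:
    def test_identical_cohort_alignments_are_identity(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((5, 60))
        cohort = [cd.ModeSet(base.copy(), fish_id=f"f{i}") for i in range(4)]
        aligned, avg = cd.canonical_order(cohort)
        for m in aligned:
            np.testing.assert_allclose(m.modes, base)
        np.testing.assert_allclose(avg.modes, base)

    def test_scrambled_copy_recovers_original_r(self):
        rng = np.random.default_rng(5)
        cohort = [cd.ModeSet(rng.standard_normal((5, 60)), fish_id=f"f{i}") for i in range(3)]
        scrambled = cohort[2].modes[[3, 0, 4, 1, 2]] * np.array([[1], [-1], [1], [-1], [1]])
        cohort_s = cohort[:2] + [cd.ModeSet(scrambled, fish_id="f2")]
        aligned_o, avg_o = cd.canonical_order(cohort)
        aligned_s, avg_s = cd.canonical_order(cohort_s)
        r_o = [np.corrcoef(aligned_o[2].modes[m], avg_o.modes[m])[0, 1] for m in range(5)]
        r_s = [np.corrcoef(aligned_s[2].modes[m], avg_s.modes[m])[0, 1] for m in range(5)]
        np.testing.assert_allclose(np.abs(r_s), np.abs(r_o), atol=1e-8)

    def test_single_individual(self):
        ms = cd.ModeSet(np.random.default_rng(6).standard_normal((5, 60)), fish_id="only")
        aligned, avg = cd.canonical_order([ms])
        np.testing.assert_allclose(avg.modes, ms.modes)

    def test_input_order_invariance_with_fixed_seed_individual(self):
        rng = np.random.default_rng(7)
        cohort = [cd.ModeSet(rng.standard_normal((4, 50)), fish_id=f"f{i}") for i in range(4)]
        aligned_a, avg_a = cd.canonical_order(cohort, reference_policy="first")
        reordered = [cohort[2], cohort[0], cohort[3], cohort[1]]
        aligned_b, avg_b = cd.canonical_order(reordered, reference_policy="first")
        np.testing.assert_allclose(avg_a.modes, avg_b.modes, atol=1e-10)
        by_id_a = {m.fish_id: m.modes for m in aligned_a}
        by_id_b = {m.fish_id: m.modes for m in aligned_b}
        for fid in by_id_a:
            np.testing.assert_allclose(by_id_a[fid], by_id_b[fid], atol=1e-10)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cd.canonical_order([])
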