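"""Feature computation and distance-correlation selection, checked against a
direct transcription of the defining sums and against an independent
implementation (pingouin)."""

import numpy as np
import pytest

from brakesense.features import (
    BANDS,
    dcc_scores,
    linear_envelope,
    select_features,
    spectral_features,
    temporal_features_eeg,
    temporal_features_emg,
)


def dcor_reference(x, y):
    """Brute-force O(n^2) sample distance correlation for scalar series."""
    n = len(x)
    a = np.zeros((n, n))
    b = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = abs(x[i] - x[j])
            b[i, j] = abs(y[i] - y[j])
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = a[i, j] - a[i].mean() - a[:, j].mean() + a.mean()
            B[i, j] = b[i, j] - b[i].mean() - b[:, j].mean() + b.mean()
    dcov2 = (A * B).sum() / n**2
    dvar2_a = (A * A).sum() / n**2
    dvar2_b = (B * B).sum() / n**2
    if dvar2_a <= 0 or dvar2_b <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar2_a * dvar2_b)))


class TestTemporalFeatures:
    def test_eeg_layout_contract(self):
        proj = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        fv = temporal_features_eeg(proj)
        np.testing.assert_array_equal(fv.values, [1, 2, 3, 4, 5, 6])
        assert fv.names[:3] == [(0, 0), (0, 1), (0, 2)]
        assert len(fv.values) == proj.size

    def test_eeg_zero_in_zero_out(self):
        assert np.all(temporal_features_eeg(np.zeros((3, 10))).values == 0)

    def test_envelope_constant_passes_dc(self):
        x = np.full((1, 400), 3.0)
        env = linear_envelope(x, 200.0)
        np.testing.assert_allclose(env, 3.0, rtol=1e-6)

    def test_envelope_of_sinusoid_is_mean_rectified_value(self):
        """|a sin| has mean 2a/pi; the 2 Hz low-pass leaves < 5% ripple."""
        fs, a = 200.0, 1.5
        t = np.arange(int(4 * fs)) / fs
        x = (a * np.sin(2 * np.pi * 30.0 * t))[None, :]
        env = linear_envelope(x, fs)
        mid = env[0, 200:-200]
        expected = 2 * a / np.pi
        assert mid.mean() == pytest.approx(expected, rel=0.02)
        assert np.abs(mid - expected).max() < 0.05 * expected

    def test_envelope_nonnegative(self, rng):
        x = rng.normal(size=(2, 400))
        env = linear_envelope(x, 200.0)
        assert env.min() >= -1e-6 * np.abs(env).max()

    def test_emg_features_flatten_envelope(self, rng):
        proj = rng.normal(size=(2, 200))
        fv = temporal_features_emg(proj, 200.0)
        np.testing.assert_allclose(
            fv.values, linear_envelope(proj, 200.0).ravel()
        )


class TestSpectralFeatures:
    def test_bin_centred_sinusoid_dominates(self):
        fs = 200.0
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        fv = spectral_features(x, fs, BANDS["full"])
        freqs = np.array([f for _, f in fv.names])
        power = fv.values
        assert power[freqs == 10.0].sum() / power.sum() >= 0.95

    def test_parseval(self, rng):
        fs = 200.0
        x = rng.normal(size=(1, int(fs)))
        fv = spectral_features(x, fs, (0.0, fs / 2))
        # 1 Hz bins: sum(PSD) * df equals the mean square
        assert fv.values.sum() * 1.0 == pytest.approx(np.mean(x**2), rel=1e-6)

    def test_alpha_band_bins(self, rng):
        fs = 200.0
        x = rng.normal(size=(2, int(fs)))
        fv = spectral_features(x, fs, BANDS["alpha"])
        freqs = sorted({f for _, f in fv.names})
        assert freqs == [8.0, 9.0, 10.0, 11.0, 12.0, 13.0]

    def test_eeg_full_band_starts_at_one_hz(self, rng):
        fv = spectral_features(np.ones((1, 200)), 200.0, BANDS["full"])
        freqs = [f for _, f in fv.names]
        assert min(freqs) == 1.0 and max(freqs) == 60.0

    def test_nonnegative_and_band_check(self, rng):
        x = rng.normal(size=(1, 200))
        assert spectral_features(x, 200.0, (15.0, 90.0)).values.min() >= 0
        with pytest.raises(ValueError):
            spectral_features(x, 200.0, (15.0, 150.0))


class TestDcc:
    def test_label_copy_scores_one(self):
        y = np.array([1, 1, 1, -1, -1, -1])
        X = np.column_stack([y.astype(float)])
        sel = dcc_scores(X, y)
        assert sel.scores[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_feature_scores_zero(self):
        y = np.array([1, 1, -1, -1])
        X = np.column_stack([np.full(4, 2.5), y.astype(float)])
        sel = dcc_scores(X, y)
        assert sel.scores[0] == 0.0

    def test_matches_bruteforce_reference(self, rng):
        X = rng.normal(size=(10, 5))
        y = np.where(rng.random(10) > 0.5, 1, -1)
        if np.unique(y).size < 2:
            y[0] = -y[1]
        sel = dcc_scores(X, y)
        for q in range(X.shape[1]):
            assert sel.scores[q] == pytest.approx(
                dcor_reference(X[:, q], y.astype(float)), abs=1e-12
            )

    def test_matches_pingouin(self, rng):
        import pingouin

        x = rng.normal(size=24)
        y = np.where(rng.random(24) > 0.5, 1.0, -1.0)
        ours = dcc_scores(x[:, None], y).scores[0]
        theirs = pingouin.distance_corr(x, y, n_boot=None)
        assert ours == pytest.approx(float(theirs), abs=1e-10)

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.where(rng.random(20) > 0.5, 1, -1)
        y[:2] = [1, -1]
        s1 = dcc_scores(X, y).scores
        s2 = dcc_scores(3.7 * X - 11.0, y).scores
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            dcc_scores(rng.normal(size=(3, 2)), np.array([1, -1, 1]))
        with pytest.raises(ValueError):
            dcc_scores(rng.normal(size=(6, 2)), np.ones(6))


class TestSelection:
    def test_select_all_is_permutation(self, rng):
        X = rng.normal(size=(12, 6))
        y = np.array([1, -1] * 6)
        sel = dcc_scores(X, y, W=6)
        out = select_features(sel, X)
        assert sorted(sel.selected_indices.tolist()) == list(range(6))
        np.testing.assert_array_equal(out, X[:, sel.selected_indices])

    def test_w1_picks_label_copy(self):
        y = np.array([1, 1, 1, -1, -1, -1])
        X = np.column_stack([np.random.default_rng(0).normal(size=6), y.astype(float)])
        sel = dcc_scores(X, y, W=1)
        assert sel.selected_indices.tolist() == [1]

    def test_w_clamped_with_warning(self, rng, caplog):
        X = rng.normal(size=(8, 3))
        y = np.array([1, -1] * 4)
        with caplog.at_level("WARNING"):
            sel = dcc_scores(X, y, W=10)
        assert sel.W == 3

    def test_tie_break_prefers_lower_index(self):
        y = np.array([1, 1, -1, -1])
        f = y.astype(float)
        X = np.column_stack([f, f, f])  # identical scores
        sel = dcc_scores(X, y, W=2)
        assert sel.selected_indices.tolist() == [0, 1]

    def test_planted_informative_features_rank_high(self):
        """5 of 50 features carry a class mean shift; they land in the top 10
        in >= 95% of seeded replicates at n=90."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = np.repeat([1, -1], 45)
            X = rng.normal(size=(90, 50))
            X[:, :5] += 1.2 * y[:, None]
            sel = dcc_scores(X, y, W=10)
            if set(range(5)) <= set(sel.selected_indices.tolist()):
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_no_test_fold_leakage(self, rng):
        """Scores are fitted on training data only: test labels cannot move
        the selection."""
        X_train = rng.normal(size=(30, 8))
        y_train = np.array([1, -1] * 15)
        X_train[:, 2] += y_train
        sel = dcc_scores(X_train, y_train, W=3)
        X_test = rng.normal(size=(10, 8))
        out1 = select_features(sel, X_test)
        sel2 = dcc_scores(X_train, y_train, W=3)  # refit, test data untouched
        np.testing.assert_array_equal(sel.selected_indices, sel2.selected_indices)
        np.testing.assert_array_equal(out1, X_test[:, sel.selected_indices])
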