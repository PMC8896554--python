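"""Epoch truncation, cross-validated RDMs, templates, nulls, and selection."""

import numpy as np
import pytest

from latentlearn import rsa
from latentlearn.maxent import analytic_estimate


def make_epochs(rng, n_channels=2, n_trials=60, fs=100.0, rt_range=(0.25, 0.6), labels=None):
    rts = rng.uniform(*rt_range, n_trials)
    n_times = int(np.ceil(rts.max() * fs))
    if labels is None:
        labels = np.tile(np.arange(10), n_trials // 10 + 1)[:n_trials]
    data = rng.standard_normal((n_channels, n_times, n_trials))
    return rsa.EpochArray(data=data, fs=fs, labels=labels, rts=rts)


class TestTruncate:
    def test_common_length_from_shortest_trial(self, rng):
        e = make_epochs(rng, rt_range=(0.25, 0.25), fs=512.0)
        out = rsa.truncate_epochs(e, "stimulus")
        assert out.n_times == 128
        assert out.n_trials == e.n_trials

    def test_200ms_floor_discards_shorter_trials(self, rng):
        e = make_epochs(rng, n_trials=40, rt_range=(0.3, 0.5), fs=100.0)
        e.rts[5] = 0.15  # shorter than the floor
        out = rsa.truncate_epochs(e, "stimulus")
        assert out.n_times == 20  # 200 ms at 100 Hz
        assert out.n_trials == 39

    def test_alignment_sample_selection(self):
        # one 10-sample trial pins L = 10; a second, 14-sample trial shows
        # which of its samples survive under each alignment
        fs = 50.0  # floor is 0.2 * fs = 10 samples as well
        data = np.zeros((1, 14, 2))
        data[0, :, 0] = np.arange(100, 114)  # trial of length 10 (rt 0.2 s)
        data[0, :, 1] = np.arange(14)  # trial of length 14
        e = rsa.EpochArray(data=data, fs=fs, labels=[0, 1], rts=[0.2, 14 / fs])
        stim = rsa.truncate_epochs(e, "stimulus").data[0, :, 1]
        resp = rsa.truncate_epochs(e, "response").data[0, :, 1]
        mid = rsa.truncate_epochs(e, "middle").data[0, :, 1]
        assert np.array_equal(stim, np.arange(10))
        assert np.array_equal(resp, np.arange(4, 14))
        # middle keeps first ceil(L/2) and last floor(L/2) samples
        assert np.array_equal(mid, np.r_[np.arange(5), np.arange(9, 14)])

    def test_all_trials_too_short_errors(self, rng):
        e = make_epochs(rng, n_trials=12, rt_range=(0.10, 0.15), fs=100.0)
        with pytest.raises(ValueError):
            rsa.truncate_epochs(e, "stimulus")


class TestCvRdm:
    def test_noiseless_patterns_give_exact_squared_distances(self, rng):
        patterns = rng.standard_normal((10, 30))
        labels = np.tile(np.arange(10), 4)
        X = patterns[labels]
        D = rsa._cv_rdm_direct(X, labels, 10)
        for a in range(10):
            for b in range(10):
                expected = np.sum((patterns[a] - patterns[b]) ** 2) / 30
                assert np.isclose(D[a, b], expected)

    def test_symmetric_zero_diagonal(self, rng):
        e = rsa.truncate_epochs(make_epochs(rng), "stimulus")
        D = rsa.cv_euclidean_rdm(e, channel=0).values
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_unbiased_for_identical_conditions(self, rng):
        # two conditions with identical generating means: cross-validation
        # makes the expected squared distance zero
        vals = []
        for _ in range(100):
            X = rng.standard_normal((20, 15))
            labels = np.r_[np.zeros(10, int), np.ones(10, int)]
            vals.append(rsa._cv_rdm_direct(X, labels, 2)[0, 1])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    def test_condition_with_single_trial_errors(self, rng):
        e = rsa.truncate_epochs(
            make_epochs(rng, n_trials=21, labels=np.r_[np.tile(np.arange(10), 2), 3]),
            "stimulus",
        )
        e.labels[-1] = 9
        e2 = rsa.EpochArray(
            data=e.data[:, :, :19], fs=e.fs, labels=e.labels[:19], rts=e.rts[:19],
            alignment=e.alignment,
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            rsa.cv_euclidean_rdm(e2, channel=0)

    def test_gram_path_equals_direct_path(self, rng):
        X = rng.standard_normal((50, 12))
        labels = np.tile(np.arange(10), 5)
        idx = [np.nonzero(labels == c)[0] for c in range(10)]
        D_direct = rsa._cv_rdm_direct(X, labels, 10)
        D_gram = rsa._rdm_from_gram(X @ X.T, idx, X.shape[1])
        assert np.allclose(D_direct, D_gram)

    def test_invariant_to_trial_order_when_noiseless(self, rng):
        patterns = rng.standard_normal((10, 20))
        labels = np.tile(np.arange(10), 3)
        X = patterns[labels]
        perm = rng.permutation(len(labels))
        D1 = rsa._cv_rdm_direct(X, labels, 10)
        D2 = rsa._cv_rdm_direct(X[perm], labels[perm], 10)
        assert np.allclose(D1, D2)


class TestTemplateCorr:
    def test_affine_flip_of_similarity_template_gives_plus_one(self, A_mod):
        A_hat = analytic_estimate(A_mod, 1.0)
        d = rsa.DissimilarityMatrix(2.0 - A_hat, polarity="dissimilarity")
        tpl = rsa.latent_template(A_hat)
        assert np.isclose(rsa.template_corr(d, tpl), 1.0)

    def test_constant_template_errors(self, rng):
        d = rsa.DissimilarityMatrix(rng.random((10, 10)))
        tpl = rsa.DissimilarityMatrix(np.ones((10, 10)))
        with pytest.raises(rsa.UndefinedCorrelationError):
            rsa.template_corr(d, tpl)

    def test_matches_brute_force_pearson(self, rng):
        from scipy import stats

        d = rsa.DissimilarityMatrix(rng.random((10, 10)))
        tpl = rsa.DissimilarityMatrix(rng.random((10, 10)))
        xs, ys = [], []
        for i in range(10):
            for j in range(i):
                xs.append(d.values[i, j])
                ys.append(tpl.values[i, j])
        expected = stats.pearsonr(xs, ys).statistic
        assert np.isclose(rsa.template_corr(d, tpl), expected)


class TestCircularShiftNull:
    def test_distribution_length_and_split_support(self, rng, A_mod):
        e = rsa.truncate_epochs(make_epochs(rng, n_trials=80), "stimulus")
        tpl = rsa.latent_template(analytic_estimate(A_mod, 1.0))
        nulls = rsa.circular_shift_null(e, {"latent": tpl}, n_perm=100, seed=4, channel=0)
        assert len(nulls["latent"].correlations) == 100

    def test_zero_shift_reproduces_observed_correlation(self, rng, A_mod):
        e = rsa.truncate_epochs(make_epochs(rng, n_trials=80), "stimulus")
        tpl = rsa.latent_template(analytic_estimate(A_mod, 1.0))
        observed = rsa.template_corr(rsa.cv_euclidean_rdm(e, channel=0), tpl)
        X = rsa._trial_matrix(e, 0)
        idx = rsa._shifted_condition_indices(e.labels, 10, 0)
        D0 = rsa.DissimilarityMatrix(rsa._rdm_from_gram(X @ X.T, idx, X.shape[1]))
        assert np.isclose(rsa.template_corr(D0, tpl), observed)

    def test_shift_relabelling_matches_explicit_data_rotation(self, rng):
        labels = np.tile(np.arange(10), 6)
        T = len(labels)
        X = rng.standard_normal((T, 8))
        s = 17
        rotated = np.roll(X, -s, axis=0)  # data order (s+1..T, 1..s)
        D_explicit = rsa._cv_rdm_direct(rotated, labels, 10)
        idx = rsa._shifted_condition_indices(labels, 10, s)
        D_gram = rsa._rdm_from_gram(X @ X.T, idx, X.shape[1])
        assert np.allclose(D_explicit, D_gram)


class TestSelection:
    def test_below_null_threshold_not_selected(self):
        nulls = [rsa.NullDistribution(np.linspace(0, 1, 100))]
        out = rsa.select_contacts(np.array([0.5]), np.array([0.0]), nulls)
        assert not out["selected_latent"][0]

    def test_exact_space_criterion_blocks_selection(self):
        nulls = [rsa.NullDistribution(np.zeros(100) - 1.0)]
        out = rsa.select_contacts(np.array([0.5]), np.array([0.9]), nulls)
        assert out["null_exceed_count"][0] == 100
        assert not out["selected_latent"][0]

    def test_both_criteria_met_selects(self):
        nulls = [rsa.NullDistribution(np.zeros(100) - 1.0)]
        out = rsa.select_contacts(np.array([0.5]), np.array([0.1]), nulls)
        assert out["selected_latent"][0]


class TestVisualTemplate:
    def test_collinear_unit_spacing(self):
        tpl = rsa.visual_template()
        for i in range(10):
            for j in range(10):
                assert np.isclose(tpl.values[i, j], abs(i - j))

    def test_translation_invariance(self, rng):
        pos = rng.random((10, 2))
        t1 = rsa.visual_template(pos)
        t2 = rsa.visual_template(pos + 5.0)
        assert np.allclose(t1.values, t2.values)

    def test_matches_brute_force_distances_with_permutation(self, rng):
        pos = rng.random((10, 2))
        perm = rng.permutation(10)
        tpl = rsa.visual_template(pos, node_to_stimulus=perm)
        for i in range(10):
            for j in range(10):
                expected = np.linalg.norm(pos[perm[i]] - pos[perm[j]])
                assert np.isclose(tpl.values[i, j], expected)


def test_epoch_hdf5_roundtrip(tmp_path, rng):
    e = make_epochs(rng, n_trials=20)
    path = tmp_path / "epochs.h5"
    e.to_hdf5(path)
    e2 = rsa.EpochArray.from_hdf5(path)
    assert np.array_equal(e.data, e2.data)
    assert np.array_equal(e.labels, e2.labels)
    assert np.allclose(e.rts, e2.rts)
    assert e2.alignment is None
    assert e2.fs == e.fs
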