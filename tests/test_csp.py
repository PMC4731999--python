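"""Multi-class CSP algebra and cross-validated decoding."""

import numpy as np
import pytest
from scipy import linalg

from sclmi.csp import (
    ClassCovariances,
    MultiCSP,
    class_covariances,
    crossval_multicsp,
    csp_features,
    ovr_filters,
    whitening,
)


def _random_trials(rng, n_per_class, n_ch, n_samp, scales=None):
    """Four classes of white noise, optionally variance-scaled per channel."""
    X, y = [], []
    for c in range(4):
        trials = rng.standard_normal((n_per_class, n_ch, n_samp))
        if scales is not None:
            trials *= scales[c][None, :, None]
        X.append(trials)
        y.extend([f"c{c}"] * n_per_class)
    return np.concatenate(X), np.array(y)


class TestClassCovariances:
    def test_trace_normalized_to_one(self):
        rng = np.random.default_rng(0)
        X, y = _random_trials(rng, 5, 6, 100)
        cov = class_covariances(X, y)
        for sigma in cov.sigma.values():
            assert np.trace(sigma) == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(sigma, sigma.T, atol=1e-10)

    def test_white_noise_near_scaled_identity(self):
        rng = np.random.default_rng(1)
        X, y = _random_trials(rng, 70, 8, 500)
        cov = class_covariances(X, y)
        for sigma in cov.sigma.values():
            off = sigma - np.diag(np.diag(sigma))
            assert np.abs(off).max() < 0.02
            assert np.allclose(np.diag(sigma), 1 / 8, atol=0.02)

    def test_duplicating_trials_changes_nothing(self):
        rng = np.random.default_rng(2)
        X, y = _random_trials(rng, 4, 5, 80)
        c1 = class_covariances(X, y)
        c2 = class_covariances(
            np.concatenate([X, X]), np.concatenate([y, y])
        )
        for k in c1.sigma:
            assert np.allclose(c1.sigma[k], c2.sigma[k], atol=1e-12)

    def test_rejects_all_zero_class(self):
        X = np.zeros((4, 3, 50))
        X[2:] = np.random.default_rng(0).standard_normal((2, 3, 50))
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            class_covariances(X, y)


class TestWhitening:
    def test_whitens_composite_covariance(self):
        rng = np.random.default_rng(3)
        X, y = _random_trials(rng, 10, 6, 200)
        cov = class_covariances(X, y)
        P = whitening(cov)
        eye = P @ cov.total() @ P.T
        assert np.abs(eye - np.eye(6)).max() < 1e-8

    def test_scaled_identity_closed_form(self):
        # four identical identity-covariance classes: total = 4 I,
        # so P must be orthonormal rows scaled by 1/2
        cov = ClassCovariances({c: np.eye(4) for c in "abcd"})
        P = whitening(cov)
        assert np.allclose(P @ P.T, np.eye(4) / 4, atol=1e-12)

    def test_two_by_two_diagonal_toy(self):
        cov = ClassCovariances({"a": np.diag([4.0, 1.0])})
        P = whitening(cov)
        # hand eigendecomposition: P = diag(1/2, 1) up to row order and sign
        assert np.allclose(sorted(np.abs(P[P != 0])), [0.5, 1.0])
        assert np.allclose(P @ np.diag([4.0, 1.0]) @ P.T, np.eye(2), atol=1e-12)

    def test_rank_deficiency_rejected_with_count(self):
        rng = np.random.default_rng(4)
        X, y = _random_trials(rng, 6, 5, 100)
        X -= X.mean(axis=1, keepdims=True)  # average reference: rank 4
        cov = class_covariances(X, y)
        with pytest.raises(ValueError, match="1 dimension"):
            whitening(cov)
        P = whitening(cov, on_deficient="reduce")
        assert P.shape == (4, 5)
        assert np.abs(P @ cov.total() @ P.T - np.eye(4)).max() < 1e-8


class TestOvrFilters:
    def test_eigenvalue_pairs_sum_to_one(self):
        rng = np.random.default_rng(5)
        X, y = _random_trials(
            rng, 20, 6, 300,
            scales=[np.array([2.0, 1, 1, 1, 1, 1]),
                    np.array([1, 2.0, 1, 1, 1, 1]),
                    np.array([1, 1, 2.0, 1, 1, 1]),
                    np.array([1, 1, 1, 2.0, 1, 1])],
        )
        cov = class_covariances(X, y)
        P = whitening(cov)
        fs = ovr_filters(cov, P)
        total = cov.total()
        for cls in cov.classes:
            lam = fs.eigenvalues[cls]
            rest = total - cov.sigma[cls]
            U = (fs.filters[cls] @ np.linalg.pinv(P)).T  # recover U_i
            lam_rest = np.diag(U.T @ (P @ rest @ P.T) @ U)
            assert np.allclose(lam + lam_rest, 1.0, atol=1e-10)
            assert np.all(np.diff(lam) <= 1e-12)  # sorted descending

    def test_equal_classes_give_quarter_eigenvalues(self):
        sigma = np.diag([3.0, 2.0, 1.0]) / 6.0
        cov = ClassCovariances({c: sigma.copy() for c in "abcd"})
        fs = ovr_filters(cov, whitening(cov))
        for cls in "abcd":
            assert np.allclose(fs.eigenvalues[cls], 0.25, atol=1e-10)

    def test_two_class_matches_generalized_eigenproblem_oracle(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((6, 6))
        B = rng.standard_normal((6, 6))
        S1 = A @ A.T / np.trace(A @ A.T)
        S2 = B @ B.T / np.trace(B @ B.T)
        cov = ClassCovariances({"a": S1, "b": S2})
        fs = ovr_filters(cov, whitening(cov))
        # classical CSP: eigenvectors of S1 w = lambda (S1 + S2) w
        evals, evecs = linalg.eigh(S1, S1 + S2)
        order = np.argsort(evals)[::-1]
        oracle = evecs[:, order].T
        W = fs.filters["a"]
        for row, orow in zip(W, oracle):
            c = np.abs(np.dot(row, orow)) / (
                np.linalg.norm(row) * np.linalg.norm(orow)
            )
            assert c > 0.999
        assert np.allclose(fs.eigenvalues["a"], np.sort(evals)[::-1], atol=1e-10)

    def test_planted_direction_recovered_in_top_pattern(self):
        rng = np.random.default_rng(7)
        n_ch = 12
        v = rng.standard_normal(n_ch)
        v /= np.linalg.norm(v)
        X, y = _random_trials(rng, 30, n_ch, 400)
        for k in range(30):  # class 0 trials gain variance along v
            X[k] += 3.0 * np.outer(v, rng.standard_normal(400))
        cov = class_covariances(X, y)
        fs = ovr_filters(cov, whitening(cov))
        patterns = np.linalg.pinv(fs.filters["c0"])
        top = patterns[:, 0]
        cos = abs(top @ v) / np.linalg.norm(top)
        assert cos >= 0.95


class TestFeaturesAndCV:
    def test_feature_count_is_classes_times_l(self):
        rng = np.random.default_rng(8)
        X, y = _random_trials(rng, 5, 6, 100)
        csp = MultiCSP(n_filters=1).fit(X, y)
        assert csp.transform(X).shape == (20, 4)
        assert csp_features(X, csp.filters_, 3).shape == (20, 12)

    def test_scaling_trial_shifts_features_by_log100(self):
        rng = np.random.default_rng(9)
        X, y = _random_trials(rng, 5, 6, 100)
        csp = MultiCSP(n_filters=2).fit(X, y)
        f1 = csp.transform(X[:1])
        f2 = csp.transform(10.0 * X[:1])
        assert np.allclose(f2 - f1, np.log(100.0), atol=1e-9)

    def test_filters_invariant_to_channel_rescaling(self):
        """Whitened-space filters absorb any consistent channel rescaling.

        At the covariance level the congruence S -> D S D^T maps filters to
        W D^{-1} exactly (up to sign), so log-variance features are unchanged.
        The full per-trial path additionally trace-normalizes every trial, so
        exact invariance there holds for scalar rescalings.
        """
        rng = np.random.default_rng(10)
        X, y = _random_trials(
            rng, 15, 5, 200,
            scales=[np.array([2.0, 1, 1, 1, 1]), np.array([1, 2.0, 1, 1, 1]),
                    np.array([1, 1, 2.0, 1, 1]), np.array([1, 1, 1, 2.0, 1])],
        )
        # exact: general invertible rescaling at the covariance level
        D = np.diag([0.5, 3.0, 1.0, 7.0, 0.2])
        cov = class_covariances(X, y)
        cov_s = ClassCovariances(
            {k: D @ s @ D.T for k, s in cov.sigma.items()}
        )
        fs = ovr_filters(cov, whitening(cov))
        fs_s = ovr_filters(cov_s, whitening(cov_s, "reduce"))
        Xs = np.einsum("cd,tds->tcs", D, X)
        f1 = csp_features(X, fs, 2)
        f2 = csp_features(Xs, fs_s, 2)
        assert np.allclose(f1, f2, atol=1e-8)
        # exact: scalar rescaling through the full per-trial path
        f_orig = MultiCSP(n_filters=2).fit(X, y).transform(X)
        f_scal = MultiCSP(n_filters=2).fit(2.5 * X, y).transform(2.5 * X)
        assert np.allclose(f_orig + np.log(2.5**2), f_scal, atol=1e-9)

    def test_cv_accuracy_is_exact_fold_mean_and_separates(self):
        rng = np.random.default_rng(11)
        scales = [np.ones(6) for _ in range(4)]
        for c in range(4):
            scales[c] = scales[c].copy()
            scales[c][c] = 3.0
        X, y = _random_trials(rng, 12, 6, 200, scales=scales)
        res = crossval_multicsp((X, y), l_grid=(1, 2), folds=4, seed=0)
        assert res.acc == pytest.approx(res.fold_accuracies.mean())
        assert res.confusion.sum() == len(y)
        assert res.acc > 0.9

    def test_cv_rejects_too_few_trials(self):
        rng = np.random.default_rng(12)
        X, y = _random_trials(rng, 4, 5, 50)
        with pytest.raises(ValueError, match="at least"):
            crossval_multicsp((X, y), folds=10)
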