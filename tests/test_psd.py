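"""Burg spectra, band-power features and grouped SVM-RFE."""

import numpy as np
import pytest

from sclmi.paradigm import condition_timing
from sclmi.preprocessing import EpochArray
from sclmi.generator import NEUROSCAN_64
from sclmi.psd import (
    BANDS,
    GroupedSVMRFE,
    band_powers,
    build_features,
    burg,
    burg_psd,
    grouped_svm_rfe,
    segment_epoch,
)

FS = 200.0


def test_band_definitions():
    assert BANDS["delta"] == (0.5, 4.0)
    assert BANDS["theta"] == (4.0, 8.0)
    assert BANDS["alpha"] == (8.0, 13.0)
    assert BANDS["beta"] == (14.0, 30.0)
    assert BANDS["gamma"] == (30.0, 50.0)
    for lo, hi in BANDS.values():
        assert 0 < lo < hi < FS / 2


class TestSegmentEpoch:
    @pytest.mark.parametrize("L,m", [(600, 5), (1200, 11), (200, 1)])
    def test_segment_counts(self, L, m):
        starts = segment_epoch(L)
        assert len(starts) == m
        assert starts[0] == 0 and np.all(np.diff(starts) == 100)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            segment_epoch(150)


class TestBurg:
    def test_matches_statsmodels_oracle(self):
        from statsmodels.regression.linear_model import burg as sm_burg

        rng = np.random.default_rng(0)
        for _ in range(3):
            x = np.cumsum(rng.standard_normal(300)) + rng.standard_normal(300)
            a, e = burg(x, order=5)
            rho, sigma2 = sm_burg(x - x.mean(), order=5)
            assert np.allclose(a[0, 1:], -rho, atol=1e-10)
            assert e[0] > 0

    def test_vectorized_equals_per_segment(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 200))
        a_batch, e_batch = burg(X)
        for i in range(10):
            a_one, e_one = burg(X[i])
            assert np.allclose(a_batch[i], a_one[0], atol=1e-12)
            assert np.isclose(e_batch[i], e_one[0])

    def test_rejects_constant_segment(self):
        with pytest.raises(ValueError, match="constant"):
            burg(np.ones(200))

    def test_rejects_too_short(self):
        with pytest.raises(ValueError):
            burg(np.arange(4.0), order=5)


class TestBurgPsd:
    def test_sinusoid_peak_in_alpha(self):
        rng = np.random.default_rng(2)
        t = np.arange(200) / FS
        seg = np.sin(2 * np.pi * 10 * t) + 0.05 * rng.standard_normal(200)
        freqs, psd = burg_psd(seg, fs=FS)
        peak = freqs[np.argmax(psd)]
        assert 8.0 <= peak < 13.0
        assert np.all(psd >= 0)

    def test_ar2_resonance_recovered(self):
        # AR(2) poles at radius r, angle 2*pi*f0/fs resonate at ~f0
        rng = np.random.default_rng(3)
        f0, r = 20.0, 0.95
        a1, a2 = 2 * r * np.cos(2 * np.pi * f0 / FS), -(r**2)
        x = np.zeros(1000)
        e = rng.standard_normal(1000)
        for t in range(2, 1000):
            x[t] = a1 * x[t - 1] + a2 * x[t - 2] + e[t]
        freqs, psd = burg_psd(x[200:], fs=FS)
        assert abs(freqs[np.argmax(psd)] - f0) <= 2.0

    def test_white_noise_is_order5_flat(self):
        rng = np.random.default_rng(4)
        segs = rng.standard_normal((100, 200))
        freqs, psd = burg_psd(segs, fs=FS)
        m = (freqs >= 1) & (freqs < 50)
        ratios = psd[:, m].max(axis=1) / psd[:, m].min(axis=1)
        assert np.mean(ratios < 3.0) >= 0.9  # typical per-segment envelope
        pooled = psd[:, m].mean(axis=0)
        assert pooled.max() / pooled.min() < 1.5

    def test_grid_is_one_sided_512(self):
        freqs, psd = burg_psd(np.random.default_rng(0).standard_normal(200))
        assert len(freqs) == 512
        assert freqs[0] == 0.0 and freqs[-1] == FS / 2


class TestBandPowers:
    def test_sinusoid_power_contained_in_alpha(self):
        t = np.arange(200) / FS
        seg = np.sin(2 * np.pi * 10 * t)
        seg += 0.02 * np.random.default_rng(0).standard_normal(200)
        freqs, psd = burg_psd(seg, fs=FS)
        bp = band_powers(psd, freqs)[0]
        total = psd[(freqs >= 0.5) & (freqs < 50)].sum()
        assert bp[2] > 0.8 * total  # alpha band

    def test_white_noise_sums_track_bandwidth(self):
        rng = np.random.default_rng(5)
        segs = rng.standard_normal((200, 200))
        freqs, psd = burg_psd(segs, fs=FS)
        bp = band_powers(psd, freqs).mean(axis=0)
        widths = np.array([hi - lo for lo, hi in BANDS.values()])
        density = bp / widths
        assert density.max() / density.min() < 1.5

    def test_zero_spectrum_gives_zeros(self):
        freqs = np.linspace(0, 100, 512)
        assert np.all(band_powers(np.zeros(512), freqs) == 0)


def _feature_epochs(condition, n_trials=8, seed=0):
    timing = condition_timing(condition)
    rng = np.random.default_rng(seed)
    fs = 200.0
    lo, hi = timing.epoch_window_s
    n = int((hi - lo) * fs)
    labels = list(np.tile(["RRR", "RLR", "LFL", "FRL"], n_trials // 4))
    data = rng.standard_normal((n_trials, 64, n))
    return EpochArray(
        data, lo + np.arange(n) / fs, labels, fs, list(NEUROSCAN_64), timing
    )


class TestBuildFeatures:
    @pytest.mark.parametrize("condition,m,cols", [(1, 5, 1550), (2, 11, 3410)])
    def test_dimensions(self, condition, m, cols):
        ep = _feature_epochs(condition)
        feats = build_features(ep, ep.timing)
        assert feats.m == m
        assert feats.values.shape == (ep.n_trials, cols)
        assert len(feats.channels) == 62
        assert "HEO" not in feats.channels and "VEO" not in feats.channels

    def test_groups_partition_columns(self):
        ep = _feature_epochs(1)
        feats = build_features(ep, ep.timing)
        all_cols = np.concatenate(list(feats.groups.values()))
        assert len(all_cols) == feats.values.shape[1]
        assert len(np.unique(all_cols)) == len(all_cols)
        for cols in feats.groups.values():
            assert len(cols) == 5 * feats.m

    def test_channel_major_layout(self):
        """A channel's columns hold exactly its own segment band powers."""
        ep = _feature_epochs(1)
        feats = build_features(ep, ep.timing)
        ch = "C3"
        i = ep.channel_index(ch)
        mask = ep.time_mask((0.0, 3.0))
        seg = ep.data[0, i, mask][:200]
        freqs, psd = burg_psd(seg, fs=ep.fs)
        expected = band_powers(psd, freqs)[0]
        got = feats.values[0, feats.groups[ch][:5]]
        assert np.allclose(got, expected, atol=1e-10)


class TestGroupedRFE:
    def _toy(self, seed=0, n=40, n_groups=8, block=6, informative=(1, 4)):
        rng = np.random.default_rng(seed)
        y = np.tile(["a", "b", "c", "d"], n // 4)
        X = rng.standard_normal((n, n_groups * block))
        groups = {
            f"g{i}": np.arange(i * block, (i + 1) * block)
            for i in range(n_groups)
        }
        codes = {"a": 0, "b": 1, "c": 2, "d": 3}
        for i in informative:
            X[:, i * block] += [2.0 * codes[c] for c in y]
            X[:, i * block + 1] -= [1.5 * codes[c] for c in y]
        return X, y, groups, [f"g{i}" for i in informative]

    def test_ranking_is_permutation_and_finds_informative(self):
        X, y, groups, info = self._toy()
        rfe = GroupedSVMRFE(groups=groups).fit(X, y)
        assert sorted(rfe.ranking_) == sorted(groups)
        assert set(info) <= set(rfe.ranking_[:3])

    def test_duplicated_informative_group_survives_early_rounds(self):
        X, y, groups, info = self._toy()
        # duplicate the columns of one informative group as a new group
        block = groups[info[0]]
        X2 = np.hstack([X, X[:, block]])
        groups2 = dict(groups)
        groups2["dup"] = np.arange(X.shape[1], X.shape[1] + len(block))
        rfe = GroupedSVMRFE(groups=groups2).fit(X2, y)
        # neither copy is eliminated in the first half of the rounds
        early = rfe.elimination_order_[: len(groups2) // 2]
        assert info[0] not in early and "dup" not in early

    def test_constant_columns_warn_and_are_ignored(self):
        X, y, groups, _ = self._toy()
        X[:, 0] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            rfe = GroupedSVMRFE(groups=groups).fit(X, y)
        assert sorted(rfe.ranking_) == sorted(groups)

    def test_accuracy_curve_and_best_subset(self):
        X, y, groups, info = self._toy(n=60)
        ranking = grouped_svm_rfe(
            type("F", (), {"values": X, "groups": groups,
                           "channels": list(groups), "m": 1})(),
            y, folds=5, seed=0, eval_counts=[1, 2, 4, 8],
        )
        assert len(ranking.accuracy_curve) == 4
        assert ranking.best_result.acc == pytest.approx(
            ranking.best_result.fold_accuracies.mean()
        )
        assert ranking.accuracy_curve.max() > 0.8

    def test_standardization_never_sees_test_folds(self, monkeypatch):
        """Leak canary: every scaler fit happens on a strict training subset."""
        import sclmi.psd as psd_mod
        from sklearn.preprocessing import StandardScaler

        n_seen = []

        class SpyScaler(StandardScaler):
            def fit(self, X, y=None, **kw):
                n_seen.append(X.shape[0])
                return super().fit(X, y, **kw)

        monkeypatch.setattr(psd_mod, "StandardScaler", SpyScaler)
        X, y, groups, _ = self._toy(n=40)
        rfe = GroupedSVMRFE(groups=groups).fit(X, y)
        rfe.accuracy_curve(X, y, [2, 4], folds=5, seed=0)
        assert n_seen, "scaler was never used"
        assert max(n_seen) < len(y)
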