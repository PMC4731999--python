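"""Burg-PSD band-power features and grouped (channel-wise) SVM-RFE.

Each trial's imagery period is cut into 1-s segments with 50% overlap
(200-sample windows shifted by 100 samples at 200 Hz).  Every segment is fed
to an order-5 autoregressive spectral estimator (Burg's method) and summed
over five canonical bands (delta 0.5-4, theta 4-8, alpha 8-13, beta 14-30,
gamma 30-50 Hz), giving 5*m features per channel for the 62 scalp channels
(HEO/VEO excluded).

Channel selection treats all features of one channel as a group: a linear
multiclass SVM is fit repeatedly, the channel with the smallest summed
squared weight is eliminated, and the surviving channels are re-ranked until
exhaustion (SVM-RFE with channel groups).  A tenfold cross-validated accuracy
curve over the top-n channels then locates the optimal channel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .paradigm import ConditionTiming
from .preprocessing import EOG_CHANNELS, EpochArray
from .csp import CVResult

__all__ = [
    "BANDS",
    "PSDFeatureMatrix",
    "ChannelRanking",
    "segment_epoch",
    "burg",
    "burg_psd",
    "band_powers",
    "build_features",
    "GroupedSVMRFE",
    "grouped_svm_rfe",
]

#: Canonical EEG frequency bands (Hz), half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 50.0),
}

BURG_ORDER = 5
SEGMENT_SAMPLES = 200  # 1 s at 200 Hz
SEGMENT_STEP = 100  # 0.5 s
N_FREQ = 512


@dataclass
class PSDFeatureMatrix:
    """Trials x (5 * m * n_channels) band-power feature matrix.

    ``groups`` maps each channel name to its column indices (5 * m columns,
    channel-major layout with segment-then-band minor order).
    """

    values: np.ndarray
    groups: dict[str, np.ndarray]
    m: int
    channels: list[str]
    band_names: tuple[str, ...] = tuple(BANDS)


@dataclass
class ChannelRanking:
    """Outcome of grouped SVM-RFE channel selection."""

    elimination_order: list[str]  # worst channel first
    ranking: list[str]  # best channel first
    eval_counts: np.ndarray
    accuracy_curve: np.ndarray
    best_n: int
    best_channels: list[str]
    best_result: CVResult


def segment_epoch(
    n_samples: int, win: int = SEGMENT_SAMPLES, step: int = SEGMENT_STEP
) -> np.ndarray:
    """Start indices of the m = floor((L - win)/step) + 1 sliding segments."""
    if n_samples < win:
        raise ValueError(
            f"imagery window of {n_samples} samples shorter than a "
            f"{win}-sample segment"
        )
    m = (n_samples - win) // step + 1
    return np.arange(m) * step


def burg(x: np.ndarray, order: int = BURG_ORDER) -> tuple[np.ndarray, np.ndarray]:
    """Burg AR coefficients of one or many segments.

    Parameters: ``x`` of shape (L,) or (n_segments, L).  Returns ``(a, e)``
    where ``a`` holds the AR polynomial coefficients [1, a1..ap] of
    ``x_t + a1 x_{t-1} + ... + ap x_{t-p} = eps_t`` and ``e`` the driving
    variance, per segment.  The recursion runs vectorized over segments.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n_seg, L = x.shape
    if L <= order:
        raise ValueError(f"segment length {L} must exceed the order {order}")
    x = x - x.mean(axis=1, keepdims=True)
    e = (x**2).mean(axis=1)
    if np.any(e <= 0):
        raise ValueError("constant segment: zero-variance process")
    a = np.zeros((n_seg, order + 1))
    a[:, 0] = 1.0
    f, b = x.copy(), x.copy()
    for m in range(1, order + 1):
        fm, bm = f[:, 1:], b[:, :-1]
        den = np.sum(fm**2 + bm**2, axis=1)
        k = -2.0 * np.sum(fm * bm, axis=1) / den
        a_prev = a[:, : m + 1].copy()
        a[:, 1 : m + 1] = a_prev[:, 1:] + k[:, None] * a_prev[:, ::-1][:, 1:]
        f, b = fm + k[:, None] * bm, bm + k[:, None] * fm
        e = e * (1.0 - k**2)
    return a, e


def burg_psd(
    segment: np.ndarray,
    order: int = BURG_ORDER,
    fs: float = 200.0,
    n_freq: int = N_FREQ,
) -> tuple[np.ndarray, np.ndarray]:
    """Burg power spectral density on a one-sided frequency grid.

    Returns ``(freqs, psd)`` with ``psd`` of shape (n_freq,) for a single
    segment or (n_segments, n_freq) for a batch; values are nonnegative by
    construction (driving variance over the squared AR transfer magnitude).
    """
    single = np.asarray(segment).ndim == 1
    a, e = burg(segment, order)
    freqs = np.linspace(0.0, fs / 2.0, n_freq)
    phases = np.exp(-2j * np.pi * np.outer(freqs, np.arange(order + 1)) / fs)
    transfer = a @ phases.T  # (n_seg, n_freq)
    psd = e[:, None] / (np.abs(transfer) ** 2 * fs)
    return freqs, (psd[0] if single else psd)


def band_powers(
    psd: np.ndarray, freqs: np.ndarray, bands: dict[str, tuple[float, float]] = BANDS
) -> np.ndarray:
    """Sum of PSD values at grid points inside each half-open band."""
    psd = np.atleast_2d(psd)
    out = np.empty((psd.shape[0], len(bands)))
    for j, (lo, hi) in enumerate(bands.values()):
        mask = (freqs >= lo) & (freqs < hi)
        out[:, j] = psd[:, mask].sum(axis=1)
    return out


def build_features(
    epochs: EpochArray,
    timing: ConditionTiming | None = None,
    win: int = SEGMENT_SAMPLES,
    step: int = SEGMENT_STEP,
    bands: dict[str, tuple[float, float]] = BANDS,
) -> PSDFeatureMatrix:
    """Band-power feature matrix of the imagery period of every trial.

    Columns are laid out channel-major: for each scalp channel, m segments x
    5 bands (band innermost), so every channel owns a contiguous block of
    ``5 * m`` columns — the groups used by the channel-wise RFE.
    """
    timing = timing or epochs.timing
    if timing is None:
        raise ValueError("build_features needs condition timing")
    keep = [i for i, ch in enumerate(epochs.montage) if ch not in EOG_CHANNELS]
    channels = [epochs.montage[i] for i in keep]
    mask = epochs.time_mask((0.0, timing.imagery_length_s))
    X = epochs.data[:, keep, :][:, :, mask]
    n_trials, n_ch, L = X.shape
    starts = segment_epoch(L, win, step)
    m = len(starts)

    segs = X[:, :, starts[:, None] + np.arange(win)]  # (trials, ch, m, win)
    flat = segs.reshape(-1, win)
    freqs, psd = burg_psd(flat, fs=epochs.fs)
    powers = band_powers(psd, freqs, bands)  # (trials*ch*m, 5)
    values = powers.reshape(n_trials, n_ch, m * len(bands)).reshape(n_trials, -1)

    block = m * len(bands)
    groups = {
        ch: np.arange(i * block, (i + 1) * block) for i, ch in enumerate(channels)
    }
    return PSDFeatureMatrix(values, groups, m, channels, tuple(bands))


class GroupedSVMRFE(BaseEstimator):
    """Channel-group SVM recursive feature elimination.

    Fits a linear one-vs-one multiclass SVM on the (column-standardized)
    surviving features, scores every channel by the sum of squared weights
    over its columns and all binary machines, removes the worst channel, and
    repeats to exhaustion.  ``fit`` stores the full elimination order and the
    best-first ``ranking_``.  Ties are broken by removing the channel that
    comes later in montage order.

    The ranking is computed once on the full data set (the two-stage
    protocol); the accuracy-vs-channel-count curve is then evaluated by
    stratified k-fold CV per candidate count via :meth:`accuracy_curve`, with
    feature standardization refit inside every training fold.
    """

    def __init__(self, groups=None, svm_c: float = 1.0):
        self.groups = groups
        self.svm_c = svm_c

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        groups = dict(self.groups)
        std = X.std(axis=0)
        dead = std == 0
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} constant feature column(s) dropped from "
                "the importance ranking"
            )
        Z = (X - X.mean(axis=0)) / np.where(dead, 1.0, std)
        Z[:, dead] = 0.0
        order = {ch: i for i, ch in enumerate(groups)}
        surviving = list(groups)
        eliminated: list[str] = []
        while len(surviving) > 1:
            cols = np.concatenate([groups[ch] for ch in surviving])
            svm = SVC(kernel="linear", C=self.svm_c)
            svm.fit(Z[:, cols], y)
            w2 = np.zeros(Z.shape[1])
            w2[cols] = (svm.coef_**2).sum(axis=0)
            scores = np.array([w2[groups[ch]].sum() for ch in surviving])
            worst = np.min(scores)
            ties = [ch for ch, s in zip(surviving, scores) if s == worst]
            drop = max(ties, key=lambda ch: order[ch])  # later in montage
            surviving.remove(drop)
            eliminated.append(drop)
        eliminated.extend(surviving)
        self.elimination_order_ = eliminated
        self.ranking_ = eliminated[::-1]
        return self

    def accuracy_curve(
        self,
        X,
        y,
        eval_counts,
        folds: int = 10,
        seed: int = 0,
    ) -> tuple[np.ndarray, CVResult, int]:
        """CV accuracy of the top-n channel subsets for each n in eval_counts."""
        X = np.asarray(X, float)
        y = np.asarray(y)
        groups = dict(self.groups)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accs = []
        classes = np.unique(y)
        best = None
        for n in eval_counts:
            cols = np.concatenate([groups[ch] for ch in self.ranking_[:n]])
            model = Pipeline(
                [("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=self.svm_c))]
            )
            pred = cross_val_predict(model, X[:, cols], y, cv=skf)
            fold_accs = np.array(
                [np.mean(pred[test] == y[test]) for _, test in skf.split(X, y)]
            )
            acc = float(fold_accs.mean())
            accs.append(acc)
            if best is None or acc > best[1].acc:
                conf = confusion_matrix(y, pred, labels=classes)
                best = (int(n), CVResult(fold_accs, acc, conf, int(n)))
        return np.array(accs), best[1], best[0]


def grouped_svm_rfe(
    features: PSDFeatureMatrix,
    labels,
    folds: int = 10,
    seed: int = 0,
    eval_counts=None,
    svm_c: float = 1.0,
) -> ChannelRanking:
    """Rank channels by grouped SVM-RFE and locate the optimal channel count."""
    y = np.asarray(labels)
    rfe = GroupedSVMRFE(groups=features.groups, svm_c=svm_c).fit(
        features.values, y
    )
    if eval_counts is None:
        eval_counts = np.arange(1, len(features.channels) + 1)
    eval_counts = np.asarray(sorted(eval_counts))
    curve, best_result, best_n = rfe.accuracy_curve(
        features.values, y, eval_counts, folds=folds, seed=seed
    )
    return ChannelRanking(
        rfe.elimination_order_,
        rfe.ranking_,
        eval_counts,
        curve,
        best_n,
        rfe.ranking_[:best_n],
        best_result,
    )
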