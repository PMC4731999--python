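"""One-vs-rest multi-class common spatial patterns (CSP) decoding.

For classes i = 1..4 with trial-averaged, trace-normalized covariance
matrices S_i, the composite S = sum_i S_i is whitened by P = L^(-1/2) U0^T
(from S = U0 L U0^T).  For each class, Y_i = P S_i P^T and its one-vs-rest
complement Y_i' = P (S - S_i) P^T share eigenvectors and their eigenvalue
pairs sum to one, so the eigenvectors of Y_i with the largest eigenvalues are
the directions most expressive of class i against the rest.  The projection
matrix W_i = U_i^T P stacks these spatial filters; log variances of the
filtered trials are the classification features, fed to a linear SVM.

`MultiCSP` is a scikit-learn transformer so the decoder composes with
Pipelines and model selection; the module-level functions mirror the
individual algebraic steps and the tenfold cross-validation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .preprocessing import EpochArray

__all__ = [
    "ClassCovariances",
    "SpatialFilterSet",
    "CVResult",
    "class_covariances",
    "whitening",
    "ovr_filters",
    "csp_features",
    "MultiCSP",
    "crossval_multicsp",
]

#: Band-pass applied to epochs before CSP (Hz).
CSP_BAND = (8.0, 30.0)

_RANK_TOL = 1e-10
_VAR_FLOOR = 1e-15


@dataclass
class ClassCovariances:
    """Per-class mean spatial covariance (each trial trace-normalized)."""

    sigma: dict[object, np.ndarray]

    @property
    def classes(self) -> list:
        return list(self.sigma)

    def total(self) -> np.ndarray:
        return np.sum(list(self.sigma.values()), axis=0)


@dataclass
class SpatialFilterSet:
    """Per-class full projection matrices with their eigenvalue order.

    ``filters[i]`` is (channels x channels) with rows sorted by descending
    eigenvalue of Y_i; ``eigenvalues[i]`` holds those eigenvalues.  ``P`` is
    the shared whitening matrix.
    """

    classes: list
    filters: dict[object, np.ndarray]
    eigenvalues: dict[object, np.ndarray]
    P: np.ndarray


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    acc: float
    confusion: np.ndarray
    selected: object  # best number of filters l (or channels n)

    def __post_init__(self) -> None:
        assert np.isclose(self.acc, self.fold_accuracies.mean())


def _as_xy(epochs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(epochs, EpochArray):
        return epochs.data, np.asarray(epochs.labels)
    X, y = epochs
    return np.asarray(X, float), np.asarray(y)


def class_covariances(X: np.ndarray, y: np.ndarray) -> ClassCovariances:
    """Trace-normalized trial covariances averaged within each class."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    sigma = {}
    for cls in np.unique(y):
        trials = X[y == cls]
        if len(trials) < 2:
            raise ValueError(f"class {cls!r} needs at least 2 trials")
        covs = np.einsum("tcs,tds->tcd", trials, trials)
        traces = np.trace(covs, axis1=1, axis2=2)
        if np.any(traces <= 0):
            raise ValueError(f"class {cls!r} contains an all-zero trial")
        sigma[cls] = (covs / traces[:, None, None]).mean(axis=0)
    return ClassCovariances(sigma)


def whitening(cov: ClassCovariances, on_deficient: str = "raise") -> np.ndarray:
    """Whitening matrix P with P * sum_i(S_i) * P^T = I.

    A rank-deficient composite covariance is rejected by default (reporting
    the number of deficient dimensions).  With ``on_deficient="reduce"`` the
    null dimensions are dropped instead and P maps onto the reduced space —
    the standard way to whiten average-referenced data, whose channel mean is
    identically zero (P S P^T = I then holds on the retained subspace).
    """
    total = cov.total()
    evals, evecs = np.linalg.eigh(total)
    keep = evals > _RANK_TOL * evals.max()
    deficient = int(np.sum(~keep))
    if deficient:
        if on_deficient != "reduce":
            raise ValueError(
                f"composite covariance is rank deficient in {deficient} "
                "dimension(s)"
            )
        evals, evecs = evals[keep], evecs[:, keep]
    return (evecs / np.sqrt(evals)).T


def _fix_sign(vectors: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: largest-magnitude entry positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def ovr_filters(cov: ClassCovariances, P: np.ndarray) -> SpatialFilterSet:
    """One-vs-rest spatial filters of every class on the whitened space."""
    filters, eigenvalues = {}, {}
    for cls, sigma in cov.sigma.items():
        Y = P @ sigma @ P.T
        evals, evecs = np.linalg.eigh(Y)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], _fix_sign(evecs[:, order])
        filters[cls] = evecs.T @ P
        eigenvalues[cls] = evals
    return SpatialFilterSet(cov.classes, filters, eigenvalues, P)


def csp_features(
    X: np.ndarray, filters: SpatialFilterSet, l: int
) -> np.ndarray:
    """Log variances of the first l filtered time courses of every class.

    Feature order is class-major: for each class (in ``filters.classes``
    order) the l top-eigenvalue projections, giving ``4 * l`` columns for the
    four-class problem.
    """
    X = np.asarray(X, float)
    n_rows = min(f.shape[0] for f in filters.filters.values())
    if not 1 <= l <= n_rows:
        raise ValueError(f"l must be in [1, {n_rows}], got {l}")
    feats = []
    for cls in filters.classes:
        W = filters.filters[cls][:l]
        proj = np.einsum("fc,tcs->tfs", W, X)
        var = np.maximum(proj.var(axis=-1), _VAR_FLOOR)
        feats.append(np.log(var))
    return np.concatenate(feats, axis=1)


class MultiCSP(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer: one-vs-rest CSP log-variance features.

    Parameters
    ----------
    n_filters : number of top filters l retained per class.
    on_deficient : "reduce" (default) drops null dimensions of the composite
        covariance before whitening — required for average-referenced data —
        while "raise" insists on full rank.

    Fitted attributes: ``covariances_``, ``whitening_``, ``filters_``
    (a :class:`SpatialFilterSet`), ``classes_``.
    """

    def __init__(self, n_filters: int = 2, on_deficient: str = "reduce"):
        self.n_filters = n_filters
        self.on_deficient = on_deficient

    def fit(self, X, y):
        X = np.asarray(X, float)
        if X.ndim != 3:
            raise ValueError("X must be trials x channels x samples")
        self.covariances_ = class_covariances(X, y)
        self.whitening_ = whitening(self.covariances_, self.on_deficient)
        self.filters_ = ovr_filters(self.covariances_, self.whitening_)
        self.classes_ = np.asarray(self.filters_.classes)
        return self

    def transform(self, X):
        return csp_features(X, self.filters_, self.n_filters)


def make_csp_pipeline(l: int, svm_c: float = 1.0) -> Pipeline:
    """CSP + linear SVM decoding pipeline (one-vs-one multiclass)."""
    return Pipeline(
        [
            ("csp", MultiCSP(n_filters=l)),
            ("svm", SVC(kernel="linear", C=svm_c)),
        ]
    )


def crossval_multicsp(
    epochs,
    l_grid: tuple[int, ...] = (1, 2, 3, 4),
    folds: int = 10,
    seed: int = 0,
    svm_c: float = 1.0,
    return_all: bool = False,
):
    """Stratified k-fold CV accuracy with filter-count selection.

    The same fold assignment is reused for every l (paired selection); CSP
    filters and the SVM are fit on each training fold only.  Returns the
    result of the best filter count, with ``acc`` the exact mean of the fold
    accuracies and the confusion matrix aggregated over test folds; with
    ``return_all`` additionally the per-l results.
    """
    X, y = _as_xy(epochs)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"every class needs at least {folds} trials for {folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    l_max = max(l_grid)
    folds_out: dict[int, list] = {l: [] for l in l_grid}
    preds: dict[int, list] = {l: [] for l in l_grid}
    trues = []
    for train, test in splits:
        # filters do not depend on l: fit once per fold, slice features per l
        csp = MultiCSP(n_filters=l_max).fit(X[train], y[train])
        f_train = csp.transform(X[train])
        f_test = csp.transform(X[test])
        n_cls = len(csp.classes_)
        trues.append(y[test])
        for l in l_grid:
            cols = np.concatenate(
                [np.arange(c * l_max, c * l_max + l) for c in range(n_cls)]
            )
            svm = SVC(kernel="linear", C=svm_c)
            svm.fit(f_train[:, cols], y[train])
            pred = svm.predict(f_test[:, cols])
            folds_out[l].append(float(np.mean(pred == y[test])))
            preds[l].append(pred)
    results = {}
    for l in l_grid:
        accs = np.array(folds_out[l])
        conf = confusion_matrix(
            np.concatenate(trues), np.concatenate(preds[l]), labels=classes
        )
        results[l] = CVResult(accs, float(accs.mean()), conf, l)
    best_l = max(results, key=lambda l: results[l].acc)
    best = results[best_l]
    if return_all:
        return best, results
    return best
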