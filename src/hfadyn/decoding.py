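"""Time-resolved pairwise category decoding with shrinkage LDA.

For each pair of categories and each time point, a linear discriminant
classifier is trained on the HFA pattern across electrodes:

    w = Sigma_hat^{-1} (mu_1 - mu_2),
    Sigma_hat = (1 - lambda) Sigma + lambda (trace(Sigma) / p) I,

with the pooled (class-count weighted) covariance Sigma, feature count p,
and shrinkage weight lambda from the Ledoit-Wolf estimator (computed on
training folds only). Performance is the area under the ROC curve (AUC),
computed as a rank statistic with tie correction — equal to the
probability that a random trial of class 1 outranks a random trial of
class 2, and invariant to monotone transforms of the decision values.

Repetitions of the same image are averaged so an exemplar never appears
in both the training and the test set; the larger class is undersampled
(redrawn at each repeat); 5-fold cross-validation is repeated 5 times and
averaged. Temporal generalization trains at each time point and tests at
all time points, yielding a train x test AUC matrix (TGM) whose diagonal
equals the time-resolved AUC under identical folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.covariance import ledoit_wolf_shrinkage

from .containers import TrialTensor
from . import perm_stats

__all__ = [
    "ClassifierModel", "DecodingResult", "prepare_exemplar_trials",
    "fit_shrinkage_lda", "roc_auc", "time_resolved_decoding",
    "temporal_generalization", "decoding_null", "peak_test",
    "generalization_curves",
]


@dataclass
class ClassifierModel:
    """Fitted shrinkage-LDA discriminant for one time point."""

    w: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    cov: np.ndarray
    cov_shrunk: np.ndarray
    lam: float
    classes: tuple

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w


@dataclass
class DecodingResult:
    """AUC time course and/or TGM with the CV scheme that produced it."""

    times_ms: np.ndarray
    auc: np.ndarray | None = None          # (T,)
    tgm: np.ndarray | None = None          # (T_train, T_test)
    n_per_class: int = 0
    cv: str = ""
    clusters: list = field(default_factory=list)
    significant: np.ndarray | None = None

    @property
    def peak_auc(self) -> float:
        return float(np.max(self.auc))

    @property
    def peak_time_ms(self) -> float:
        return float(self.times_ms[int(np.argmax(self.auc))])


# ----------------------------------------------------------------------
# building blocks
# ----------------------------------------------------------------------

def _pooled_cov(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class-centered data and pooled covariance (count-weighted)."""
    Xc = X.copy()
    for c in np.unique(y):
        m = y == c
        Xc[m] -= Xc[m].mean(axis=0)
    n, _ = X.shape
    dof = max(n - len(np.unique(y)), 1)
    return Xc, (Xc.T @ Xc) / dof


def fit_shrinkage_lda(X: np.ndarray, y, lam="auto") -> ClassifierModel:
    """Fit the two-class shrinkage-LDA discriminant.

    ``lam`` is a shrinkage weight in [0, 1] or ``"auto"`` for the
    Ledoit-Wolf estimate. ``lam=1`` shrinks to the scaled identity
    ``(trace(Sigma)/p) I``; ``lam=0`` uses the empirical pooled
    covariance and raises when it is singular. ``trace(Sigma_hat) ==
    trace(Sigma)`` for every ``lam``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(np.unique(y))
    if len(classes) != 2:
        raise ValueError("shrinkage LDA is defined for exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs >= 2 trials")
    if not np.isfinite(X).all():
        raise ValueError("features contain NaN or infinite values")

    Xc, cov = _pooled_cov(X, y)
    p = X.shape[1]
    mu1 = X[y == classes[0]].mean(axis=0)
    mu2 = X[y == classes[1]].mean(axis=0)
    if np.trace(cov) <= 0:
        # all features constant within class (e.g. noiseless baseline):
        # fall back to the means-only discriminant
        return ClassifierModel(w=mu1 - mu2, mu1=mu1, mu2=mu2, cov=cov,
                               cov_shrunk=cov, lam=np.nan, classes=classes)
    if lam == "auto":
        lam_val = float(ledoit_wolf_shrinkage(Xc, assume_centered=True))
    else:
        lam_val = float(lam)
        if not 0.0 <= lam_val <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if lam_val == 0.0 and X.shape[0] - 2 < p:
            raise ValueError(
                "shrunk covariance is singular (p >= n - 1); use "
                "lam='auto' or lam > 0")
    target = (np.trace(cov) / p) * np.eye(p)
    cov_shrunk = (1.0 - lam_val) * cov + lam_val * target
    try:
        w = np.linalg.solve(cov_shrunk, mu1 - mu2)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "shrunk covariance is singular; with p >= n use lam='auto' "
            "or lam > 0") from err
    return ClassifierModel(w=w, mu1=mu1, mu2=mu2, cov=cov,
                           cov_shrunk=cov_shrunk, lam=lam_val,
                           classes=classes)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by the rank statistic (ties count 1/2).

    ``labels`` must contain exactly two values; the lexicographically
    *first* unique value is the positive class, matching the convention
    that LDA decision values ``w.x`` are large for class 1.
    """
    return float(_auc_columns(np.asarray(scores, float)[:, None],
                              np.asarray(labels))[0])


def _auc_columns(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rank AUC along axis 0 for each remaining column of ``scores``."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("AUC requires exactly two label values")
    pos = labels == classes[0]
    n1, n2 = int(pos.sum()), int((~pos).sum())
    shape = scores.shape
    flat = scores.reshape(shape[0], -1)
    ranks = rankdata(flat, axis=0)          # average ranks handle ties
    r1 = ranks[pos].sum(axis=0)
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    return auc.reshape(shape[1:]) if len(shape) > 1 else auc


def prepare_exemplar_trials(t: TrialTensor, pair: tuple[str, str],
                            rng=None, undersample: bool = True,
                            min_duration_ms: float = 900.0):
    """Exemplar-averaged, class-balanced design for one category pair.

    Repetitions of each unique exemplar are averaged into a single trial
    (so no exemplar straddles the train/test split), then the larger
    class is undersampled to the smaller. Returns ``(X, y, exemplar_ids)``
    with ``X`` of shape ``(n, electrodes, times)``.
    """
    rng = np.random.default_rng(rng)
    sub = t.select_trials(
        t.trials["duration_ms"] >= min_duration_ms, category=list(pair))
    if sub.n_trials == 0:
        raise ValueError(f"no trials for pair {pair}")
    X_list, y_list, ex_list = [], [], []
    for (ex, cat), grp in sub.trials.groupby(["exemplar_id", "category"],
                                             sort=True):
        X_list.append(sub.hfa[grp.index.to_numpy()].mean(axis=0))
        y_list.append(cat)
        ex_list.append(ex)
    X = np.stack(X_list, axis=0)
    y = np.asarray(y_list)
    ex_ids = np.asarray(ex_list)
    for cat in pair:
        if (y == cat).sum() == 0:
            raise ValueError(f"category {cat!r} has no exemplars")
    if undersample:
        keep = _undersample_mask(y, rng)
        X, y, ex_ids = X[keep], y[keep], ex_ids[keep]
    return X, y, ex_ids


def _undersample_mask(y: np.ndarray, rng) -> np.ndarray:
    counts = {c: (y == c).sum() for c in np.unique(y)}
    n_min = min(counts.values())
    keep = np.zeros(y.size, dtype=bool)
    for c in counts:
        idx = np.where(y == c)[0]
        keep[rng.choice(idx, size=n_min, replace=False)] = True
    return keep


def _stratified_folds(y: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold index per trial; classes dealt round-robin after shuffling."""
    folds = np.empty(y.size, dtype=int)
    for c in np.unique(y):
        idx = rng.permutation(np.where(y == c)[0])
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


# ----------------------------------------------------------------------
# cross-validated decoding engine
# ----------------------------------------------------------------------

def _cv_auc(X: np.ndarray, y: np.ndarray, n_folds: int, n_repeats: int,
            lam, rng, tgm: bool, undersample_each_repeat: bool):
    """Mean CV AUC over folds and repeats; (T,) or (T, T) when ``tgm``."""
    n, _, T = X.shape
    n_min = min((y == c).sum() for c in np.unique(y))
    if n_min < n_folds:
        warnings.warn(
            f"smallest class has {n_min} exemplars; reducing folds "
            f"from {n_folds} to {n_min}")
        n_folds = max(int(n_min), 2)

    acc = np.zeros((T, T) if tgm else T)
    n_cells = 0
    for _ in range(n_repeats):
        if undersample_each_repeat:
            keep = _undersample_mask(y, rng)
        else:
            keep = np.ones(n, dtype=bool)
        Xr, yr = X[keep], y[keep]
        folds = _stratified_folds(yr, n_folds, rng)
        rep = np.zeros_like(acc)
        for k in range(n_folds):
            te = folds == k
            W = _fit_weights_all_times(Xr[~te], yr[~te], lam)
            if tgm:
                # scores[i, t_train, t_test]
                scores = np.einsum("net,ek->nkt", Xr[te], W)
            else:
                scores = np.einsum("net,et->nt", Xr[te], W)
            rep += _auc_columns(scores, yr[te])
        acc += rep / n_folds
        n_cells = int((yr == yr[0]).sum())
    return acc / n_repeats, n_cells


def _fit_weights_all_times(Xtr: np.ndarray, ytr: np.ndarray, lam
                           ) -> np.ndarray:
    """LDA weights per time point, stacked as ``electrodes x times``."""
    T = Xtr.shape[2]
    W = np.empty((Xtr.shape[1], T))
    for ti in range(T):
        W[:, ti] = fit_shrinkage_lda(Xtr[:, :, ti], ytr, lam=lam).w
    return W


def time_resolved_decoding(t: TrialTensor, pair: tuple[str, str],
                           n_folds: int = 5, n_repeats: int = 5,
                           lam="auto", rng=None,
                           min_duration_ms: float = 900.0) -> DecodingResult:
    """Cross-validated AUC time course for one category pair."""
    rng = np.random.default_rng(rng)
    X, y, _ = prepare_exemplar_trials(t, pair, rng=rng, undersample=False,
                                      min_duration_ms=min_duration_ms)
    auc, n_cells = _cv_auc(X, y, n_folds, n_repeats, lam, rng, tgm=False,
                           undersample_each_repeat=True)
    return DecodingResult(times_ms=t.times_ms, auc=auc, n_per_class=n_cells,
                          cv=f"{n_folds}x{n_repeats}")


def temporal_generalization(t: TrialTensor, pair: tuple[str, str],
                            n_folds: int = 5, n_repeats: int = 5,
                            lam="auto", rng=None,
                            min_duration_ms: float = 900.0) -> DecodingResult:
    """Train x test AUC matrix (TGM); diagonal equals the time-resolved
    AUC for the same fold assignments."""
    rng = np.random.default_rng(rng)
    X, y, _ = prepare_exemplar_trials(t, pair, rng=rng, undersample=False,
                                      min_duration_ms=min_duration_ms)
    tgm, n_cells = _cv_auc(X, y, n_folds, n_repeats, lam, rng, tgm=True,
                           undersample_each_repeat=True)
    return DecodingResult(times_ms=t.times_ms, auc=np.diag(tgm).copy(),
                          tgm=tgm, n_per_class=n_cells,
                          cv=f"{n_folds}x{n_repeats}")


def decoding_null(t: TrialTensor, pair: tuple[str, str],
                  n_perm: int = 1000, n_folds: int = 5, n_repeats: int = 1,
                  lam="auto", rng=None, tgm: bool = False,
                  min_duration_ms: float = 900.0,
                  fold_seed: int = 0) -> perm_stats.PermutationNull:
    """Null AUC distribution by shuffling category labels across trials.

    Each permutation shuffles the exemplar-averaged labels once and reruns
    the full CV with the same fold-assignment seed as the observed run
    (``fold_seed``), which stabilizes the null.
    """
    rng = np.random.default_rng(rng)
    X, y, _ = prepare_exemplar_trials(t, pair, rng=rng, undersample=False,
                                      min_duration_ms=min_duration_ms)

    def stat(perm_labels):
        eng = np.random.default_rng(fold_seed)
        auc, _ = _cv_auc(X, perm_labels, n_folds, n_repeats, lam, eng,
                         tgm=tgm, undersample_each_repeat=True)
        return auc

    return perm_stats.build_null(stat, y, n_perm=n_perm, rng=rng,
                                 scheme="category-shuffle")


def peak_test(observed_auc: np.ndarray, null: perm_stats.PermutationNull
              ) -> float:
    """One-sided p for peak decoding against the null's per-permutation
    peak AUC (max across time points)."""
    axes = tuple(range(1, null.perm_stats.ndim))
    null_peaks = null.perm_stats.max(axis=axes)
    obs = float(np.max(observed_auc))
    return float((1.0 + (null_peaks >= obs).sum()) / (null.n_perm + 1.0))


def generalization_curves(tgm: np.ndarray, times_ms: np.ndarray,
                          block_ms: float = 200.0):
    """Mean generalization time course per training-time block.

    Returns ``(block_edges_ms, curves)`` with ``curves[b]`` the mean over
    training rows falling in block ``b``.
    """
    tgm = np.asarray(tgm, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    edges = np.arange(times_ms[0], times_ms[-1] + block_ms, block_ms)
    curves, spans = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        rows = (times_ms >= lo) & (times_ms < hi)
        if rows.any():
            curves.append(tgm[rows].mean(axis=0))
            spans.append((lo, hi))
    return np.asarray(spans), np.asarray(curves)
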