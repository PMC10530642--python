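"""Exemplar-level representational similarity analysis (RSA).

Representational geometry is summarized per time point by the matrix of
pairwise dissimilarities (RDM) between the electrode-pattern responses to
individual images, using correlation dissimilarity ``1 - r`` or Euclidean
distance. Exemplar coding is considered real only if the geometry is
reliable across two separate repetitions of the same images:

* Item Reliability (IR): for each presentation, the Spearman correlation
  between its dissimilarity vector to all other images *within its own
  repetition* and its dissimilarity vector to all other images *of the
  other repetition*, averaged over images and repetitions. The null
  shuffles the stimulus identities of the other repetition (the anchor is
  never permuted).
* Geometry Reliability (GR): the full 2N x 2N cross-repetition RDM is
  split into two within-repetition triangles and two between-repetition
  triangles; each within set is averaged elementwise with one between set
  (Geometry 1 and Geometry 2), and the two geometry vectors are Spearman
  correlated. The null shuffles the identity of all single exemplars in
  repetition 2.

Because both statistics mix within- and between-repetition
dissimilarities, they are sensitive to preservation of the geometry *and*
of the state-space location; because they are z-scored against identity
shuffles, indistinguishable exemplars reduce them even when the geometry
itself is preserved.

Category structure can be partialed out by replacing the plain Spearman
correlation with a Spearman partial correlation against one of four
category-model RDMs (0 within category, 0.5 between categories sharing a
higher-order group, 1 otherwise). Temporal stability generalizes the
reliability statistics to pairs of time points (t1, t2); the diagonal of
a stability matrix equals the reliability time course.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm, rankdata

from .containers import TrialTensor
from . import perm_stats

__all__ = [
    "ReliabilityResult", "compute_rdm", "repetition_patterns",
    "item_reliability", "geometry_reliability", "reliability_analysis",
    "stability_matrix", "category_model_rdm", "model_correlation_timecourse",
    "spearman_threshold", "strongest_model", "CATEGORY_MODELS",
]

CATEGORIES = ("face", "watch", "object", "animal")

# higher-order groupings: categories in the same group are 50% similar
CATEGORY_MODELS = {
    "single-category": [],
    "low-level": [("face", "watch"), ("object", "animal")],
    "semantic": [("face", "animal"), ("watch", "object")],
    "face-vs-rest": [("watch", "object", "animal")],
}


@dataclass
class ReliabilityResult:
    times_ms: np.ndarray
    metric: str
    ir_raw: np.ndarray | None = None
    ir_z: np.ndarray | None = None
    gr_raw: np.ndarray | None = None
    gr_z: np.ndarray | None = None
    ir_clusters: list = field(default_factory=list)
    gr_clusters: list = field(default_factory=list)
    model: str | None = None       # model partialed out, if any
    n_exemplars: int = 0
    n_perm: int = 0


# ----------------------------------------------------------------------
# building blocks
# ----------------------------------------------------------------------

def compute_rdm(patterns: np.ndarray, metric: str = "correlation"
                ) -> np.ndarray:
    """Pairwise dissimilarity matrix of row patterns.

    ``correlation`` is ``1 - Pearson r`` (range [0, 2]); ``euclidean`` the
    L2 distance. Symmetric with a zero diagonal.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[0] < 2:
        raise ValueError("an RDM needs at least two presentations")
    if metric not in ("correlation", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    d = cdist(patterns, patterns, metric=metric)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def repetition_patterns(t: TrialTensor, min_duration_ms: float = 900.0,
                        categories=CATEGORIES):
    """Response patterns of exemplars seen in both of the first two
    qualifying repetitions.

    Returns ``(P, exemplars)`` with ``P`` of shape ``(2, N, E, T)`` and an
    exemplar table (id, category). Exemplars with more than two
    presentations contribute their first two repetitions.
    """
    sub = t.select_trials(t.trials["duration_ms"] >= min_duration_ms,
                          category=list(categories))
    picks, rows = [], []
    for ex, grp in sub.trials.groupby("exemplar_id", sort=True):
        grp = grp.sort_values("repetition")
        if len(grp) < 2:
            continue
        picks.append((grp.index[0], grp.index[1]))
        rows.append((ex, grp["category"].iloc[0]))
    if len(rows) < 4:
        raise ValueError(
            "need >= 4 exemplars seen at least twice for reliability analysis")
    idx = np.asarray(picks)                    # N x 2 row positions
    P = np.stack([sub.hfa[idx[:, 0]], sub.hfa[idx[:, 1]]], axis=0)
    exemplars = pd.DataFrame(rows, columns=["exemplar_id", "category"])
    return P, exemplars


def _cross_blocks(p1: np.ndarray, p2: np.ndarray, metric: str):
    """Within- and between-repetition dissimilarity blocks at one time."""
    W1 = compute_rdm(p1, metric)
    W2 = compute_rdm(p2, metric)
    B = cdist(p1, p2, metric=metric)
    return W1, W2, B


def _offdiag(M: np.ndarray) -> np.ndarray:
    """Rows of ``M`` with the diagonal element removed -> (N, N-1)."""
    N = M.shape[0]
    return M[~np.eye(N, dtype=bool)].reshape(N, N - 1)


def _rank_rows(M: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis.

    Fast double-argsort path for tie-free rows (the generic case for
    continuous dissimilarities); rows containing ties fall back to
    scipy's average-rank handling.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[-1]
    flat = M.reshape(-1, n)
    order = np.argsort(flat, axis=-1, kind="stable")
    ranks = np.empty_like(flat)
    np.put_along_axis(ranks, order,
                      np.broadcast_to(np.arange(1.0, n + 1.0),
                                      flat.shape).copy(), axis=-1)
    sorted_ = np.take_along_axis(flat, order, axis=-1)
    tied = (np.diff(sorted_, axis=-1) == 0).any(axis=-1)
    if tied.any():
        ranks[tied] = rankdata(flat[tied], axis=-1)
    return ranks.reshape(M.shape)


def _row_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of corresponding rows (last axis)."""
    Ac = A - A.mean(axis=-1, keepdims=True)
    Bc = B - B.mean(axis=-1, keepdims=True)
    num = (Ac * Bc).sum(axis=-1)
    den = np.sqrt((Ac ** 2).sum(axis=-1) * (Bc ** 2).sum(axis=-1))
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def _residualize_rows(R: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residual of each row of ``R`` after regressing on the matching row
    of ``M`` (with intercept)."""
    Rc = R - R.mean(axis=-1, keepdims=True)
    Mc = M - M.mean(axis=-1, keepdims=True)
    var = (Mc ** 2).sum(axis=-1, keepdims=True)
    num = (Rc * Mc).sum(axis=-1, keepdims=True)
    beta = np.divide(num, var, out=np.zeros_like(num),
                     where=np.broadcast_to(var > 0, num.shape))
    return Rc - beta * Mc


def _row_spearman(A: np.ndarray, B: np.ndarray,
                  model: np.ndarray | None = None) -> np.ndarray:
    """Row-wise Spearman (average-rank ties); optionally partial w.r.t.
    the matching rows of ``model``."""
    Ra, Rb = _rank_rows(A), _rank_rows(B)
    if model is None:
        return _row_pearson(Ra, Rb)
    Rm = _rank_rows(model)
    return _row_pearson(_residualize_rows(Ra, Rm), _residualize_rows(Rb, Rm))


# ----------------------------------------------------------------------
# Item Reliability
# ----------------------------------------------------------------------

def _ir_vectors(W1, W2, B):
    """Anchor-wise within/between dissimilarity vectors, shape (2N, N-1).

    Anchors from repetition 1 use rows of W1 against rows of B; anchors
    from repetition 2 use rows of W2 against columns of B.
    """
    A = np.concatenate([_offdiag(W1), _offdiag(W2)], axis=0)
    Bv = np.concatenate([_offdiag(B), _offdiag(B.T)], axis=0)
    return A, Bv


def item_reliability(p1: np.ndarray, p2: np.ndarray,
                     metric: str = "correlation",
                     model_rows: np.ndarray | None = None) -> float:
    """Raw IR at one time point: mean anchor-wise Spearman correlation.

    ``p1``/``p2`` are ``N x electrodes`` patterns of the two repetitions;
    ``model_rows`` (``N x N-1``, the model RDM rows without the diagonal)
    switches to the Spearman partial correlation.
    """
    W1, W2, B = _cross_blocks(np.asarray(p1, float), np.asarray(p2, float),
                              metric)
    if W1.shape[0] < 4:
        raise ValueError("IR requires >= 4 exemplars")
    A, Bv = _ir_vectors(W1, W2, B)
    m = None if model_rows is None else np.tile(model_rows, (2, 1))
    return float(_row_spearman(A, Bv, m).mean())


# ----------------------------------------------------------------------
# Geometry Reliability
# ----------------------------------------------------------------------

def _triu(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def _geometries(W1, W2, B, strategy: str = "average"):
    """Geometry 1 and Geometry 2 vectors from the cross-repetition RDM.

    Default pairing averages the within-repetition-1 triangle elementwise
    with the upper between-repetition triangle, and within-repetition-2
    with the lower (transposed) between triangle. ``strategy="separate"``
    returns the raw set pairs for correlate-then-average.
    """
    w1, w2 = _triu(W1), _triu(W2)
    bu, bl = _triu(B), _triu(B.T)
    if strategy == "average":
        return (w1 + bu) / 2.0, (w2 + bl) / 2.0
    if strategy == "separate":
        return (w1, w2), (bu, bl)
    raise ValueError(f"unknown GR strategy {strategy!r}")


def geometry_reliability(p1: np.ndarray, p2: np.ndarray,
                         metric: str = "correlation",
                         model_vec: np.ndarray | None = None,
                         strategy: str = "average") -> float:
    """Raw GR at one time point: Spearman correlation of the two geometry
    vectors (partial w.r.t. the unfolded model RDM when given)."""
    W1, W2, B = _cross_blocks(np.asarray(p1, float), np.asarray(p2, float),
                              metric)
    if W1.shape[0] < 4:
        raise ValueError("GR requires >= 4 exemplars")
    if strategy == "separate":
        (a1, a2), (b1, b2) = _geometries(W1, W2, B, strategy)
        m = None if model_vec is None else model_vec[None, :]
        r1 = _row_spearman(a1[None, :], a2[None, :], m)[0]
        r2 = _row_spearman(b1[None, :], b2[None, :], m)[0]
        return float((r1 + r2) / 2.0)
    g1, g2 = _geometries(W1, W2, B, strategy)
    m = None if model_vec is None else model_vec[None, :]
    return float(_row_spearman(g1[None, :], g2[None, :], m)[0])


# ----------------------------------------------------------------------
# time courses with permutation z-scores
# ----------------------------------------------------------------------

def _draw_perms(n_exemplars: int, n_perm: int, rng) -> np.ndarray:
    rng = np.random.default_rng(rng)
    return np.stack([rng.permutation(n_exemplars) for _ in range(n_perm)])


def _ir_timecourse(P: np.ndarray, metric: str, perms: np.ndarray,
                   model_rows: np.ndarray | None):
    """Raw IR(t) and the (n_perm, T) identity-shuffle null.

    The same permutation set is applied at every time point to preserve
    the temporal structure. Anchors are never permuted; only the
    other-repetition vector is relabeled.
    """
    _, N, _, T = P.shape
    n_perm = perms.shape[0]
    raw = np.empty(T)
    null = np.empty((n_perm, T))
    m = None if model_rows is None else np.tile(model_rows, (2, 1))
    off = ~np.eye(N, dtype=bool)
    for ti in range(T):
        W1, W2, B = _cross_blocks(P[0, :, :, ti], P[1, :, :, ti], metric)
        A, Bv = _ir_vectors(W1, W2, B)
        raw[ti] = _row_spearman(A, Bv, m).mean()
        Bp_all = _perm_ir_between(B, perms, off)     # (n_perm, 2N, N-1)
        mm = None if m is None else m[None, :, :]
        null[:, ti] = _row_spearman(
            np.broadcast_to(A, Bp_all.shape), Bp_all, mm).mean(axis=-1)
    return raw, null


def _perm_ir_between(B: np.ndarray, perms: np.ndarray, off: np.ndarray
                     ) -> np.ndarray:
    """Other-repetition IR vectors for all permutations at once.

    ``B[:, perms]`` relabels the other repetition; the observed ``j != i``
    positions are kept so the anchor column is never included.
    """
    N = B.shape[0]
    n_perm = perms.shape[0]
    b1 = B[:, perms].transpose(1, 0, 2)[:, off].reshape(n_perm, N, N - 1)
    b2 = B.T[:, perms].transpose(1, 0, 2)[:, off].reshape(n_perm, N, N - 1)
    return np.concatenate([b1, b2], axis=1)


def _gr_timecourse(P: np.ndarray, metric: str, perms: np.ndarray,
                   model_vec: np.ndarray | None, strategy: str = "average"):
    """Raw GR(t) and its exemplar-shuffle null (repetition 2 relabeled)."""
    _, N, _, T = P.shape
    n_perm = perms.shape[0]
    raw = np.empty(T)
    null = np.empty((n_perm, T))
    m = None if model_vec is None else model_vec[None, :]
    iu = np.triu_indices(N, k=1)
    for ti in range(T):
        W1, W2, B = _cross_blocks(P[0, :, :, ti], P[1, :, :, ti], metric)
        g1, g2 = _geometries(W1, W2, B)
        raw[ti] = _row_spearman(g1[None, :], g2[None, :], m)[0]
        # relabel repetition 2 for all permutations at once
        W2p = W2[perms[:, :, None], perms[:, None, :]]   # n_perm x N x N
        Bp = B[:, perms].transpose(1, 0, 2)              # n_perm x N x N
        g1p = (_triu(W1)[None, :] + Bp[:, iu[0], iu[1]]) / 2.0
        g2p = (W2p[:, iu[0], iu[1]] +
               Bp.transpose(0, 2, 1)[:, iu[0], iu[1]]) / 2.0
        null[:, ti] = _row_spearman(g1p, g2p, m)
    return raw, null


def _z_and_clusters(raw, null, threshold_z, alpha):
    pnull = perm_stats.PermutationNull(null, scheme="identity-shuffle")
    z = pnull.zscore(raw)
    zn = pnull.perm_z
    clusters = perm_stats.cluster_test(z, zn, threshold=threshold_z,
                                       tail="greater", alpha=alpha)
    return z, [c for c in clusters]


def reliability_analysis(t: TrialTensor,
                         metric: str = "correlation",
                         n_perm: int = 1000,
                         rng=None,
                         model: str | None = None,
                         cluster_threshold_z: float = 1.5,
                         alpha: float = 0.05,
                         min_duration_ms: float = 900.0
                         ) -> ReliabilityResult:
    """IR and GR time courses, permutation z-scores and significant
    clusters for one (region-restricted) tensor.

    ``model`` names a category model from :data:`CATEGORY_MODELS` to
    partial out; the same permutation nulls are applied to the partialed
    statistic. The cluster-forming threshold is in z units (1.5 for 50-ms
    smoothing; 0.75 is the paired choice for 100-ms-smoothed
    single-category analyses).
    """
    P, exemplars = repetition_patterns(t, min_duration_ms=min_duration_ms)
    N = len(exemplars)
    perms = _draw_perms(N, n_perm, rng)

    model_rows = model_vec = None
    model_rdm = None
    if model is not None:
        model_rdm = category_model_rdm(model, exemplars["category"])
        model_rows = _offdiag(model_rdm)
        model_vec = _triu(model_rdm)

    ir_raw, ir_null = _ir_timecourse(P, metric, perms, model_rows)
    gr_raw, gr_null = _gr_timecourse(P, metric, perms, model_vec)
    ir_z, ir_clusters = _z_and_clusters(ir_raw, ir_null,
                                        cluster_threshold_z, alpha)
    gr_z, gr_clusters = _z_and_clusters(gr_raw, gr_null,
                                        cluster_threshold_z, alpha)
    return ReliabilityResult(times_ms=t.times_ms, metric=metric,
                             ir_raw=ir_raw, ir_z=ir_z, gr_raw=gr_raw,
                             gr_z=gr_z, ir_clusters=ir_clusters,
                             gr_clusters=gr_clusters, model=model,
                             n_exemplars=N, n_perm=n_perm)


# ----------------------------------------------------------------------
# temporal stability
# ----------------------------------------------------------------------

def stability_matrix(t_or_P, metric: str = "IR",
                     dissimilarity: str = "correlation",
                     n_perm: int = 200, rng=None,
                     time_step: int = 1,
                     min_duration_ms: float = 900.0) -> dict:
    """T x T stability of the representation across time-point pairs.

    Entry (t1, t2) correlates the within-repetition structure at t1 with
    the other-repetition structure at t2, so at least one side of every
    comparison crosses repetitions and spontaneous temporally correlated
    fluctuations cannot inflate it. The diagonal equals the corresponding
    reliability time course. Returns ``{"times_ms", "raw", "z"}``.
    """
    if isinstance(t_or_P, TrialTensor):
        P, _ = repetition_patterns(t_or_P, min_duration_ms=min_duration_ms)
        times = t_or_P.times_ms
    else:
        P, times = t_or_P, np.arange(t_or_P.shape[-1], dtype=float)
    sel = np.arange(0, P.shape[-1], time_step)
    P = P[:, :, :, sel]
    times = times[sel]
    _, N, _, T = P.shape
    perms = _draw_perms(N, n_perm, rng)
    off = ~np.eye(N, dtype=bool)

    if metric.upper() == "IR":
        # per time: ranked anchor (within) and other-rep vectors
        rank_A = np.empty((T, 2 * N, N - 1))
        rank_B = np.empty((T, 2 * N, N - 1))
        rank_Bp = np.empty((n_perm, T, 2 * N, N - 1))
        for ti in range(T):
            W1, W2, B = _cross_blocks(P[0, :, :, ti], P[1, :, :, ti],
                                      dissimilarity)
            A, Bv = _ir_vectors(W1, W2, B)
            rank_A[ti] = _rank_rows(A)
            rank_B[ti] = _rank_rows(Bv)
            rank_Bp[:, ti] = _rank_rows(_perm_ir_between(B, perms, off))
        raw = _stability_from_ranks(rank_A, rank_B)           # T x T
        null = np.stack([_stability_from_ranks(rank_A, rank_Bp[k])
                         for k in range(n_perm)])
    elif metric.upper() == "GR":
        L = N * (N - 1) // 2
        iu = np.triu_indices(N, k=1)
        g1 = np.empty((T, L))
        g2 = np.empty((T, L))
        g1p = np.empty((n_perm, T, L))
        g2p = np.empty((n_perm, T, L))
        for ti in range(T):
            W1, W2, B = _cross_blocks(P[0, :, :, ti], P[1, :, :, ti],
                                      dissimilarity)
            a, b = _geometries(W1, W2, B)
            g1[ti], g2[ti] = a, b
            W2p = W2[perms[:, :, None], perms[:, None, :]]
            Bp = B[:, perms].transpose(1, 0, 2)
            g1p[:, ti] = (_triu(W1)[None, :] + Bp[:, iu[0], iu[1]]) / 2.0
            g2p[:, ti] = (W2p[:, iu[0], iu[1]] +
                          Bp.transpose(0, 2, 1)[:, iu[0], iu[1]]) / 2.0
        r1 = _rank_rows(g1)
        raw = _pairwise_pearson(r1, _rank_rows(g2))
        null = np.stack([_pairwise_pearson(_rank_rows(g1p[k]),
                                           _rank_rows(g2p[k]))
                         for k in range(n_perm)])
    else:
        raise ValueError("metric must be 'IR' or 'GR'")

    pnull = perm_stats.PermutationNull(null, scheme="identity-shuffle")
    return {"times_ms": times, "raw": raw, "z": pnull.zscore(raw),
            "null": pnull}


def _stability_from_ranks(rank_A: np.ndarray, rank_B: np.ndarray
                          ) -> np.ndarray:
    """Mean anchor-wise Pearson of ranks across (t1, t2) pairs."""
    Ac = rank_A - rank_A.mean(axis=-1, keepdims=True)
    Bc = rank_B - rank_B.mean(axis=-1, keepdims=True)
    na = np.sqrt((Ac ** 2).sum(axis=-1))
    nb = np.sqrt((Bc ** 2).sum(axis=-1))
    num = np.einsum("tan,san->tsa", Ac, Bc)
    den = na[:, None, :] * nb[None, :, :]
    corr = np.zeros_like(num)
    np.divide(num, den, out=corr, where=den > 0)
    return corr.mean(axis=-1)


def _pairwise_pearson(RA: np.ndarray, RB: np.ndarray) -> np.ndarray:
    """(T1, T2) Pearson between rows of RA and rows of RB."""
    Ac = RA - RA.mean(axis=-1, keepdims=True)
    Bc = RB - RB.mean(axis=-1, keepdims=True)
    na = np.linalg.norm(Ac, axis=-1)
    nb = np.linalg.norm(Bc, axis=-1)
    num = Ac @ Bc.T
    den = np.outer(na, nb)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


# ----------------------------------------------------------------------
# category models
# ----------------------------------------------------------------------

def category_model_rdm(model: str, categories) -> np.ndarray:
    """Model RDM: 0 within category, 0.5 between categories sharing a
    higher-order group, 1 otherwise.

    Models: ``single-category`` (no grouping), ``low-level`` ({face,
    watch} vs {object, animal}), ``semantic`` ({face, animal} vs {watch,
    object}), ``face-vs-rest`` ({watch, object, animal} grouped).
    """
    if model not in CATEGORY_MODELS:
        raise ValueError(f"unknown model {model!r}; "
                         f"choose from {sorted(CATEGORY_MODELS)}")
    cats = np.asarray(list(categories))
    unknown = set(cats) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {unknown}")
    group = {}
    for g, members in enumerate(CATEGORY_MODELS[model]):
        for c in members:
            group[c] = g
    n = cats.size
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if cats[i] == cats[j]:
                out[i, j] = 0.0
            elif group.get(cats[i], -1) == group.get(cats[j], -2):
                out[i, j] = 0.5
    return out


def spearman_threshold(n_pairs: int, alpha: float = 0.05) -> float:
    """Cluster-forming correlation threshold: the one-sided normal
    approximation ``z(1-alpha) / sqrt(n_pairs)`` (0.0391 for the 1,770
    pairs of a 60-image geometry at alpha = 0.05)."""
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    return float(norm.ppf(1.0 - alpha) / np.sqrt(n_pairs))


def model_correlation_timecourse(t: TrialTensor, model: str,
                                 metric: str = "correlation",
                                 n_perm: int = 1000, rng=None,
                                 alpha: float = 0.05,
                                 min_duration_ms: float = 900.0) -> dict:
    """Spearman rho(t) between the neural RDM and a category model, with
    cluster significance at the analytic first-level threshold.

    The neural RDM per time point averages the two within-repetition
    RDMs; the null shuffles exemplar identities (same shuffle for both
    repetitions and all time points).
    """
    P, exemplars = repetition_patterns(t, min_duration_ms=min_duration_ms)
    N = len(exemplars)
    model_vec = _triu(category_model_rdm(model, exemplars["category"]))
    rank_m = _rank_rows(model_vec[None, :])
    perms = _draw_perms(N, n_perm, rng)
    T = P.shape[-1]

    tri = np.triu_indices(N, k=1)
    neural = np.empty((T, tri[0].size))
    for ti in range(T):
        W1 = compute_rdm(P[0, :, :, ti], metric)
        W2 = compute_rdm(P[1, :, :, ti], metric)
        neural[ti] = ((W1 + W2) / 2.0)[tri]
    rank_n = _rank_rows(neural)
    rho = _row_pearson(rank_n, np.repeat(rank_m, T, axis=0))

    null = np.empty((n_perm, T))
    for k in range(n_perm):
        pi = perms[k]
        mv = _triu(category_model_rdm(
            model, exemplars["category"].to_numpy()[pi]))
        rm = _rank_rows(mv[None, :])
        null[k] = _row_pearson(rank_n, np.repeat(rm, T, axis=0))

    thr = spearman_threshold(tri[0].size, alpha)
    clusters = perm_stats.cluster_test(rho, null, threshold=thr,
                                       tail="greater", alpha=alpha)
    return {"times_ms": t.times_ms, "rho": rho, "threshold": thr,
            "clusters": clusters, "model": model}


def strongest_model(t: TrialTensor, models=tuple(CATEGORY_MODELS),
                    metric: str = "correlation",
                    window_ms: tuple = (100.0, 900.0),
                    min_duration_ms: float = 900.0) -> str:
    """Model whose RDM correlates most with the neural RDM on average
    within ``window_ms`` (used to pick the strictest control model)."""
    best, best_val = None, -np.inf
    for m in models:
        res = model_correlation_timecourse(
            t, m, metric=metric, n_perm=1, rng=0,
            min_duration_ms=min_duration_ms)
        wmask = (res["times_ms"] >= window_ms[0]) & \
            (res["times_ms"] < window_ms[1])
        val = float(res["rho"][wmask].mean())
        if val > best_val:
            best, best_val = m, val
    return best
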