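"""Permutation inference shared by all analyses.

Implements the label-shuffle null machinery used throughout the package:

* :func:`build_null` — evaluate a statistic under ``N_perm`` label shuffles,
  keeping the *same* shuffled assignment for every time point (or TGM cell)
  within one permutation so the temporal structure of the data is preserved.
* :func:`max_stat_test` — family-wise control via the distribution of the
  maximal column-z-scored statistic across time points. Observed and
  permuted statistics are standardized with the same column means/SDs,
  since under the null hypothesis they come from the same distribution.
* :func:`cluster_test` — cluster-based permutation correction: contiguous
  supra-threshold samples (1-D spans, or 4-connected components for
  train x test matrices) are summarized by the sum of their values and
  compared with the null distribution of the maximal cluster mass.
* :func:`fdr_bh` — Benjamini-Hochberg step-up false-discovery control.

p values follow the convention that the observed statistic is a member of
its own null distribution, so the smallest attainable p is
``1 / (N_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationNull", "ClusterRecord", "build_null", "zscore_observed",
    "max_stat_test", "cluster_test", "fdr_bh",
]


@dataclass
class PermutationNull:
    """Null distribution of a (possibly multi-dimensional) statistic.

    ``perm_stats`` has shape ``(n_perm, *stat_shape)``; z-scoring is per
    statistic entry ("column") over permutations. Columns with zero SD
    yield z = 0 rather than NaN.
    """

    perm_stats: np.ndarray
    scheme: str = "label-shuffle"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.perm_stats = np.asarray(self.perm_stats, dtype=float)
        if self.perm_stats.ndim < 2:
            self.perm_stats = self.perm_stats[:, None]

    @property
    def n_perm(self) -> int:
        return self.perm_stats.shape[0]

    @property
    def stat_shape(self) -> tuple:
        return self.perm_stats.shape[1:]

    @property
    def col_mean(self) -> np.ndarray:
        return self.perm_stats.mean(axis=0)

    @property
    def col_sd(self) -> np.ndarray:
        return self.perm_stats.std(axis=0)

    def zscore(self, stats: np.ndarray) -> np.ndarray:
        """Standardize ``stats`` with the null's column means and SDs."""
        stats = np.asarray(stats, dtype=float)
        sd = self.col_sd
        out = np.zeros_like(stats, dtype=float)
        np.divide(stats - self.col_mean, sd, out=out, where=sd > 0)
        return out

    @property
    def perm_z(self) -> np.ndarray:
        return self.zscore(self.perm_stats)

    @property
    def max_z(self) -> np.ndarray:
        """Maximal z per permutation across all statistic entries."""
        axes = tuple(range(1, self.perm_stats.ndim))
        return self.perm_z.max(axis=axes)

    def save(self, path) -> None:
        """Cache the null matrix to an HDF5 container."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("perm_stats", data=self.perm_stats)
            f.attrs["scheme"] = self.scheme
            f.attrs["seed"] = -1 if self.seed is None else int(self.seed)

    @classmethod
    def load(cls, path) -> "PermutationNull":
        import h5py

        with h5py.File(path, "r") as f:
            seed = int(f.attrs["seed"])
            return cls(perm_stats=f["perm_stats"][()],
                       scheme=str(f.attrs["scheme"]),
                       seed=None if seed < 0 else seed)


@dataclass
class ClusterRecord:
    """One contiguous supra-threshold cluster and its permutation p value."""

    indices: np.ndarray          # (n_members, ndim) integer index array
    mask: np.ndarray             # boolean mask over the statistic's shape
    stat: float                  # sum of member values (signed)
    p: float = np.nan

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass
class MaxStatResult:
    z: np.ndarray
    critical_z: float
    significant: np.ndarray
    p: np.ndarray
    null: PermutationNull = field(repr=False, default=None)


def build_null(statistic_fn: Callable[[np.ndarray], np.ndarray],
               labels: Sequence,
               n_perm: int = 1000,
               rng: np.random.Generator | int | None = None,
               scheme: str = "label-shuffle") -> PermutationNull:
    """Evaluate ``statistic_fn`` under ``n_perm`` label shuffles.

    ``statistic_fn`` receives a permuted copy of ``labels`` and must return
    the statistic (scalar, time series or matrix) computed on the data it
    closes over. One shuffled assignment is drawn per permutation and
    applied to all time points by construction, because the statistic
    function sees a single label vector.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    rows = []
    for _ in range(n_perm):
        rows.append(np.asarray(statistic_fn(rng.permutation(labels)),
                               dtype=float))
    return PermutationNull(np.stack(rows, axis=0), scheme=scheme)


def zscore_observed(null: PermutationNull, observed: np.ndarray) -> np.ndarray:
    return null.zscore(observed)


def max_stat_test(null: PermutationNull, observed: np.ndarray,
                  alpha: float = 0.05) -> MaxStatResult:
    """One-sided max-statistic test at family-wise level ``alpha``.

    The observed statistic is z-scored with the null's column means/SDs;
    points whose z exceeds the ``1 - alpha`` quantile of the per-permutation
    maximal z are significant. Pointwise p values use the +1 convention.
    """
    if null.n_perm < 100:
        raise ValueError("max-statistic test requires >= 100 permutations")
    z = null.zscore(observed)
    max_z = null.max_z
    # "larger than (1 - alpha) of the null": strictly exceed the
    # ceil((1 - alpha) * N)-th order statistic, no interpolation
    critical = float(np.quantile(max_z, 1.0 - alpha, method="higher"))
    significant = z > critical
    p = (1.0 + (max_z[(...,) + (None,) * z.ndim] >= z).sum(axis=0)) \
        / (null.n_perm + 1.0)
    return MaxStatResult(z=z, critical_z=critical, significant=significant,
                         p=p, null=null)


# ----------------------------------------------------------------------
# cluster-based permutation correction
# ----------------------------------------------------------------------

def _clusters_onesided(values: np.ndarray, threshold: float,
                       sign: int) -> list[tuple[np.ndarray, float]]:
    """Connected components of ``sign * values >= threshold``.

    2-D inputs use 4-connectivity (shared edge) over both axes.
    Returns ``(mask, signed cluster sum)`` per component.
    """
    supra = (sign * values) >= threshold
    structure = ndimage.generate_binary_structure(values.ndim, 1)
    lab, n = ndimage.label(supra, structure=structure)
    out = []
    for k in range(1, n + 1):
        mask = lab == k
        out.append((mask, float(values[mask].sum())))
    return out


def _max_cluster_mass(values: np.ndarray, threshold: float,
                      tail: str) -> float:
    masses = []
    if tail in ("greater", "two-sided"):
        masses += [abs(s) for _, s in _clusters_onesided(values, threshold, 1)]
    if tail in ("less", "two-sided"):
        masses += [abs(s) for _, s in _clusters_onesided(values, threshold, -1)]
    return max(masses) if masses else 0.0


def cluster_test(observed: np.ndarray,
                 null: PermutationNull | np.ndarray,
                 threshold: float,
                 tail: str = "greater",
                 alpha: float = 0.05) -> list[ClusterRecord]:
    """Cluster-based permutation test.

    Parameters
    ----------
    observed
        Statistic in its native units (AUC, AUC difference, z, rho), 1-D
        time series or 2-D train x test matrix.
    null
        Permutation statistics of the same shape (``PermutationNull`` or a
        raw ``(n_perm, ...)`` array). For each permutation only the maximal
        cluster mass is retained.
    threshold
        First-level threshold in the statistic's units (e.g. AUC 0.60,
        AUC-difference 0.10, z 1.5 or 0.75, rho 0.0391).
    tail
        ``"greater"`` (default), ``"less"`` or ``"two-sided"``. Two-sided
        tests cluster positive and negative excursions separately and
        compare absolute cluster masses.

    Returns the observed clusters (possibly empty) with permutation p
    values; clusters with ``p <= alpha`` are significant.
    """
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    observed = np.asarray(observed, dtype=float)
    perm = null.perm_stats if isinstance(null, PermutationNull) else \
        np.asarray(null, dtype=float)
    if perm.shape[1:] != observed.shape:
        raise ValueError("null statistics do not match the observed shape")

    null_max = np.array([_max_cluster_mass(row, threshold, tail)
                         for row in perm])
    records: list[ClusterRecord] = []
    signs = {"greater": (1,), "less": (-1,), "two-sided": (1, -1)}[tail]
    for sign in signs:
        for mask, stat in _clusters_onesided(observed, threshold, sign):
            p = (1.0 + (null_max >= abs(stat)).sum()) / (len(null_max) + 1.0)
            records.append(ClusterRecord(
                indices=np.argwhere(mask), mask=mask, stat=stat, p=float(p)))
    records.sort(key=lambda r: r.indices[0].tolist() if r.size else [0])
    return records


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p values must lie in [0, 1]")
    flat = pvals.ravel()
    reject, _, _, _ = multipletests(flat, alpha=q, method="fdr_bh")
    return reject.reshape(pvals.shape)
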