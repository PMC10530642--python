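"""Minimal visualization helpers (matplotlib).

PCA is used here solely for display: trajectories are condition averages
projected on 3 principal components fit on the concatenated states; no
inference depends on this projection.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

from .containers import Trajectory


def pca_trajectories(trajs: list[Trajectory], n_components: int = 3):
    """Project condition trajectories to a shared PC space.

    Returns ``(projected, pca)`` with ``projected[k]`` of shape
    ``n_components x n_times``.
    """
    stacked = np.concatenate([tr.states.T for tr in trajs], axis=0)
    pca = PCA(n_components=n_components)
    pca.fit(stacked)
    return [pca.transform(tr.states.T).T for tr in trajs], pca


def plot_state_space(trajs: list[Trajectory], labels=None, ax=None):
    """3-D PC trajectory plot; line darkness encodes time."""
    import matplotlib.pyplot as plt

    proj, _ = pca_trajectories(trajs, n_components=3)
    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    for k, p in enumerate(proj):
        label = labels[k] if labels else None
        ax.plot(p[0], p[1], p[2], label=label)
    if labels:
        ax.legend()
    return ax


def plot_tgm(tgm: np.ndarray, times_ms: np.ndarray, ax=None,
             vmin: float = 0.3, vmax: float = 1.0):
    """Temporal generalization matrix (train time on the y axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = [times_ms[0], times_ms[-1], times_ms[0], times_ms[-1]]
    im = ax.imshow(tgm, origin="lower", extent=extent, vmin=vmin, vmax=vmax,
                   cmap="RdBu_r", aspect="auto")
    ax.set_xlabel("test time (ms)")
    ax.set_ylabel("train time (ms)")
    plt.colorbar(im, ax=ax, label="AUC")
    return ax
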