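"""Multivariate state-space trajectory metrics and their inference.

The neural state at time t is the vector of HFA responses across the
electrodes of a region; a trajectory is the condition-averaged sequence
of states. Scalar summaries:

* distance from baseline  ``||s_t||``  (trials are baseline-corrected, so
  the prestimulus state is the origin),
* transition speed  ``||s_t - s_{t-1}||``  per ms,
* distance between two condition trajectories  ``||s1_t - s2_t||``,
* category selectivity index  ``sqrt(mean_C ||s_Ct - mean_C(s_Ct)||^2)``,
  the multivariate analogue of a standard deviation across categories.

Duration effects are tested by shuffling duration labels across trials and
applying the max-statistic correction (perm_stats); confidence intervals
come from a jackknife that drops one trial per patient and condition.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .containers import TrialTensor, Trajectory, check_same_electrodes
from . import perm_stats

__all__ = [
    "condition_trajectory", "baseline_distance", "transition_speed",
    "trajectory_distance", "category_selectivity_index", "duration_test",
    "jackknife_ci",
]


def condition_trajectory(t: TrialTensor, mask=None, **filters) -> Trajectory:
    """Mean over trials matching the condition filter, per electrode/time."""
    sub = t.select_trials(mask=mask, **filters)
    if sub.n_trials == 0:
        raise ValueError(f"no trials match condition {filters!r}")
    return Trajectory(states=sub.hfa.mean(axis=0), times_ms=sub.times_ms,
                      condition=dict(filters),
                      electrode_ids=sub.electrodes["electrode_id"].to_numpy())


def baseline_distance(traj: Trajectory) -> np.ndarray:
    """L2 norm of the state vector per time point (distance from baseline)."""
    return np.linalg.norm(traj.states, axis=0)


def transition_speed(traj: Trajectory, per_ms: bool = True) -> np.ndarray:
    """Distance traveled per step ``||s_t - s_{t-1}||``.

    With ``per_ms=True`` (default) the step distances are rescaled to a
    1-ms base when the time axis is decimated. First sample is 0.
    """
    steps = np.diff(traj.times_ms)
    if steps.size and not np.allclose(steps, steps[0]):
        raise ValueError("transition speed requires a uniform time axis")
    d = np.linalg.norm(np.diff(traj.states, axis=1), axis=0)
    if per_ms and steps.size:
        d = d / steps[0]
    return np.concatenate([[0.0], d])


def trajectory_distance(a: Trajectory, b: Trajectory) -> np.ndarray:
    """Point-by-point Euclidean distance between two trajectories."""
    check_same_electrodes(a, b)
    return np.linalg.norm(a.states - b.states, axis=0)


def category_selectivity_index(trajs: Sequence[Trajectory]) -> np.ndarray:
    """Dispersion of category trajectories around their common mean.

    ``sqrt(mean_C ||s_Ct - mean_C(s_Ct)||^2)`` per time point; invariant
    to adding a common time-varying offset to every category.
    """
    if len(trajs) < 2:
        raise ValueError("selectivity index requires >=2 categories")
    for other in trajs[1:]:
        check_same_electrodes(trajs[0], other)
    stack = np.stack([tr.states for tr in trajs], axis=0)  # C x E x T
    centered = stack - stack.mean(axis=0, keepdims=True)
    return np.sqrt((centered ** 2).sum(axis=1).mean(axis=0))


def _duration_distance_stat(hfa: np.ndarray, durations: np.ndarray,
                            pair: tuple) -> np.ndarray:
    short, long_ = pair
    m1 = hfa[durations == long_].mean(axis=0)
    m0 = hfa[durations == short].mean(axis=0)
    return np.linalg.norm(m1 - m0, axis=0)


def duration_test(t: TrialTensor,
                  dur_pair: tuple = (300, 900),
                  window_ms: tuple | None = None,
                  n_perm: int = 1000,
                  alpha: float = 0.05,
                  rng=None) -> perm_stats.MaxStatResult:
    """Max-statistic permutation test for a duration effect.

    The statistic is the trajectory distance between the two duration
    conditions; the null shuffles duration labels across trials (one
    shuffle per permutation, applied to all time points). By default the
    test window is restricted to ``[short, long]`` ms, where a difference
    can exist while only one stimulus remains on screen.

    The returned result carries ``times_ms`` for the tested window.
    """
    short, long_ = sorted(int(d) for d in dur_pair)
    if window_ms is None:
        window_ms = (float(short), float(long_))
    sub = t.select_trials(t.trials["duration_ms"].isin([short, long_]))
    durations = sub.trials["duration_ms"].to_numpy()
    for d in (short, long_):
        if (durations == d).sum() == 0:
            raise ValueError(f"no trials with duration {d} ms")
    tmask = sub.time_mask(*window_ms)
    hfa = sub.hfa[:, :, tmask]

    observed = _duration_distance_stat(hfa, durations, (short, long_))
    null = perm_stats.build_null(
        lambda lab: _duration_distance_stat(hfa, lab, (short, long_)),
        durations, n_perm=n_perm, rng=rng, scheme="duration-shuffle")
    result = perm_stats.max_stat_test(null, observed, alpha=alpha)
    result.times_ms = sub.times_ms[tmask]
    return result


def jackknife_ci(t: TrialTensor,
                 statistic: Callable[[TrialTensor], float | np.ndarray],
                 condition: dict | None = None,
                 n_iter: int = 1000,
                 rng=None,
                 ci: float = 0.95) -> dict:
    """Jackknife distribution of a trajectory statistic.

    Per iteration, for every patient and condition cell, one random trial
    is dropped and ``statistic`` is recomputed on the reduced tensor
    (patients share trials under the aligned design, so the drop zeroes
    that patient's electrode block contribution by excluding the trial for
    those electrodes: the recomputation averages each patient block over
    its own retained trials). ``n_iter`` leave-one-per-patient sets are
    sampled uniformly at random; sampling is reproducible under ``rng``.

    Returns ``{"samples", "low", "high"}`` with the central ``ci`` band.
    """
    rng = np.random.default_rng(rng)
    sub = t if condition is None else t.select_trials(**condition)
    cond_key = sub.trials["category"].astype(str) + "/" + \
        sub.trials["duration_ms"].astype(str)
    patients = sub.electrodes["patient"].unique()
    cells = {c: np.where((cond_key == c).to_numpy())[0]
             for c in cond_key.unique()}
    for c, idx in cells.items():
        if idx.size < 2:
            raise ValueError(f"condition cell {c} has <2 trials")

    samples = []
    for _ in range(n_iter):
        parts = []
        for p in patients:
            emask = (sub.electrodes["patient"] == p).to_numpy()
            drop = {c: idx[rng.integers(idx.size)] for c, idx in cells.items()}
            keep = np.ones(sub.n_trials, dtype=bool)
            keep[list(drop.values())] = False
            block = sub.select_electrodes(mask=emask).select_trials(mask=keep)
            parts.append(block)
        merged = _merge_blocks(parts)
        samples.append(np.asarray(statistic(merged), dtype=float))
    samples = np.stack(samples, axis=0)
    lo = (1.0 - ci) / 2.0
    return {"samples": samples,
            "low": np.quantile(samples, lo, axis=0),
            "high": np.quantile(samples, 1.0 - lo, axis=0)}


def _merge_blocks(blocks: list[TrialTensor]) -> TrialTensor:
    """Merge per-patient blocks back into one tensor on shared trials.

    Blocks may retain different trial subsets (the jackknife drops
    independently per patient); the merge keeps the intersection of
    trial_ids so the electrode axis can be concatenated.
    """
    import functools
    import pandas as pd

    common = functools.reduce(
        lambda a, b: a & b, (set(b.trials["trial_id"]) for b in blocks))
    aligned, tables = [], []
    trials = None
    for b in blocks:
        keep = b.trials["trial_id"].isin(common).to_numpy()
        sel = b.select_trials(mask=keep)
        order = np.argsort(sel.trials["trial_id"].to_numpy())
        aligned.append(sel.hfa[order])
        tables.append(sel.electrodes)
        if trials is None:
            trials = sel.trials.iloc[order].reset_index(drop=True)
    return TrialTensor(hfa=np.concatenate(aligned, axis=1),
                       times_ms=blocks[0].times_ms, trials=trials,
                       electrodes=pd.concat(tables, ignore_index=True),
                       sampling_rate=blocks[0].sampling_rate,
                       smoothing_window_ms=blocks[0].smoothing_window_ms)
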