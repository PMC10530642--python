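"""Core data containers shared by all analysis stages.

The universal exchange object is :class:`TrialTensor`: a dense
``trials x electrodes x time`` array of baseline-corrected high-frequency
activity (HFA) together with trial and electrode metadata tables. The
electrode axis may concatenate electrodes from several patients recorded
with a shared stimulus design; patient identity then lives on the
electrode table, and the columns of a trial belonging to different
patients hold that patient's response to the same stimulus presentation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

TRIAL_COLUMNS = ("trial_id", "patient", "category", "exemplar_id",
                 "duration_ms", "repetition", "is_target")
ELECTRODE_COLUMNS = ("electrode_id", "patient", "region")


@dataclass
class ContinuousRecording:
    """Continuous voltage traces (``electrodes x samples``) with metadata."""

    voltage: np.ndarray
    sampling_rate: float
    electrodes: pd.DataFrame
    layout: dict | None = None  # electrode_id -> list of adjacent electrode_ids

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.voltage.ndim != 2:
            raise ValueError("voltage must be 2-D (electrodes x samples)")
        if not np.isfinite(self.voltage).all():
            raise ValueError("voltage contains NaN or infinite samples")
        if len(self.electrodes) != self.voltage.shape[0]:
            raise ValueError("electrode table does not match voltage rows")

    @property
    def n_electrodes(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]


@dataclass
class TrialTensor:
    """Epoched HFA: ``trials x electrodes x time`` plus metadata.

    Parameters
    ----------
    hfa
        Baseline-corrected HFA amplitude, shape ``(n_trials, n_electrodes,
        n_times)``.
    times_ms
        Strictly increasing time axis in milliseconds relative to stimulus
        onset.
    trials
        One row per trial: ``trial_id, patient, category, exemplar_id,
        duration_ms, repetition, is_target`` (extra columns preserved).
    electrodes
        One row per electrode: ``electrode_id, patient, region`` (extra
        columns such as ``sign`` preserved).
    sampling_rate
        Samples per second of the time axis.
    smoothing_window_ms
        Width of the moving-average smoothing already applied, or ``None``
        for unsmoothed data.
    """

    hfa: np.ndarray
    times_ms: np.ndarray
    trials: pd.DataFrame
    electrodes: pd.DataFrame
    sampling_rate: float
    smoothing_window_ms: float | None = None

    def __post_init__(self) -> None:
        self.hfa = np.asarray(self.hfa, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.hfa.ndim != 3:
            raise ValueError("hfa must be 3-D (trials x electrodes x time)")
        if self.hfa.shape[2] != self.times_ms.size:
            raise ValueError("time axis does not match hfa")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if len(self.trials) != self.hfa.shape[0]:
            raise ValueError("trial table does not match hfa")
        if len(self.electrodes) != self.hfa.shape[1]:
            raise ValueError("electrode table does not match hfa")
        self.trials = self.trials.reset_index(drop=True)
        self.electrodes = self.electrodes.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.hfa.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.hfa.shape[1]

    @property
    def n_times(self) -> int:
        return self.hfa.shape[2]

    def time_index(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times_ms - t_ms)))

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Boolean mask over the time axis for ``start_ms <= t < stop_ms``."""
        return (self.times_ms >= start_ms) & (self.times_ms < stop_ms)

    # ------------------------------------------------------------------
    def select_trials(self, mask=None, **filters) -> "TrialTensor":
        """Subset trials by boolean mask and/or metadata equality filters.

        ``filters`` values may be scalars or sequences, e.g.
        ``select_trials(category="face", duration_ms=[900, 1500])``.
        """
        keep = np.ones(self.n_trials, dtype=bool)
        if mask is not None:
            keep &= np.asarray(mask, dtype=bool)
        for col, val in filters.items():
            if col not in self.trials.columns:
                raise KeyError(f"unknown trial column {col!r}")
            if isinstance(val, (list, tuple, set, np.ndarray, pd.Series)):
                keep &= self.trials[col].isin(list(val)).to_numpy()
            else:
                keep &= (self.trials[col] == val).to_numpy()
        return dataclasses.replace(
            self, hfa=self.hfa[keep], trials=self.trials.loc[keep])

    def select_electrodes(self, mask=None, region=None,
                          ids: Sequence | None = None) -> "TrialTensor":
        keep = np.ones(self.n_electrodes, dtype=bool)
        if mask is not None:
            keep &= np.asarray(mask, dtype=bool)
        if region is not None:
            regions = [region] if isinstance(region, str) else list(region)
            keep &= self.electrodes["region"].isin(regions).to_numpy()
        if ids is not None:
            keep &= self.electrodes["electrode_id"].isin(list(ids)).to_numpy()
        return dataclasses.replace(
            self, hfa=self.hfa[:, keep], electrodes=self.electrodes.loc[keep])

    def crop(self, start_ms: float, stop_ms: float) -> "TrialTensor":
        tmask = self.time_mask(start_ms, stop_ms)
        return dataclasses.replace(
            self, hfa=self.hfa[:, :, tmask], times_ms=self.times_ms[tmask])

    def copy(self) -> "TrialTensor":
        return dataclasses.replace(
            self, hfa=self.hfa.copy(), times_ms=self.times_ms.copy(),
            trials=self.trials.copy(), electrodes=self.electrodes.copy())


@dataclass
class Trajectory:
    """Condition-averaged state-space path (``electrodes x time``)."""

    states: np.ndarray
    times_ms: np.ndarray
    condition: dict = field(default_factory=dict)
    electrode_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.states.ndim != 2:
            raise ValueError("states must be 2-D (electrodes x time)")
        if self.states.shape[1] != self.times_ms.size:
            raise ValueError("time axis does not match states")
        if self.electrode_ids is not None:
            self.electrode_ids = np.asarray(self.electrode_ids)
            if self.electrode_ids.size != self.states.shape[0]:
                raise ValueError("electrode_ids does not match states")

    @property
    def n_electrodes(self) -> int:
        return self.states.shape[0]


def check_same_electrodes(a: Trajectory, b: Trajectory) -> None:
    """Raise when two trajectories are not defined over the same electrodes."""
    if a.states.shape[0] != b.states.shape[0]:
        raise ValueError("trajectories have different electrode counts")
    if a.electrode_ids is not None and b.electrode_ids is not None:
        if not np.array_equal(a.electrode_ids, b.electrode_ids):
            raise ValueError("trajectories have different electrode order")
    if a.times_ms.size != b.times_ms.size or \
            not np.allclose(a.times_ms, b.times_ms):
        raise ValueError("trajectories have different time axes")
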