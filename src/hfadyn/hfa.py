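"""Broadband high-frequency activity (HFA, 70-150 Hz) estimation.

The HFA envelope is a proxy for local population firing. It is estimated
sub-band by sub-band to counter the 1/f spectral profile: the signal is
band-pass filtered in eight 10-Hz ranges between 70 and 150 Hz (zero-phase
FIR, Hamming design), the instantaneous amplitude of each band is taken
with the Hilbert transform and divided by that band's mean amplitude over
the whole recording, and the normalized envelopes are averaged. Epochs are
then cut around stimulus onsets, baseline corrected by subtracting the
mean over the 300 ms before onset, screened for excessive noise, and
smoothed with a 50-ms moving window.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ContinuousRecording, TrialTensor

logger = logging.getLogger(__name__)

__all__ = [
    "extract_hfa", "epoch_baseline_smooth", "baseline_correct",
    "smooth_tensor", "moving_average", "decimate", "reject_noisy_trials",
    "neighbor_rereference",
]


def _fir_bandpass(lo: float, hi: float, fs: float,
                  transition_hz: float = 2.5) -> np.ndarray:
    """Hamming-window FIR band-pass taps.

    Order from the Hamming transition-width heuristic N ~= 3.3 / (df/fs),
    forced odd for a type-I (symmetric, integer-delay) filter.
    """
    numtaps = int(np.ceil(3.3 / (transition_hz / fs)))
    numtaps += 1 - numtaps % 2
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs,
                         window="hamming")


def extract_hfa(rec: ContinuousRecording | np.ndarray,
                sampling_rate: float | None = None,
                band: tuple[float, float] = (70.0, 150.0),
                n_subbands: int = 8,
                norm_mask: np.ndarray | None = None) -> np.ndarray:
    """Normalized HFA envelope of continuous traces.

    Parameters
    ----------
    rec
        :class:`ContinuousRecording` or a raw ``electrodes x samples``
        array (then ``sampling_rate`` is required).
    band, n_subbands
        Frequency range split into equal sub-bands (default eight 10-Hz
        bands between 70 and 150 Hz).
    norm_mask
        Optional boolean sample mask restricting the normalization span
        (e.g. task blocks only); default is the whole recording.

    Returns
    -------
    ndarray, ``electrodes x samples``. By construction the whole-recording
    mean of every normalized sub-band envelope is 1, so a stationary
    recording yields an output near 1; the estimate is invariant to
    multiplying the whole recording by a positive constant.
    """
    if isinstance(rec, ContinuousRecording):
        voltage, fs = rec.voltage, rec.sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a raw array")
        voltage, fs = np.atleast_2d(np.asarray(rec, dtype=float)), sampling_rate
    if band[1] >= fs / 2:
        raise ValueError(
            f"band edge {band[1]} Hz is at or above Nyquist ({fs / 2} Hz)")
    if fs < 500:
        raise ValueError("HFA extraction requires sampling >= 500 Hz")

    edges = np.linspace(band[0], band[1], n_subbands + 1)
    out = np.zeros_like(voltage)
    for lo, hi in zip(edges[:-1], edges[1:]):
        taps = _fir_bandpass(lo, hi, fs)
        if voltage.shape[1] <= 3 * len(taps):
            raise ValueError(
                f"recording too short for the FIR filter ({len(taps)} taps)")
        filtered = signal.filtfilt(taps, 1.0, voltage, axis=1)
        amp = np.abs(signal.hilbert(filtered, axis=1))
        # normalize by the whole-recording mean amplitude, excluding the
        # filter's edge-transient region
        edge = len(taps)
        valid = np.zeros(amp.shape[1], dtype=bool)
        valid[edge:-edge] = True
        if norm_mask is not None:
            valid &= np.asarray(norm_mask, dtype=bool)
            if not valid.any():
                raise ValueError("norm_mask leaves no valid samples")
        mean_amp = amp[:, valid].mean(axis=1, keepdims=True)
        # silent channel: leave the (all-zero) envelope untouched
        np.divide(amp, mean_amp, out=amp, where=mean_amp > 0)
        out += amp
    out /= n_subbands
    return out


def epoch_baseline_smooth(traces: np.ndarray,
                          sampling_rate: float,
                          events: pd.DataFrame,
                          window_ms: tuple[float, float] = (-300.0, 1600.0),
                          baseline_ms: float = 300.0,
                          smooth_ms: float | None = 50.0,
                          reject_k: float | None = 5.0,
                          electrodes: pd.DataFrame | None = None
                          ) -> TrialTensor:
    """Cut epochs around onsets, baseline correct, reject noise, smooth.

    ``events`` needs an ``onset_sample`` column; remaining columns become
    trial metadata. Events too close to the recording edge are dropped
    with a warning, as are trials flagged by the noise-rejection rule
    (peak |amplitude| beyond ``reject_k`` robust SDs of the per-electrode
    distribution of trial peaks).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if "onset_sample" not in events.columns:
        raise ValueError("events must contain an 'onset_sample' column")
    start = int(round(window_ms[0] * sampling_rate / 1000.0))
    stop = int(round(window_ms[1] * sampling_rate / 1000.0))
    rel = np.arange(start, stop)
    times_ms = rel * 1000.0 / sampling_rate

    keep_rows, epochs = [], []
    for row_idx, onset in enumerate(events["onset_sample"].to_numpy()):
        lo, hi = int(onset) + start, int(onset) + stop
        if lo < 0 or hi > traces.shape[1]:
            warnings.warn(
                f"event at sample {onset} too close to the recording edge; "
                "trial dropped")
            continue
        epochs.append(traces[:, lo:hi])
        keep_rows.append(row_idx)
    if not epochs:
        raise ValueError("no events fall inside the recording")
    hfa = np.stack(epochs, axis=0)
    trials = events.iloc[keep_rows].drop(columns=["onset_sample"]).copy()

    if electrodes is None:
        electrodes = pd.DataFrame({
            "electrode_id": [f"e{i}" for i in range(hfa.shape[1])],
            "patient": "p0", "region": "unknown"})

    tensor = TrialTensor(hfa=hfa, times_ms=times_ms, trials=trials,
                         electrodes=electrodes, sampling_rate=sampling_rate)
    tensor = baseline_correct(tensor, baseline_ms=baseline_ms)
    if reject_k is not None:
        keep = reject_noisy_trials(tensor, k=reject_k)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("noise rejection dropped %d / %d trials",
                        n_drop, tensor.n_trials)
            tensor = tensor.select_trials(mask=keep)
    if smooth_ms is not None:
        tensor = smooth_tensor(tensor, smooth_ms)
    return tensor


def baseline_correct(t: TrialTensor, baseline_ms: float = 300.0
                     ) -> TrialTensor:
    """Subtract the per-trial/electrode mean over ``[-baseline_ms, 0)``.

    Idempotent: correcting an already corrected tensor changes nothing.
    """
    bmask = (t.times_ms >= -baseline_ms) & (t.times_ms < 0)
    if not bmask.any():
        raise ValueError("epoch window contains no baseline samples")
    base = t.hfa[:, :, bmask].mean(axis=2, keepdims=True)
    return dataclasses.replace(t, hfa=t.hfa - base)


def moving_average(x: np.ndarray, width_samples: int) -> np.ndarray:
    """Centered boxcar along the last axis, window shrunk at the edges."""
    if width_samples <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(width_samples)
    counts = np.convolve(np.ones(x.shape[-1]), kernel, mode="same")
    smoothed = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), -1, np.asarray(x, float))
    return smoothed / counts


def smooth_tensor(t: TrialTensor, smooth_ms: float = 50.0) -> TrialTensor:
    width = max(int(round(smooth_ms * t.sampling_rate / 1000.0)), 1)
    return dataclasses.replace(t, hfa=moving_average(t.hfa, width),
                               smoothing_window_ms=smooth_ms)


def decimate(t: TrialTensor, target_rate: float = 200.0) -> TrialTensor:
    """Downsample by integer stride (smoothing acts as the anti-alias)."""
    factor = t.sampling_rate / target_rate
    if factor < 1 or abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"target rate {target_rate} is not an integer divisor of "
            f"{t.sampling_rate}")
    step = int(round(factor))
    if step == 1:
        return t
    return dataclasses.replace(t, hfa=t.hfa[:, :, ::step],
                               times_ms=t.times_ms[::step],
                               sampling_rate=t.sampling_rate / step)


def reject_noisy_trials(t: TrialTensor, k: float = 5.0) -> np.ndarray:
    """Keep-mask; a trial is excessive-noise if any electrode's peak
    |amplitude| exceeds ``k`` robust SDs (1.4826 MAD) of that electrode's
    distribution of trial peaks."""
    peaks = np.abs(t.hfa).max(axis=2)                 # trials x electrodes
    med = np.median(peaks, axis=0, keepdims=True)
    mad = np.median(np.abs(peaks - med), axis=0, keepdims=True)
    robust_sd = 1.4826 * mad
    robust_sd[robust_sd == 0] = np.inf
    return ~((peaks - med) / robust_sd > k).any(axis=1)


def neighbor_rereference(t: TrialTensor, layout: dict) -> TrialTensor:
    """Subtract from each electrode the mean HFA of its grid neighbors.

    ``layout`` maps ``electrode_id`` to a list of adjacent electrode ids
    on the same grid. Electrodes without neighbors pass through with a
    warning; electrodes absent from the layout raise.
    """
    ids = list(t.electrodes["electrode_id"])
    missing = [i for i in ids if i not in layout]
    if missing:
        raise ValueError(f"layout missing electrodes: {missing}")
    index = {eid: pos for pos, eid in enumerate(ids)}
    out = t.hfa.copy()
    for pos, eid in enumerate(ids):
        neigh = [index[n] for n in layout[eid] if n in index]
        if not neigh:
            warnings.warn(f"electrode {eid} has no neighbors; passed through")
            continue
        out[:, pos] = t.hfa[:, pos] - t.hfa[:, neigh].mean(axis=1)
    return dataclasses.replace(t, hfa=out)
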