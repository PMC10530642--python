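"""Synthetic multi-patient iEEG/HFA datasets with planted ground truth.

The generator emulates the design of a multi-duration visual experiment:
grayscale images from four categories (faces ~30%, watches ~30%, other
objects ~18%, animals ~10% of the stimulus stream) shown for 300, 900 or
1,500 ms with jittered inter-stimulus intervals, while subdural electrodes
over occipital (Occ), ventral-temporal (VT), parietal (Par) and prefrontal
(PFC) cortex record high-frequency activity. Each region follows a
:class:`CodingProfile`: a transient onset peak that decays to a sustained
fraction of the peak while the stimulus is on (a sustained fraction near
0.2 emulates the roughly five-fold post-onset attenuation seen in sensory
cortex) and decays back to baseline after offset. Category and exemplar
information is planted as per-electrode gain patterns; a profile may be
``stable`` (one pattern throughout) or ``dynamic`` (patterns supported on
disjoint electrode subsets before and after a switch time, hence
orthogonal between the early and late windows).

All patients share the same stimulus sequence, so the dataset is a single
``trials x electrodes x time`` tensor whose electrode axis concatenates
patients — the convention used downstream when merging trajectories and
decoders across patients.

Noise is additive Gaussian on the HFA amplitude, optionally with
trial-level multiplicative gain jitter. The planted structure is returned
as a :class:`GroundTruth` that suffices to score recovery by the
downstream stages.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, TrialTensor
from . import hfa as _hfa

__all__ = [
    "CodingProfile", "SimulationConfig", "GroundTruth", "RawTraces",
    "generate_dataset", "generate_raw_traces", "ground_truth_report",
    "base_envelope",
]

CATEGORIES = ("face", "watch", "object", "animal")


@dataclass
class CodingProfile:
    """Region-level response dynamics and coding structure.

    All times in ms. ``sustained_fraction`` is the proportion of the
    transient peak maintained while the stimulus stays on;
    ``tuning_strength`` is the SD of per-electrode category gain
    deviations around the common gain of 1; ``exemplar_gain_sd`` the SD of
    the isotropic per-exemplar perturbation around the category centroid.
    """

    onset_latency_ms: float = 100.0
    rise_ms: float = 80.0
    decay_ms: float = 150.0
    transient_peak_amplitude: float = 4.0
    sustained_fraction: float = 0.2
    offset_decay_ms: float = 150.0
    tuning_strength: float = 0.5
    category_tuning: np.ndarray | None = None   # electrodes x categories
    exemplar_gain_sd: float = 0.2
    code_stationarity: str = "stable"           # "stable" | "dynamic"
    switch_ms: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sustained_fraction <= 1.0:
            raise ValueError("sustained_fraction must lie in [0, 1]")
        if self.code_stationarity not in ("stable", "dynamic"):
            raise ValueError("code_stationarity must be 'stable' or 'dynamic'")


def _default_profiles() -> dict[str, CodingProfile]:
    return {
        "Occ": CodingProfile(onset_latency_ms=80, rise_ms=70,
                             transient_peak_amplitude=5.0,
                             sustained_fraction=0.25),
        "VT": CodingProfile(onset_latency_ms=120, rise_ms=80,
                            transient_peak_amplitude=4.0,
                            sustained_fraction=0.2),
        "Par": CodingProfile(onset_latency_ms=150, rise_ms=100,
                             transient_peak_amplitude=2.0,
                             sustained_fraction=0.05),
        "PFC": CodingProfile(onset_latency_ms=180, rise_ms=120,
                             transient_peak_amplitude=1.8,
                             sustained_fraction=0.0),
    }


def _default_exemplars() -> dict[str, int]:
    # composition of the 60-image shared set: 18 faces, 19 watches,
    # 13 other objects, 10 animals
    return {"face": 18, "watch": 19, "object": 13, "animal": 10}


@dataclass
class SimulationConfig:
    n_patients: int = 2
    electrodes_per_region: dict = field(
        default_factory=lambda: {"Occ": 10, "VT": 12, "Par": 6, "PFC": 8})
    fraction_negative_responders: float = 0.15
    fraction_unresponsive: float = 0.1
    n_exemplars_per_category: dict = field(default_factory=_default_exemplars)
    n_repetitions_per_exemplar: int = 2
    durations_ms: tuple = (300, 900, 1500)
    isi_ms: tuple = (600, 750, 900, 1050, 1200)
    sampling_rate_hz: float = 200.0
    epoch_window_ms: tuple = (-300.0, 1600.0)
    region_profiles: dict = field(default_factory=_default_profiles)
    noise_sd: float = 1.0
    trial_gain_jitter_sd: float = 0.0
    raw_modulation_depth: float = 0.5
    raw_noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_repetitions_per_exemplar < 1:
            raise ValueError("n_repetitions_per_exemplar must be >= 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if min(self.n_exemplars_per_category.values()) < 0 or \
                sum(self.n_exemplars_per_category.values()) < 1:
            raise ValueError("exemplar counts must be >= 0 and not all zero")
        if self.epoch_window_ms[1] < max(self.durations_ms):
            raise ValueError("epoch window must contain the longest duration")
        unknown = set(self.electrodes_per_region) - set(self.region_profiles)
        if unknown:
            raise ValueError(f"regions without a coding profile: {unknown}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure, sufficient to score recovery."""

    electrodes: pd.DataFrame      # electrode_id, patient, region, sign, responsive
    exemplars: pd.DataFrame       # exemplar_id, category
    tuning: dict                  # region -> {"early","late": E_r x C, "stationarity"}
    exemplar_patterns: dict       # region -> {"early","late": E_r x N amplitude}
    config: SimulationConfig
    dataset_id: str = ""


@dataclass
class RawTraces:
    recording: ContinuousRecording
    events: pd.DataFrame          # onset_sample + trial metadata
    planted_envelope: np.ndarray  # electrodes x samples modulation envelope


# ----------------------------------------------------------------------


def base_envelope(times_ms: np.ndarray, duration_ms: float,
                  profile: CodingProfile) -> np.ndarray:
    """Noiseless unit-peak response envelope for one stimulus duration.

    Zero before ``onset_latency_ms``; squared-sine rise to a peak of 1;
    exponential relaxation toward ``sustained_fraction`` while the stimulus
    is on; exponential return to baseline after stimulus offset (offset
    reaching the region with the same latency as the onset).
    """
    t = np.asarray(times_ms, dtype=float)
    L, rise = profile.onset_latency_ms, profile.rise_ms
    peak_t = L + rise
    off_t = duration_ms + L
    env = np.zeros_like(t)

    rising = (t >= L) & (t < min(peak_t, off_t))
    env[rising] = np.sin(0.5 * np.pi * (t[rising] - L) / rise) ** 2

    f = profile.sustained_fraction
    on = (t >= peak_t) & (t < off_t)
    env[on] = f + (1 - f) * np.exp(-(t[on] - peak_t) / profile.decay_ms)

    if off_t >= peak_t:
        v_off = f + (1 - f) * np.exp(-(off_t - peak_t) / profile.decay_ms)
    else:  # stimulus shorter than the rise time
        v_off = np.sin(0.5 * np.pi * (off_t - L) / rise) ** 2
    after = t >= off_t
    env[after] = v_off * np.exp(-(t[after] - off_t) / profile.offset_decay_ms)
    return env


def _switch_weight(times_ms: np.ndarray, switch_ms: float,
                   width_ms: float = 50.0) -> np.ndarray:
    """Smooth early-window indicator: 1 before the switch, 0 after."""
    return 1.0 / (1.0 + np.exp((times_ms - switch_ms) / (width_ms / 4.0)))


def _make_exemplar_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cat in CATEGORIES:
        n = config.n_exemplars_per_category.get(cat, 0)
        for i in range(n):
            rows.append((f"{cat}_{i:03d}", cat))
    return pd.DataFrame(rows, columns=["exemplar_id", "category"])


def _make_trial_table(config: SimulationConfig,
                      exemplars: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for rep in range(1, config.n_repetitions_per_exemplar + 1):
        for _, ex in exemplars.iterrows():
            rows.append({
                "patient": "all", "category": ex.category,
                "exemplar_id": ex.exemplar_id,
                "duration_ms": int(rng.choice(config.durations_ms)),
                "repetition": rep,
                "isi_ms": int(rng.choice(config.isi_ms)),
                "is_target": False,
            })
    trials = pd.DataFrame(rows)
    order = rng.permutation(len(trials))
    trials = trials.iloc[order].reset_index(drop=True)
    trials.insert(0, "trial_id", np.arange(len(trials)))
    return trials


def _make_electrode_table(config: SimulationConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for p in range(1, config.n_patients + 1):
        for region, n in config.electrodes_per_region.items():
            for i in range(n):
                rows.append({
                    "electrode_id": f"S{p}_{region}_{i:02d}",
                    "patient": f"S{p}", "region": region})
    tab = pd.DataFrame(rows)
    n = len(tab)
    responsive = rng.random(n) >= config.fraction_unresponsive
    sign = np.where(rng.random(n) < config.fraction_negative_responders,
                    -1, 1)
    tab["responsive"] = responsive
    tab["sign"] = np.where(responsive, sign, 0)
    return tab


def _region_tuning(profile: CodingProfile, n_elec: int,
                   rng: np.random.Generator) -> dict:
    """Early/late category-gain matrices (``n_elec x 4``).

    Stable profiles share one matrix. Dynamic profiles carry their
    category contrast on disjoint electrode halves before and after the
    switch, making the early and late discriminating patterns orthogonal.
    """
    C = len(CATEGORIES)
    if profile.category_tuning is not None:
        early = np.asarray(profile.category_tuning, dtype=float)
        if early.shape != (n_elec, C):
            raise ValueError("category_tuning must be electrodes x 4")
        return {"early": early, "late": early.copy(),
                "stationarity": profile.code_stationarity}
    base = np.ones((n_elec, C))
    if profile.code_stationarity == "stable":
        early = base + profile.tuning_strength * rng.standard_normal((n_elec, C))
        return {"early": early, "late": early.copy(), "stationarity": "stable"}
    half = n_elec // 2
    early, late = base.copy(), base.copy()
    early[:half] += profile.tuning_strength * rng.standard_normal((half, C))
    late[half:] += profile.tuning_strength * rng.standard_normal(
        (n_elec - half, C))
    return {"early": early, "late": late, "stationarity": "dynamic"}


def generate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[TrialTensor, GroundTruth]:
    """Simulate an epoched HFA dataset with planted coding structure.

    Deterministic for a fixed ``config.seed`` (pass ``rng`` to override).
    Returns the baseline-corrected, unsmoothed :class:`TrialTensor` and
    the matching :class:`GroundTruth`.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    exemplars = _make_exemplar_table(config)
    trials = _make_trial_table(config, exemplars, rng)
    electrodes = _make_electrode_table(config, rng)

    fs = config.sampling_rate_hz
    t0, t1 = config.epoch_window_ms
    n_times = int(round((t1 - t0) * fs / 1000.0))
    times_ms = t0 + np.arange(n_times) * 1000.0 / fs

    n_trials, n_elec = len(trials), len(electrodes)
    cat_index = {c: k for k, c in enumerate(CATEGORIES)}
    ex_index = {e: k for k, e in enumerate(exemplars["exemplar_id"])}
    trial_ex = trials["exemplar_id"].map(ex_index).to_numpy()
    trial_cat = trials["category"].map(cat_index).to_numpy()

    hfa_arr = np.zeros((n_trials, n_elec, n_times))
    tuning: dict = {}
    patterns: dict = {}

    for region, profile in config.region_profiles.items():
        emask = (electrodes["region"] == region).to_numpy()
        if not emask.any():
            continue
        e_idx = np.where(emask)[0]
        n_r = e_idx.size
        tun = _region_tuning(profile, n_r, rng)
        tuning[region] = tun
        # exemplar amplitude = category centroid + isotropic perturbation
        N = len(exemplars)
        cat_of_ex = exemplars["category"].map(cat_index).to_numpy()
        amp_early = tun["early"][:, cat_of_ex] + \
            profile.exemplar_gain_sd * rng.standard_normal((n_r, N))
        if tun["stationarity"] == "stable":
            amp_late = amp_early.copy()
        else:
            amp_late = tun["late"][:, cat_of_ex] + \
                profile.exemplar_gain_sd * rng.standard_normal((n_r, N))
        patterns[region] = {"early": amp_early, "late": amp_late,
                            "stationarity": tun["stationarity"]}

        resp = (electrodes.loc[emask, "responsive"].to_numpy() *
                electrodes.loc[emask, "sign"].to_numpy()).astype(float)
        scale = profile.transient_peak_amplitude * resp  # 0 for unresponsive

        if tun["stationarity"] == "stable":
            w_early = np.ones(n_times)
        else:
            w_early = _switch_weight(times_ms, profile.switch_ms)
        w_late = 1.0 - w_early

        for dur in np.unique(trials["duration_ms"]):
            tmask = (trials["duration_ms"] == dur).to_numpy()
            env = base_envelope(times_ms, float(dur), profile)
            ex_ids = trial_ex[tmask]
            sig = (amp_early[:, ex_ids].T[:, :, None] * (env * w_early) +
                   amp_late[:, ex_ids].T[:, :, None] * (env * w_late))
            hfa_arr[np.ix_(tmask, e_idx)] = sig * scale[None, :, None]

    if config.trial_gain_jitter_sd > 0:
        gain = np.maximum(
            1.0 + config.trial_gain_jitter_sd * rng.standard_normal(n_trials),
            0.0)
        hfa_arr *= gain[:, None, None]
    if config.noise_sd > 0:
        hfa_arr += config.noise_sd * rng.standard_normal(hfa_arr.shape)

    tensor = TrialTensor(hfa=hfa_arr, times_ms=times_ms, trials=trials,
                         electrodes=electrodes[
                             ["electrode_id", "patient", "region"]].copy(),
                         sampling_rate=fs)
    tensor = _hfa.baseline_correct(
        tensor, baseline_ms=abs(config.epoch_window_ms[0]))

    dataset_id = hashlib.sha1(
        f"{config.seed}-{n_trials}-{n_elec}-{n_times}".encode()).hexdigest()[:12]
    gt = GroundTruth(electrodes=electrodes, exemplars=exemplars,
                     tuning=tuning, exemplar_patterns=patterns,
                     config=config, dataset_id=dataset_id)
    return tensor, gt


# ----------------------------------------------------------------------


def generate_raw_traces(config: SimulationConfig,
                        n_trials: int = 20,
                        sampling_rate_hz: float = 1000.0,
                        rng: np.random.Generator | None = None) -> RawTraces:
    """Continuous voltage traces for validating the HFA extraction stage.

    Each electrode carries eight sinusoids at the centers of the 70-150 Hz
    sub-bands, amplitude-modulated by the planted response envelope
    (``1 + depth * envelope``), plus broadband Gaussian noise. Returns the
    recording, the event list and the planted modulation envelope.
    """
    config.validate()
    if sampling_rate_hz < 2 * 150:
        raise ValueError(
            "sampling rate below 300 Hz aliases the 70-150 Hz band")
    if sampling_rate_hz < 500:
        raise ValueError("raw-trace generation requires sampling >= 500 Hz")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    fs = sampling_rate_hz
    exemplars = _make_exemplar_table(config)
    # one electrode per region of the first patient keeps this light
    regions = list(config.electrodes_per_region)
    n_elec = len(regions)

    rows, onset = [], int(1.0 * fs)  # 1 s lead-in for filter transients
    for i in range(n_trials):
        ex = exemplars.iloc[int(rng.integers(len(exemplars)))]
        dur = int(rng.choice(config.durations_ms))
        isi = int(rng.choice(config.isi_ms))
        rows.append({"onset_sample": onset, "trial_id": i, "patient": "S1",
                     "category": ex.category, "exemplar_id": ex.exemplar_id,
                     "duration_ms": dur, "repetition": 1, "is_target": False})
        onset += int((dur + isi + 400) * fs / 1000.0)
    events = pd.DataFrame(rows)
    n_samples = onset + int(1.5 * fs)

    t_ms = np.arange(n_samples) * 1000.0 / fs
    envelope = np.zeros((n_elec, n_samples))
    for e, region in enumerate(regions):
        profile = config.region_profiles[region]
        for _, ev in events.iterrows():
            rel = t_ms - ev.onset_sample * 1000.0 / fs
            seg = (rel >= -300) & (rel <= ev.duration_ms + 600)
            envelope[e, seg] += base_envelope(rel[seg], float(ev.duration_ms),
                                              profile)

    centers = np.linspace(75, 145, 8)
    t_s = np.arange(n_samples) / fs
    voltage = np.zeros((n_elec, n_samples))
    for e in range(n_elec):
        phases = rng.uniform(0, 2 * np.pi, size=centers.size)
        carrier = np.sum(np.sin(2 * np.pi * centers[:, None] * t_s
                                + phases[:, None]), axis=0)
        voltage[e] = carrier * (1.0 + config.raw_modulation_depth
                                * envelope[e])
    if config.raw_noise_sd > 0:
        voltage += config.raw_noise_sd * rng.standard_normal(voltage.shape)

    electrodes = pd.DataFrame({
        "electrode_id": [f"S1_{r}_raw" for r in regions],
        "patient": "S1", "region": regions})
    rec = ContinuousRecording(voltage=voltage, sampling_rate=fs,
                              electrodes=electrodes)
    return RawTraces(recording=rec, events=events, planted_envelope=envelope)


# ----------------------------------------------------------------------


def ground_truth_report(gt: GroundTruth,
                        selection=None,
                        decoding_results: dict | None = None,
                        reliability_results: dict | None = None) -> dict:
    """Score pipeline outputs against the planted structure.

    Returns a dict with electrode-selection sensitivity/specificity and
    sign agreement (``None`` where a class is empty), per-region decoding
    recovery deltas (peak AUC above chance where separability was
    planted), and IR/GR recovery flags.
    """
    report: dict = {"dataset_id": gt.dataset_id}
    if selection is not None:
        sel_ids = set(selection.responsive[selection.responsive].index)
        gt_ids = set(gt.electrodes["electrode_id"])
        if not set(selection.responsive.index) <= gt_ids:
            raise ValueError("selection does not match this dataset")
        truth = gt.electrodes.set_index("electrode_id")
        pos = truth.index[truth["responsive"]]
        neg = truth.index[~truth["responsive"]]
        pos = [i for i in pos if i in selection.responsive.index]
        neg = [i for i in neg if i in selection.responsive.index]
        report["selection_sensitivity"] = (
            None if not pos else
            float(np.mean([i in sel_ids for i in pos])))
        report["selection_specificity"] = (
            None if not neg else
            float(np.mean([i not in sel_ids for i in neg])))
        hits = [i for i in pos if i in sel_ids]
        report["sign_agreement"] = (
            None if not hits else
            float(np.mean([np.sign(selection.sign[i]) == truth.loc[i, "sign"]
                           for i in hits])))
    if decoding_results:
        deltas = {}
        for region, res in decoding_results.items():
            planted = gt.config.region_profiles[region].tuning_strength > 0
            deltas[region] = {
                "planted_separability": bool(planted),
                "peak_auc_minus_chance": float(np.nanmax(res.auc) - 0.5),
            }
        report["decoding_recovery"] = deltas
    if reliability_results:
        flags = {}
        for region, res in reliability_results.items():
            flags[region] = {
                "ir_recovered": bool(any(c.p <= 0.05 for c in res.ir_clusters)),
                "gr_recovered": bool(any(c.p <= 0.05 for c in res.gr_clusters)),
            }
        report["reliability_recovery"] = flags
    return report
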