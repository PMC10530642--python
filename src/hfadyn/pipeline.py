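"""Orchestration and on-disk formats.

Epochs travel as an HDF5 container (`epochs.h5`: datasets ``hfa`` and
``times_ms``, attrs ``sampling_rate`` / ``smoothing_window_ms``) with TSV
sidecars ``trials.tsv`` and ``electrodes.tsv``. :func:`run` executes the
stages simulate -> smooth/select -> state-space -> decode -> RSA in
dependency order, derives a recorded sub-seed per stochastic stage from
the master seed, and writes every result as TSV plus a provenance JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import TrialTensor
from . import hfa as hfa_mod
from . import simulate, electrode_stats, state_space, decoding, rsa
from . import perm_stats

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "read_epochs", "write_epochs"]

TRIAL_KNOWN = {"trial_id", "patient", "category", "exemplar_id",
               "duration_ms", "repetition", "is_target", "isi_ms"}


def write_epochs(t: TrialTensor, path) -> Path:
    """Write a TrialTensor to ``path`` (directory); lossless round trip."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "epochs.h5", "w") as f:
        f.create_dataset("hfa", data=t.hfa)
        f.create_dataset("times_ms", data=t.times_ms)
        f.attrs["sampling_rate"] = t.sampling_rate
        f.attrs["smoothing_window_ms"] = \
            -1.0 if t.smoothing_window_ms is None else t.smoothing_window_ms
    t.trials.to_csv(path / "trials.tsv", sep="\t", index=False)
    t.electrodes.to_csv(path / "electrodes.tsv", sep="\t", index=False)
    return path


def read_epochs(path) -> TrialTensor:
    path = Path(path)
    h5 = path / "epochs.h5"
    if not h5.exists():
        raise FileNotFoundError(f"no epochs container at {h5}")
    try:
        with h5py.File(h5, "r") as f:
            arr = f["hfa"][()]
            times = f["times_ms"][()]
            fs = float(f.attrs["sampling_rate"])
            sm = float(f.attrs["smoothing_window_ms"])
    except (OSError, KeyError) as err:
        raise ValueError(f"corrupted or invalid epochs container: {h5}") \
            from err
    trials = pd.read_csv(path / "trials.tsv", sep="\t")
    electrodes = pd.read_csv(path / "electrodes.tsv", sep="\t")
    extra = set(trials.columns) - TRIAL_KNOWN
    if extra:
        warnings.warn(f"unknown trial columns preserved: {sorted(extra)}")
    return TrialTensor(hfa=arr, times_ms=times, trials=trials,
                       electrodes=electrodes, sampling_rate=fs,
                       smoothing_window_ms=None if sm < 0 else sm)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the study's analysis settings
    (1000 permutations, 5x5 CV, 50-ms smoothing, 200 Hz analysis rate,
    cluster thresholds AUC 0.60 / z 1.5)."""

    stages: tuple = ("simulate", "select", "statespace", "decode", "rsa")
    seed: int = 0
    out_dir: str = "hfadyn_run"
    simulation: dict = field(default_factory=dict)
    smooth_ms: float = 50.0
    analysis_rate_hz: float = 200.0
    n_perm: int = 1000
    n_folds: int = 5
    n_repeats: int = 5
    auc_cluster_threshold: float = 0.60
    z_cluster_threshold: float = 1.5
    decode_pairs: tuple = (("face", "watch"),)
    regions: tuple | None = None
    rsa_metric: str = "correlation"
    log_level: str = "INFO"

    @classmethod
    def fast(cls, **overrides) -> "RunConfig":
        """Reduced profile for smoke tests: 200 permutations, 3x3 CV."""
        base = dict(n_perm=200, n_folds=3, n_repeats=3)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        for key in ("stages", "decode_pairs", "regions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in raw[key])
        return cls(**raw)


def _sub_seeds(seed: int, names) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


def run(config: RunConfig, epochs_path=None) -> Path:
    """Execute the configured stages and write results + provenance.

    ``epochs_path`` replaces the simulate stage with on-disk epochs.
    Raises before any computation when a required input is missing.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper()))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _sub_seeds(config.seed,
                       ["simulate", "statespace", "decode", "rsa"])

    if "simulate" in config.stages:
        sim_cfg = simulate.SimulationConfig(
            **{**config.simulation, "seed": seeds["simulate"]})
        tensor, gt = simulate.generate_dataset(sim_cfg)
        write_epochs(tensor, out / "epochs")
        gt.electrodes.to_csv(out / "ground_truth_electrodes.tsv",
                             sep="\t", index=False)
    elif epochs_path is not None:
        if not Path(epochs_path).exists():
            raise FileNotFoundError(
                f"stage 'input': epochs path {epochs_path} does not exist")
        tensor, gt = read_epochs(epochs_path), None
    else:
        raise ValueError("stage 'input': no epochs given and simulate "
                         "not requested")

    smoothed = hfa_mod.smooth_tensor(tensor, config.smooth_ms)
    if tensor.sampling_rate > config.analysis_rate_hz:
        smoothed = hfa_mod.decimate(smoothed, config.analysis_rate_hz)

    selection = None
    if "select" in config.stages:
        selection = electrode_stats.select_responsive(tensor)
        selection = electrode_stats.select_selective(tensor, selection)
        frame = selection.to_frame()
        frame.to_csv(out / "selection.tsv", sep="\t")
        keep = smoothed.electrodes["electrode_id"].map(
            selection.responsive).to_numpy()
        smoothed = smoothed.select_electrodes(mask=keep)
        tensor = tensor.select_electrodes(mask=keep)

    regions = config.regions or tuple(
        smoothed.electrodes["region"].unique())

    if "statespace" in config.stages:
        rng = np.random.default_rng(seeds["statespace"])
        rows = []
        for region in regions:
            sub = smoothed.select_electrodes(region=region)
            if sub.n_electrodes == 0:
                continue
            for cat in pd.unique(sub.trials["category"]):
                traj = state_space.condition_trajectory(
                    sub, category=cat,
                    mask=sub.trials["duration_ms"] >= 900)
                dist = state_space.baseline_distance(traj)
                for tm, v in zip(traj.times_ms, dist):
                    rows.append((region, cat, tm, v))
        pd.DataFrame(rows, columns=["region", "condition", "time_ms",
                                    "baseline_distance"]).to_csv(
            out / "statespace.tsv", sep="\t", index=False)

    if "decode" in config.stages:
        rng = np.random.default_rng(seeds["decode"])
        rows = []
        for region in regions:
            sub = smoothed.select_electrodes(region=region)
            if sub.n_electrodes == 0:
                continue
            for pair in config.decode_pairs:
                res = decoding.time_resolved_decoding(
                    sub, pair, n_folds=config.n_folds,
                    n_repeats=config.n_repeats, rng=rng)
                null = decoding.decoding_null(
                    sub, pair, n_perm=config.n_perm,
                    n_folds=config.n_folds, rng=rng)
                clusters = perm_stats.cluster_test(
                    res.auc, null, threshold=config.auc_cluster_threshold)
                sig = np.zeros(res.auc.size, dtype=bool)
                for c in clusters:
                    if c.p <= 0.05:
                        sig |= c.mask
                for tm, v, s in zip(res.times_ms, res.auc, sig):
                    rows.append((region, "-".join(pair), tm, v, bool(s)))
        pd.DataFrame(rows, columns=["region", "pair", "time_ms", "auc",
                                    "significant"]).to_csv(
            out / "decoding.tsv", sep="\t", index=False)

    if "rsa" in config.stages:
        rng = np.random.default_rng(seeds["rsa"])
        rows = []
        for region in regions:
            sub = smoothed.select_electrodes(region=region)
            if sub.n_electrodes == 0:
                continue
            try:
                res = rsa.reliability_analysis(
                    sub, metric=config.rsa_metric, n_perm=config.n_perm,
                    rng=rng, cluster_threshold_z=config.z_cluster_threshold)
            except ValueError as err:
                logger.warning("rsa skipped for %s: %s", region, err)
                continue
            for tm, ir, gr in zip(res.times_ms, res.ir_z, res.gr_z):
                rows.append((region, tm, ir, gr))
        pd.DataFrame(rows, columns=["region", "time_ms", "ir_z", "gr_z"]) \
            .to_csv(out / "reliability.tsv", sep="\t", index=False)

    provenance = {
        "hfadyn_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": list(config.stages),
        "parameters": {k: v for k, v in vars(config).items()
                       if isinstance(v, (int, float, str))},
    }
    with open(out / "provenance.json", "w") as f:
        json.dump(provenance, f, indent=2, default=str)
    return out
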