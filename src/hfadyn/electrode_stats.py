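"""Single-electrode responsiveness, selectivity and response dynamics.

Visual responsiveness is tested per category in four non-overlapping
200-ms windows (100-300, 300-500, 500-700, 700-900 ms after onset,
trials >= 900 ms only) against the mean of the 200 ms before onset
(two-tailed paired t test on *unsmoothed* window means). p values are
Bonferroni-corrected across the four windows and FDR-corrected across
electrodes; an electrode is responsive when any test survives, and its
sign (+/-) is the sign of the sum of t statistics over all its tests.
Category selectivity uses the same window/correction scheme with a
one-way ANOVA across the four categories, and a point-by-point selectivity
time course 100*eta^2 (percent variance explained by category).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .containers import TrialTensor
from .perm_stats import fdr_bh

logger = logging.getLogger(__name__)

__all__ = [
    "WINDOWS_MS", "ElectrodeSelection", "ResponseSummary",
    "select_responsive", "select_selective", "selectivity_timecourse",
    "response_summary", "group_comparison",
]

WINDOWS_MS = ((100, 300), (300, 500), (500, 700), (700, 900))
CATEGORIES = ("face", "watch", "object", "animal")


@dataclass
class ElectrodeSelection:
    """Per-electrode test table plus responsiveness/selectivity flags.

    ``table`` has one row per electrode x category x window with the
    paired t statistic, raw p, and BH q (computed across electrodes within
    each category/window family). ``responsive``/``selective`` are boolean
    Series indexed by electrode_id; ``sign`` holds +1/-1 for responsive
    electrodes and 0 otherwise.
    """

    table: pd.DataFrame
    responsive: pd.Series
    sign: pd.Series
    selective: pd.Series | None = None
    selectivity_table: pd.DataFrame | None = None
    alpha: float = 0.05
    n_windows: int = 4

    def responsive_ids(self) -> list:
        return list(self.responsive.index[self.responsive])

    def to_frame(self) -> pd.DataFrame:
        """One row per electrode: flags, sign, strongest statistics."""
        out = pd.DataFrame({"responsive": self.responsive, "sign": self.sign})
        if self.selective is not None:
            out["selective"] = self.selective
        best = self.table.loc[self.table.groupby("electrode_id")["p"].idxmin()]
        out = out.join(best.set_index("electrode_id")[
            ["category", "window", "t", "p", "q"]].add_prefix("best_"))
        return out.rename_axis("electrode_id")


@dataclass
class ResponseSummary:
    """Peak and late response of a mean HFA time course.

    ``attenuation_percent = 100 * (Presp - Eresp) / Presp`` and may exceed
    100 when the late response falls below baseline.
    """

    peak: float
    peak_time_ms: float
    end_response: float
    attenuation_percent: float = field(init=False)

    def __post_init__(self) -> None:
        self.attenuation_percent = float(
            100.0 * (self.peak - self.end_response) / self.peak)


def _window_means(t: TrialTensor, windows, baseline_ms: float):
    """Mean HFA per trial/electrode in each test window and the baseline.

    Averaging precedes any smoothing by contract: the input tensor must be
    unsmoothed to avoid leakage between adjacent windows.
    """
    if t.smoothing_window_ms is not None:
        raise ValueError(
            "window tests require an unsmoothed tensor "
            "(averaging precedes smoothing)")
    wmeans = [t.hfa[:, :, t.time_mask(lo, hi)].mean(axis=2)
              for lo, hi in windows]
    bmask = (t.times_ms >= -baseline_ms) & (t.times_ms < 0)
    return np.stack(wmeans, axis=0), t.hfa[:, :, bmask].mean(axis=2)


def select_responsive(t: TrialTensor,
                      windows=WINDOWS_MS,
                      baseline_ms: float = 200.0,
                      alpha: float = 0.05,
                      min_duration_ms: float = 900.0) -> ElectrodeSelection:
    """Flag visually responsive electrodes and their response signs."""
    tt = t.select_trials(t.trials["duration_ms"] >= min_duration_ms)
    if tt.n_trials == 0:
        raise ValueError(f"no trials with duration >= {min_duration_ms} ms")
    wmeans, base = _window_means(tt, windows, baseline_ms)

    cats = [c for c in CATEGORIES if (tt.trials["category"] == c).any()]
    rows = []
    for cat in cats:
        cmask = (tt.trials["category"] == cat).to_numpy()
        if cmask.sum() < 2:
            logger.info("category %s has <2 trials; tests skipped", cat)
            continue
        for w, (lo, hi) in enumerate(windows):
            tstat, p = stats.ttest_rel(wmeans[w][cmask], base[cmask], axis=0)
            for e in range(tt.n_electrodes):
                rows.append({
                    "electrode_id": tt.electrodes["electrode_id"].iloc[e],
                    "category": cat, "window": f"{lo}-{hi}",
                    "t": float(tstat[e]), "p": float(p[e])})
    table = pd.DataFrame(rows)

    # BH across electrodes within each (category, window) family,
    # thresholded at alpha / n_windows (Bonferroni across windows)
    table["q"] = np.nan
    for (_, _), grp in table.groupby(["category", "window"]):
        q = multipletests(grp["p"].to_numpy(), method="fdr_bh")[1]
        table.loc[grp.index, "q"] = q
    n_windows = len(windows)
    table["reject"] = table["q"] < alpha / n_windows

    ids = list(t.electrodes["electrode_id"])
    by_e = table.groupby("electrode_id")
    responsive = by_e["reject"].any().reindex(ids, fill_value=False)
    tsum = by_e["t"].sum().reindex(ids, fill_value=0.0)
    sign = pd.Series(np.where(responsive, np.sign(tsum), 0).astype(int),
                     index=ids)
    return ElectrodeSelection(table=table, responsive=responsive, sign=sign,
                              alpha=alpha, n_windows=n_windows)


def select_selective(t: TrialTensor, selection: ElectrodeSelection,
                     windows=WINDOWS_MS, alpha: float = 0.05,
                     min_duration_ms: float = 900.0) -> ElectrodeSelection:
    """Add category-selectivity flags (window ANOVA, same corrections)."""
    tt = t.select_trials(t.trials["duration_ms"] >= min_duration_ms)
    wmeans, _ = _window_means(tt, windows, baseline_ms=200.0)
    cats = [c for c in CATEGORIES if (tt.trials["category"] == c).sum() >= 2]
    if len(cats) < 2:
        raise ValueError("selectivity requires >=2 categories with >=2 trials")
    masks = [(tt.trials["category"] == c).to_numpy() for c in cats]

    rows = []
    for w, (lo, hi) in enumerate(windows):
        groups = [wmeans[w][m] for m in masks]
        F, p = stats.f_oneway(*groups, axis=0)
        for e in range(tt.n_electrodes):
            rows.append({
                "electrode_id": tt.electrodes["electrode_id"].iloc[e],
                "window": f"{lo}-{hi}", "F": float(F[e]), "p": float(p[e])})
    table = pd.DataFrame(rows)
    table["reject"] = False
    for _, grp in table.groupby("window"):
        rej = fdr_bh(grp["p"].to_numpy(), q=alpha / len(windows))
        table.loc[grp.index, "reject"] = rej
    ids = list(t.electrodes["electrode_id"])
    selective = table.groupby("electrode_id")["reject"].any() \
        .reindex(ids, fill_value=False)
    selection.selective = selective
    selection.selectivity_table = table
    return selection


def selectivity_timecourse(t: TrialTensor, electrode) -> np.ndarray:
    """100*eta^2 per time point from a one-way ANOVA across categories.

    ``electrode`` is an electrode_id or positional index. Time points with
    zero total variance return 0. Invariant to adding a constant to all
    trials; bounded in [0, 100]. Typically run on smoothed traces to match
    plotted time courses.
    """
    if isinstance(electrode, str):
        pos = list(t.electrodes["electrode_id"]).index(electrode)
    else:
        pos = int(electrode)
    x = t.hfa[:, pos, :]                      # trials x time
    cats = t.trials["category"].to_numpy()
    labels = [c for c in np.unique(cats) if (cats == c).sum() >= 2]
    if len(labels) < 2:
        raise ValueError("eta^2 requires >=2 categories with >=2 trials")
    keep = np.isin(cats, labels)
    x, cats = x[keep], cats[keep]
    grand = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum(axis=0)
    ss_between = np.zeros_like(grand)
    for c in labels:
        m = cats == c
        ss_between += m.sum() * (x[m].mean(axis=0) - grand) ** 2
    eta2 = np.zeros_like(grand)
    np.divide(ss_between, ss_total, out=eta2, where=ss_total > 0)
    return 100.0 * eta2


def response_summary(mean_response: np.ndarray, times_ms: np.ndarray,
                     peak_window_ms: tuple[float, float] = (0.0, 900.0),
                     end_window_ms: tuple[float, float] = (800.0, 900.0)
                     ) -> ResponseSummary:
    """Peak (0-900 ms), peak time, late mean (800-900 ms) and attenuation.

    The input is the electrode's mean response over the categories it
    responds to, durations >= 900 ms. Attenuation is invariant to positive
    rescaling of the response.
    """
    mean_response = np.asarray(mean_response, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    pmask = (times_ms >= peak_window_ms[0]) & (times_ms <= peak_window_ms[1])
    emask = (times_ms >= end_window_ms[0]) & (times_ms <= end_window_ms[1])
    if not pmask.any() or not emask.any():
        raise ValueError("time axis does not cover the summary windows")
    seg = mean_response[pmask]
    k = int(np.argmax(seg))
    return ResponseSummary(peak=float(seg[k]),
                           peak_time_ms=float(times_ms[pmask][k]),
                           end_response=float(mean_response[emask].mean()))


def group_comparison(values, groups) -> dict:
    """One-way ANOVA + Tukey-Kramer post hocs + pairwise Cohen's d.

    ``values`` per electrode (e.g. attenuation), ``groups`` the region
    labels. Returns ``{"F", "p", "df", "tukey": DataFrame, "cohens_d":
    {(a, b): d}}``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups) if (groups == g).sum() >= 2]
    if len(names) < 2:
        raise ValueError("group comparison requires >=2 groups with >=2 members")
    keep = np.isin(groups, names)
    values, groups = values[keep], groups[keep]
    samples = [values[groups == g] for g in names]
    F, p = stats.f_oneway(*samples)

    tk = pairwise_tukeyhsd(values, groups)
    tukey = pd.DataFrame(tk.summary().data[1:],
                         columns=tk.summary().data[0])
    d = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = values[groups == a], values[groups == b]
            pooled = np.sqrt(((len(xa) - 1) * xa.var(ddof=1) +
                              (len(xb) - 1) * xb.var(ddof=1)) /
                             (len(xa) + len(xb) - 2))
            d[(a, b)] = float((xa.mean() - xb.mean()) / pooled) \
                if pooled > 0 else 0.0
    df = (len(names) - 1, len(values) - len(names))
    return {"F": float(F), "p": float(p), "df": df, "tukey": tukey,
            "cohens_d": d}
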