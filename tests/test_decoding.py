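"""Shrinkage LDA, rank AUC, CV decoding and temporal generalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from hfadyn import decoding, hfa, simulate

from conftest import small_config


def brute_force_auc(scores, labels):
    """Pair counting: P(positive outranks negative), ties = 1/2."""
    classes = np.unique(labels)
    pos = scores[labels == classes[0]]
    neg = scores[labels == classes[1]]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_hand_example(self):
        # positives {0.9, 0.4}, negatives {0.8, 0.2}: 3 of 4 pairs ordered
        scores = np.array([0.9, 0.4, 0.8, 0.2])
        labels = np.array(["a", "a", "b", "b"])
        assert decoding.roc_auc(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation_is_one(self):
        scores = np.array([3.0, 2.0, 1.0, 0.0])
        labels = np.array(["a", "a", "b", "b"])
        assert decoding.roc_auc(scores, labels) == 1.0

    def test_matches_bruteforce_and_sklearn_on_random_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 25))
            scores = np.round(rng.normal(size=n), 1)   # provoke ties
            labels = np.where(rng.random(n) < 0.5, "a", "b")
            if len(np.unique(labels)) < 2:
                continue
            ours = decoding.roc_auc(scores, labels)
            assert ours == pytest.approx(brute_force_auc(scores, labels))
            assert ours == pytest.approx(
                roc_auc_score(labels == "a", scores))

    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=20))
    @settings(max_examples=30, deadline=None)
    def test_monotone_invariance_and_label_flip(self, vals):
        # coarse grid so the monotone transform cannot create new float
        # ties between almost-equal scores
        scores = np.round(np.asarray(vals), 3)
        labels = np.array((["a", "b"] * 10)[:len(vals)])
        base = decoding.roc_auc(scores, labels)
        mono = decoding.roc_auc(np.exp(scores / 2.0), labels)
        assert base == pytest.approx(mono)
        flipped = decoding.roc_auc(
            scores, np.where(labels == "a", "b", "a"))
        assert flipped == pytest.approx(1.0 - base)


class TestShrinkageLda:
    def test_full_shrinkage_is_scaled_identity(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.repeat([0, 1], 15)
        m = decoding.fit_shrinkage_lda(X, y, lam=1.0)
        assert np.allclose(m.cov_shrunk,
                           (np.trace(m.cov) / 4) * np.eye(4))

    def test_zero_shrinkage_keeps_empirical(self, rng):
        X = rng.normal(size=(200, 3))
        y = np.repeat([0, 1], 100)
        m = decoding.fit_shrinkage_lda(X, y, lam=0.0)
        assert np.allclose(m.cov_shrunk, m.cov)

    def test_trace_preserved_for_all_lambda(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.repeat([0, 1], 20)
        for lam in (0.0, 0.2, 0.5, 0.9, 1.0):
            m = decoding.fit_shrinkage_lda(X, y, lam=lam)
            assert np.trace(m.cov_shrunk) == pytest.approx(np.trace(m.cov))

    def test_identity_covariance_closed_form(self, rng):
        X = np.concatenate([rng.normal([1, 0], 1e-3, size=(50, 2)),
                            rng.normal([0, 0], 1e-3, size=(50, 2))])
        y = np.repeat([0, 1], 50)
        m = decoding.fit_shrinkage_lda(X, y, lam=1.0)
        w = m.w / np.linalg.norm(m.w)
        assert abs(w[0]) == pytest.approx(1.0, abs=1e-3)

    def test_singular_unregularized_raises(self, rng):
        X = rng.normal(size=(8, 20))   # p > n
        y = np.repeat([0, 1], 4)
        with pytest.raises(ValueError, match="singular"):
            decoding.fit_shrinkage_lda(X, y, lam=0.0)

    def test_weights_converge_to_population_direction(self, rng):
        """Cosine similarity > 0.95 to Sigma^-1 (mu1 - mu2) at n = 2000."""
        p = 8
        A = rng.normal(size=(p, p))
        cov = A @ A.T / p + np.eye(p)
        mu1, mu2 = np.zeros(p), np.ones(p) * 0.5
        X = np.concatenate([
            rng.multivariate_normal(mu1, cov, size=1000),
            rng.multivariate_normal(mu2, cov, size=1000)])
        y = np.repeat([0, 1], 1000)
        m = decoding.fit_shrinkage_lda(X, y, lam="auto")
        ideal = np.linalg.solve(cov, mu1 - mu2)
        cos = m.w @ ideal / (np.linalg.norm(m.w) * np.linalg.norm(ideal))
        assert cos > 0.95


class TestPrepareExemplarTrials:
    def test_repetitions_averaged(self, small_dataset):
        tensor, _ = small_dataset
        X, y, ex = decoding.prepare_exemplar_trials(
            tensor, ("face", "watch"), rng=0, undersample=False)
        assert len(ex) == len(set(ex))
        one = ex[0]
        rows = tensor.trials[
            (tensor.trials["exemplar_id"] == one) &
            (tensor.trials["duration_ms"] >= 900)].index.to_numpy()
        assert np.allclose(X[0], tensor.hfa[rows].mean(axis=0))

    def test_undersampling_balances_classes(self, small_dataset):
        tensor, _ = small_dataset
        _, y, _ = decoding.prepare_exemplar_trials(
            tensor, ("face", "animal"), rng=0, undersample=True,
            min_duration_ms=0)
        counts = {c: (y == c).sum() for c in np.unique(y)}
        assert len(set(counts.values())) == 1

    def test_different_seeds_draw_different_subsets(self, small_dataset):
        tensor, _ = small_dataset
        out = [decoding.prepare_exemplar_trials(
            tensor, ("face", "animal"), rng=s, min_duration_ms=0)[2]
            for s in range(6)]
        assert any(not np.array_equal(out[0], o) for o in out[1:])


class TestDecoding:
    def test_noiseless_separable_gives_auc_one(self):
        prof = simulate.CodingProfile(tuning_strength=0.8,
                                      sustained_fraction=0.3)
        cfg = small_config(seed=8, noise_sd=0.0, durations_ms=(900,),
                          electrodes_per_region={"VT": 20},
                          region_profiles={"VT": prof},
                          fraction_unresponsive=0.0,
                          n_exemplars_per_category={"face": 15, "watch": 15})
        tensor, _ = simulate.generate_dataset(cfg)
        res = decoding.time_resolved_decoding(
            hfa.smooth_tensor(tensor, 50), ("face", "watch"), rng=1)
        coding = (res.times_ms >= 250) & (res.times_ms <= 700)
        assert np.allclose(res.auc[coding], 1.0)

    def test_untuned_data_near_chance_and_peak_not_significant(self):
        prof = simulate.CodingProfile(tuning_strength=0.0,
                                      exemplar_gain_sd=0.0)
        cfg = small_config(seed=13, durations_ms=(900,),
                          electrodes_per_region={"VT": 10},
                          region_profiles={"VT": prof},
                          n_exemplars_per_category={"face": 12, "watch": 12})
        tensor, _ = simulate.generate_dataset(cfg)
        sm = hfa.decimate(hfa.smooth_tensor(tensor, 50), 100.0)
        res = decoding.time_resolved_decoding(sm, ("face", "watch"), rng=2)
        assert abs(res.auc.mean() - 0.5) < 0.06
        null = decoding.decoding_null(sm, ("face", "watch"), n_perm=100,
                                      rng=3)
        assert decoding.peak_test(res.auc, null) > 0.05

    def test_tgm_diagonal_matches_time_resolved_run(self, smoothed_dataset):
        tensor, _ = smoothed_dataset
        vt = tensor.select_electrodes(region="VT")
        tgm_res = decoding.temporal_generalization(
            vt, ("face", "watch"), n_folds=3, n_repeats=2, rng=11)
        tr_res = decoding.time_resolved_decoding(
            vt, ("face", "watch"), n_folds=3, n_repeats=2, rng=11)
        assert np.allclose(np.diag(tgm_res.tgm), tr_res.auc)

    def test_sustained_vs_transient_cluster_extent(self, smoothed_dataset):
        """The sustained region's significant cluster spans the stimulus;
        the transient region's is confined to the onset epoch."""
        from hfadyn import perm_stats

        tensor, _ = smoothed_dataset
        tensor = hfa.decimate(tensor, 100.0)
        spans = {}
        for region in ("VT", "PFC"):
            sub = tensor.select_electrodes(region=region)
            res = decoding.time_resolved_decoding(
                sub, ("face", "watch"), n_repeats=2, rng=21)
            null = decoding.decoding_null(sub, ("face", "watch"),
                                          n_perm=100, rng=22)
            clusters = perm_stats.cluster_test(res.auc, null, threshold=0.6)
            sig = [c for c in clusters if c.p <= 0.05]
            assert sig, f"no significant cluster in {region}"
            times = np.concatenate(
                [res.times_ms[c.mask] for c in sig])
            spans[region] = (times.min(), times.max())
        assert spans["VT"][1] > 850.0      # persists through the stimulus
        assert spans["PFC"][1] < 850.0     # onset-limited
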