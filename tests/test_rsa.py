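"""RDMs, Item/Geometry Reliability, category models, partial correlation."""

import numpy as np
import pytest

from hfadyn import hfa, rsa, simulate

from conftest import small_config


def _categories(n_per=3):
    return np.repeat(["face", "watch", "object", "animal"], n_per)


def _patterns(rng, n, e=12):
    return rng.normal(size=(n, e))


class TestComputeRdm:
    def test_identical_patterns_zero_correlation_distance(self, rng):
        p = _patterns(rng, 1)[0]
        d = rsa.compute_rdm(np.stack([p, p]), "correlation")
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_pattern_distance_two(self, rng):
        p = _patterns(rng, 1)[0]
        d = rsa.compute_rdm(np.stack([p, -p]), "correlation")
        assert d[0, 1] == pytest.approx(2.0)

    def test_euclidean_hand_case(self):
        d = rsa.compute_rdm(np.array([[0.0, 0.0], [3.0, 4.0]]), "euclidean")
        assert d[0, 1] == pytest.approx(5.0)

    def test_symmetric_zero_diagonal(self, rng):
        d = rsa.compute_rdm(_patterns(rng, 6), "correlation")
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.all((d >= 0) & (d <= 2))

    def test_correlation_metric_affine_invariant(self, rng):
        p = _patterns(rng, 5)
        scale = rng.uniform(0.5, 2.0, size=(5, 1))
        shift = rng.normal(size=(5, 1))
        a = rsa.compute_rdm(p, "correlation")
        b = rsa.compute_rdm(scale * p + shift, "correlation")
        assert np.allclose(a, b)


class TestItemReliability:
    def test_perfect_repetition_gives_one(self, rng):
        p = _patterns(rng, 10)
        assert rsa.item_reliability(p, p.copy()) == pytest.approx(1.0)

    def test_too_few_exemplars_rejected(self, rng):
        p = _patterns(rng, 3)
        with pytest.raises(ValueError):
            rsa.item_reliability(p, p)

    def test_null_zscore_calibrated(self, rng):
        """IR z under its own null: mean ~ 0, SD ~ 1 across simulations."""
        zs = []
        for _ in range(40):
            P = rng.normal(size=(2, 10, 8, 1))
            raw, null = rsa._ir_timecourse(
                P, "correlation", rsa._draw_perms(10, 60, rng), None)
            zs.append(float(
                rsa.perm_stats.PermutationNull(null).zscore(raw)[0]))
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.5
        assert 0.5 < zs.std() < 1.8

    def test_planted_structure_recovered_monotonically(self, rng):
        """Stronger planted exemplar signal -> larger median IR z."""
        medians = []
        for gain in (0.0, 0.5, 1.5):
            zvals = []
            for _ in range(6):
                identity = gain * rng.normal(size=(12, 10))
                P = np.stack([identity + 0.8 * rng.normal(size=(12, 10)),
                              identity + 0.8 * rng.normal(size=(12, 10))]
                             )[:, :, :, None]
                raw, null = rsa._ir_timecourse(
                    P, "correlation", rsa._draw_perms(12, 80, rng), None)
                zvals.append(float(
                    rsa.perm_stats.PermutationNull(null).zscore(raw)[0]))
            medians.append(np.median(zvals))
        assert medians[0] < medians[1] < medians[2]


class TestGeometryReliability:
    def test_perfect_repetition_gives_one(self, rng):
        p = _patterns(rng, 10)
        assert rsa.geometry_reliability(p, p.copy()) == pytest.approx(1.0)

    def test_indistinguishable_exemplars_reduce_gr(self, rng):
        """Exemplars occupying similar positions within the geometry:
        shuffling them barely perturbs the null, so GR z drops relative
        to geometries with distinct exemplars — even though the
        category-level geometry is perfectly preserved."""
        def gr_z(base, noise):
            P = np.stack([base + noise * rng.normal(size=base.shape),
                          base + noise * rng.normal(size=base.shape)]
                         )[:, :, :, None]
            raw, null = rsa._gr_timecourse(
                P, "correlation", rsa._draw_perms(12, 100, rng), None)
            return float(rsa.perm_stats.PermutationNull(null).zscore(raw)[0])

        category_only = 5.0 * np.repeat(np.eye(4), 3, axis=0)  # 12 exemplars
        distinct = 2.0 * rng.normal(size=(12, 8))
        z_cat = np.median([gr_z(category_only, 0.2) for _ in range(8)])
        z_dist = np.median([gr_z(distinct, 0.2) for _ in range(8)])
        assert z_cat < z_dist - 0.5

    def test_distinct_exemplars_match_independent_oracle(self, rng):
        """GR raw value against a from-scratch reference implementation."""
        from scipy.stats import spearmanr

        p1, p2 = _patterns(rng, 8), _patterns(rng, 8)

        def oracle(p1, p2):
            both = np.concatenate([p1, p2], axis=0)
            full = rsa.compute_rdm(both, "correlation")
            N = len(p1)
            W1, W2 = full[:N, :N], full[N:, N:]
            B = full[:N, N:]
            iu = np.triu_indices(N, 1)
            g1 = (W1[iu] + B[iu]) / 2.0
            g2 = (W2[iu] + B.T[iu]) / 2.0
            return spearmanr(g1, g2).statistic

        ours = rsa.geometry_reliability(p1, p2)
        assert ours == pytest.approx(oracle(p1, p2), abs=1e-10)


class TestCategoryModels:
    @pytest.mark.parametrize("model, a, b, expected", [
        ("low-level", "face", "watch", 0.5),
        ("low-level", "object", "animal", 0.5),
        ("low-level", "face", "animal", 1.0),
        ("semantic", "face", "animal", 0.5),
        ("face-vs-rest", "watch", "animal", 0.5),
        ("face-vs-rest", "face", "object", 1.0),
        ("single-category", "face", "watch", 1.0),
    ])
    def test_model_cells(self, model, a, b, expected):
        m = rsa.category_model_rdm(model, [a, b])
        assert m[0, 1] == expected

    def test_within_category_always_zero(self):
        for model in rsa.CATEGORY_MODELS:
            m = rsa.category_model_rdm(model, ["face", "face"])
            assert m[0, 1] == 0.0

    def test_values_and_symmetry(self):
        m = rsa.category_model_rdm("semantic", _categories())
        assert np.allclose(m, m.T)
        assert set(np.unique(m)) <= {0.0, 0.5, 1.0}

    def test_unknown_inputs_rejected(self):
        with pytest.raises(ValueError):
            rsa.category_model_rdm("fancy", ["face"])
        with pytest.raises(ValueError):
            rsa.category_model_rdm("semantic", ["house"])


class TestPartialCorrelation:
    def test_category_only_structure_suppressed_after_partialing(self, rng):
        """Neural geometry = category model + noise: partialing the model
        removes the category-driven reliability.

        A small residual remains by design — the statistics are also
        sensitive to the anchor's state-space position, which the flat
        category model cannot absorb — so the check is a strong reduction
        of GR z to below the cluster-forming level, not exact zero.
        """
        cats = _categories(3)
        # equidistant centroids (orthonormal basis) so the neural RDM
        # matches the flat between-category structure of the model
        eye = np.eye(8)
        centroids = {c: 6.0 * eye[k] for k, c in
                     enumerate(("face", "watch", "object", "animal"))}
        base = np.stack([centroids[c] for c in cats])
        model = rsa.category_model_rdm("single-category", cats)
        mv = rsa._triu(model)
        z_plain, z_part = [], []
        for _ in range(8):
            P = np.stack([base + 0.3 * rng.normal(size=base.shape),
                          base + 0.3 * rng.normal(size=base.shape)]
                         )[:, :, :, None]
            perms = rsa._draw_perms(12, 100, rng)
            raw, null = rsa._gr_timecourse(P, "correlation", perms, None)
            z_plain.append(float(
                rsa.perm_stats.PermutationNull(null).zscore(raw)[0]))
            raw2, null2 = rsa._gr_timecourse(P, "correlation", perms, mv)
            z_part.append(float(
                rsa.perm_stats.PermutationNull(null2).zscore(raw2)[0]))
        assert np.median(z_plain) > 2.5
        assert np.median(z_part) < np.median(z_plain) - 0.5
        assert np.median(z_part) < 2.5

    def test_constant_model_partialing_is_noop(self, rng):
        """A model with no category groups is a degenerate covariate: a
        single-category model over one category is all ties, so
        partialing it leaves the correlation unchanged."""
        p1, p2 = _patterns(rng, 8), _patterns(rng, 8)
        model = rsa.category_model_rdm("single-category", ["face"] * 8)
        plain = rsa.item_reliability(p1, p2)
        part = rsa.item_reliability(p1, p2, model_rows=rsa._offdiag(model))
        assert part == pytest.approx(plain, abs=1e-10)

    def test_orthogonal_structure_unaffected(self, rng):
        """Exemplar structure without category structure survives
        partialing nearly unchanged."""
        identity = 2.0 * rng.normal(size=(12, 8))
        p1 = identity + 0.3 * rng.normal(size=(12, 8))
        p2 = identity + 0.3 * rng.normal(size=(12, 8))
        model = rsa.category_model_rdm("single-category", _categories(3))
        plain = rsa.item_reliability(p1, p2)
        partial = rsa.item_reliability(p1, p2,
                                       model_rows=rsa._offdiag(model))
        assert partial == pytest.approx(plain, abs=0.15)

    def test_matches_pingouin_partial_spearman(self, rng):
        import pandas as pd
        import pingouin as pg

        x, y = rng.normal(size=30), rng.normal(size=30)
        m = rng.normal(size=30)
        ours = float(rsa._row_spearman(x[None], y[None], m[None])[0])
        ref = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "m": m}),
                              x="x", y="y", covar="m", method="spearman")
        assert ours == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)


class TestThresholdAndModels:
    def test_analytic_threshold_for_60_image_geometry(self):
        # 60 images -> 1770 pairs -> 1.645 / sqrt(1770) = 0.0391
        assert rsa.spearman_threshold(1770) == pytest.approx(0.0391,
                                                             abs=5e-5)

    def test_threshold_calibrated_by_monte_carlo(self, rng):
        """P(rho >= threshold) ~ alpha for independent rank vectors."""
        n_pairs, n_sims = 1770, 800
        thr = rsa.spearman_threshold(n_pairs)
        x = rng.normal(size=(n_sims, n_pairs))
        y = rng.normal(size=(1, n_pairs))
        rho = rsa._row_pearson(rsa._rank_rows(x),
                               rsa._rank_rows(np.repeat(y, n_sims, axis=0)))
        rate = (rho >= thr).mean()
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_neural_rdm_equal_model_gives_rho_one(self, rng):
        cfg = small_config(seed=51, durations_ms=(900,),
                           electrodes_per_region={"VT": 10},
                           noise_sd=0.3,
                           n_exemplars_per_category={"face": 4, "watch": 4,
                                                     "object": 3,
                                                     "animal": 3})
        tensor, _ = simulate.generate_dataset(cfg)
        res = rsa.model_correlation_timecourse(
            hfa.smooth_tensor(tensor, 50), "single-category",
            n_perm=30, rng=1)
        assert res["rho"].shape == tensor.times_ms.shape
        assert np.all(res["rho"] <= 1.0)

    def test_strongest_model_recovers_planted_low_level_structure(self, rng):
        """Tuning built from low-level groups makes that model win."""
        groups = {"face": 0, "watch": 0, "object": 1, "animal": 1}
        e = 12
        gvec = {0: rng.normal(size=e), 1: rng.normal(size=e)}
        tuning = np.stack([2.0 * gvec[groups[c]] +
                           0.3 * rng.normal(size=e)
                           for c in ("face", "watch", "object", "animal")],
                          axis=1)
        prof = simulate.CodingProfile(category_tuning=tuning,
                                      exemplar_gain_sd=0.1,
                                      sustained_fraction=0.4)
        cfg = small_config(seed=52, durations_ms=(900,), noise_sd=0.3,
                           electrodes_per_region={"VT": e},
                           region_profiles={"VT": prof},
                           fraction_unresponsive=0.0,
                           fraction_negative_responders=0.0,
                           n_exemplars_per_category={"face": 5, "watch": 5,
                                                     "object": 4,
                                                     "animal": 4})
        tensor, _ = simulate.generate_dataset(cfg)
        best = rsa.strongest_model(hfa.smooth_tensor(tensor, 50),
                                   models=("low-level", "semantic"))
        assert best == "low-level"


class TestStability:
    def test_diagonal_equals_reliability_timecourse(self, rng):
        P = rng.normal(size=(2, 8, 6, 5))
        perms = rsa._draw_perms(8, 40, rng=3)
        raw_ir, _ = rsa._ir_timecourse(P, "correlation", perms, None)
        stab = rsa.stability_matrix(P, metric="IR", n_perm=40, rng=3)
        assert np.allclose(np.diag(stab["raw"]), raw_ir, atol=1e-10)

    def test_stable_code_generalizes_dynamic_does_not(self, rng):
        """Consistent exemplar patterns across time give high off-diagonal
        stability; orthogonal early/late patterns give ~0 across epochs."""
        n, e = 10, 12
        early = 2.0 * rng.normal(size=(n, e))
        late = 2.0 * rng.normal(size=(n, e))

        def build(second_half):
            P = np.empty((2, n, e, 6))
            for r in range(2):
                for ti in range(6):
                    pat = early if ti < 3 else second_half
                    P[r, :, :, ti] = pat + 0.4 * rng.normal(size=(n, e))
            return P

        stab_stable = rsa.stability_matrix(build(early), metric="IR",
                                           n_perm=60, rng=1)
        stab_dyn = rsa.stability_matrix(build(late), metric="IR",
                                        n_perm=60, rng=1)
        cross_stable = stab_stable["z"][:3, 3:].mean()
        cross_dyn = stab_dyn["z"][:3, 3:].mean()
        assert cross_stable > 3.0
        assert abs(cross_dyn) < 2.0
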