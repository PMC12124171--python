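import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclecover import (
    BackgroundConfig,
    ClimateStack,
    Grid,
    ModelSearchConfig,
    PredictorConfig,
    binarize,
    build_features,
    checkerboard2_partition,
    collinearity_filter,
    evaluate_auc,
    fit_maxent,
    gibbs_entropy,
    max_sss_threshold,
    predict_suitability,
    sample_background,
    select_and_fit,
)
from cyclecover.enm import maxent_objective

RNG = np.random.default_rng(42)


def _stack(layers, cell_area=4.0):
    first = next(iter(layers.values()))
    grid = Grid(nrows=first.shape[0], ncols=first.shape[1], cell_area_km2=cell_area)
    return ClimateStack(grid, dict(layers))


class TestCollinearityFilter:
    def test_identical_pair_keeps_one(self):
        a = RNG.normal(size=(20, 20))
        retained = collinearity_filter(_stack({"a": a, "b": a.copy()}))
        assert len(retained) == 1

    def test_uncorrelated_layers_all_retained(self):
        layers = {f"l{i}": RNG.normal(size=(30, 30)) for i in range(4)}
        assert len(collinearity_filter(_stack(layers))) == 4

    def test_near_duplicate_dropped_independent_kept(self):
        a = RNG.normal(size=(30, 30))
        b = a + 1e-3 * RNG.normal(size=a.shape)
        c = RNG.normal(size=a.shape)
        corr = abs(np.corrcoef([a.ravel(), b.ravel(), c.ravel()]))
        assert corr[0, 1] > 0.99  # the planted collinear pair
        retained = collinearity_filter(_stack({"a": a, "b": b, "c": c}))
        assert len(retained) == 2 and "c" in retained
        assert ("a" in retained) != ("b" in retained)

    def test_threshold_is_configurable(self):
        a = RNG.normal(size=(30, 30))
        b = 0.6 * a + 0.8 * RNG.normal(size=a.shape)  # r ~ 0.6
        names = collinearity_filter(_stack({"a": a, "b": b}),
                                    PredictorConfig(r_max=0.3))
        assert len(names) == 1


class TestBackgroundSampling:
    def test_buffer_limits_candidates_and_sample_is_deterministic(self):
        layers = {"x": RNG.normal(size=(50, 50))}
        stack = _stack(layers, cell_area=4.0)  # 2-km cells
        occ = np.array([[25, 25]])
        cfg = BackgroundConfig(n_background=10_000, buffer_km=10.0, seed=3)
        bg = sample_background(stack, occ, cfg)
        ox, oy = stack.grid.cell_center(occ[:, 0], occ[:, 1])
        bx, by = stack.grid.cell_center(bg[:, 0], bg[:, 1])
        dist = np.hypot(bx - ox, by - oy)
        assert (dist <= 10.0).all()
        # smaller candidate pool than requested -> all candidates returned
        assert len(bg) < 10_000
        bg2 = sample_background(stack, occ, cfg)
        assert np.array_equal(bg, bg2)

    def test_presence_cells_excluded_by_default(self):
        stack = _stack({"x": RNG.normal(size=(20, 20))})
        occ = np.array([[10, 10], [10, 11]])
        bg = sample_background(stack, occ, BackgroundConfig(buffer_km=1e6, seed=0))
        assert not any((tuple(c) in {(10, 10), (10, 11)}) for c in bg)


class TestFeatures:
    def test_linear_only_is_the_rescaled_covariate(self):
        X = np.linspace(0, 1, 11)[:, None]
        F, exp = build_features(X, "L", bounds=(np.array([0.0]), np.array([1.0])))
        assert np.allclose(F[:, 0], X[:, 0])
        assert exp.feature_classes == ["L"]

    def test_quadratic_square(self):
        X = np.array([[0.5], [0.0], [1.0]])
        F, _ = build_features(X, "LQ", bounds=(np.array([0.0]), np.array([1.0])))
        assert np.allclose(F[0], [0.5, 0.25])

    def test_hinge_closed_form(self):
        # 4 interior knots -> t in {0.2, 0.4, 0.6, 0.8}
        X = np.array([[0.7]])
        F, exp = build_features(X, "H", n_hinge_knots=4,
                                bounds=(np.array([0.0]), np.array([1.0])))
        idx = exp.feature_names.index("hingeF(x0,0.4000)")
        assert F[0, idx] == pytest.approx((0.7 - 0.4) / (1 - 0.4))
        ridx = exp.feature_names.index("hingeR(x0,0.4000)")
        assert F[0, ridx] == pytest.approx(0.0)

    def test_products_and_thresholds(self):
        X = np.array([[0.3, 0.6]])
        F, exp = build_features(X, "PT", n_threshold_knots=4,
                                bounds=(np.zeros(2), np.ones(2)))
        assert F[0, exp.feature_names.index("x0*x1")] == pytest.approx(0.18)
        assert F[0, exp.feature_names.index("step(x1,0.4000)")] == 1.0
        assert F[0, exp.feature_names.index("step(x0,0.4000)")] == 0.0

    def test_degenerate_covariate_rejected(self):
        X = np.ones((5, 1))
        with pytest.raises(ValueError, match="degenerate"):
            build_features(X, "L")

    def test_expansion_rebuilds_features_on_new_data(self):
        Xb = RNG.uniform(0, 10, size=(100, 2))
        F, exp = build_features(Xb, "LQH")
        F2, n_clamped = exp.transform(Xb)
        assert np.allclose(F, F2) and n_clamped == 0
        _, clamped = exp.transform(np.array([[100.0, -5.0]]))
        assert clamped == 2


class TestFitMaxent:
    def test_no_signal_shrinks_to_zero(self):
        # presences share the background feature distribution exactly
        F = RNG.normal(size=(600, 3))
        fit = fit_maxent(F, F, multiplier=1.0)
        assert np.all(np.abs(fit.beta) < 1e-3)

    def test_sign_recovered_for_concentrated_presences(self):
        xb = RNG.uniform(0, 1, size=(500, 1))
        xp = RNG.uniform(0.7, 1.0, size=(60, 1))
        fit = fit_maxent(xp, xb, multiplier=1.0)
        assert fit.beta[0] > 0
        # sign oracle: direct likelihood evaluation on a 1-D beta grid
        lam = fit.lambdas
        grid_obj = [maxent_objective(np.array([b]), xp, xb, lam)
                    for b in np.linspace(-5, 5, 201)]
        assert np.linspace(-5, 5, 201)[int(np.argmin(grid_obj))] > 0

    def test_stationarity_at_vanishing_penalty(self):
        # maximum-entropy stationarity: model-expected features match presences
        xb = RNG.uniform(0, 1, size=(400, 2))
        xp = np.clip(xb[:80] + 0.2, 0, 1)
        fit = fit_maxent(xp, xb, multiplier=1e-8, tol=1e-12)
        eta = xb @ fit.beta
        q = np.exp(eta - eta.max())
        q /= q.sum()
        model_mean = q @ xb
        assert np.allclose(model_mean, xp.mean(axis=0), atol=1e-3)

    def test_constant_background_feature_is_pinned_at_zero(self):
        Fb = np.column_stack([RNG.uniform(size=300), np.zeros(300)])
        Fp = np.column_stack([RNG.uniform(0.5, 1, size=50), np.ones(50)])
        fit = fit_maxent(Fp, Fb, multiplier=1.0)
        assert fit.beta[1] == 0.0


class TestCheckerboard:
    def test_all_four_bins_on_16x16(self):
        grid = Grid(nrows=16, ncols=16)
        cells = np.array(list(itertools.product(range(16), range(16))))
        labels = checkerboard2_partition(cells, grid, (2, 2))
        assert set(labels) == {1, 2, 3, 4}

    def test_same_fine_block_same_label(self):
        grid = Grid(nrows=16, ncols=16)
        labels = checkerboard2_partition(np.array([[4, 6], [5, 7]]), grid, (2, 2))
        assert labels[0] == labels[1]

    def test_labels_partition_the_lattice_evenly(self):
        grid = Grid(nrows=64, ncols=64)
        cells = np.array(list(itertools.product(range(64), range(64))))
        labels = checkerboard2_partition(cells, grid, (2, 2))
        frac = np.bincount(labels, minlength=5)[1:] / len(cells)
        assert np.all(np.abs(frac - 0.25) < 0.05)

    def test_each_cell_gets_exactly_one_label(self):
        grid = Grid(nrows=16, ncols=16)
        cells = np.array(list(itertools.product(range(16), range(16))))
        l1 = checkerboard2_partition(cells, grid, (2, 2))
        l2 = checkerboard2_partition(cells, grid, (2, 2))
        assert np.array_equal(l1, l2)  # deterministic, cell-only function

    def test_grid_smaller_than_coarse_block_rejected(self):
        with pytest.raises(ValueError, match="coarse"):
            checkerboard2_partition(np.array([[0, 0]]), Grid(nrows=3, ncols=3), (2, 2))


class TestAUC:
    @pytest.mark.parametrize("p,b,expected", [
        ([0.9, 0.8], [0.1, 0.2], 1.0),
        ([0.5, 0.5, 0.1], [0.5, 0.5, 0.1], 0.5),
        ([0.9, 0.4], [0.5, 0.1], 0.75),
    ])
    def test_known_values(self, p, b, expected):
        assert evaluate_auc(np.array(p), np.array(b)) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(0, 10), min_size=1, max_size=10),
           st.lists(st.integers(0, 10), min_size=1, max_size=10))
    def test_matches_brute_force_pair_counting(self, p, b):
        p, b = np.array(p, dtype=float), np.array(b, dtype=float)
        pairs = [(1.0 if x > y else 0.5 if x == y else 0.0) for x in p for y in b]
        assert evaluate_auc(p, b) == pytest.approx(np.mean(pairs))

    def test_monotone_transform_invariance(self):
        p, b = RNG.normal(size=30), RNG.normal(size=50)
        assert evaluate_auc(p, b) == pytest.approx(evaluate_auc(np.exp(p), np.exp(b)))


class TestThreshold:
    def test_perfect_separation_brute_force(self):
        p = np.array([0.9, 0.8, 0.7])
        b = np.array([0.1, 0.2, 0.3])
        tau, sens, spec = max_sss_threshold(p, b)
        assert sens == 1.0 and spec == 1.0
        assert tau == pytest.approx(0.3)  # largest observed score below 0.7
        mask, _ = binarize(np.array([[0.9, 0.1]]), p, b)
        assert mask.tolist() == [[True, False]]

    def test_brute_force_oracle_on_overlapping_scores(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.3, 1.0, 40)
        b = rng.uniform(0.0, 0.7, 60)
        tau, sens, spec = max_sss_threshold(p, b)
        # oracle: evaluate sens+spec over every candidate by brute force
        best = max((p >= t).mean() + (b < t).mean() for t in np.unique(p))
        assert sens + spec == pytest.approx(best)
        assert (p > tau).mean() == pytest.approx(sens)
        assert (b <= tau).mean() == pytest.approx(spec)

    def test_degenerate_identical_multisets(self):
        p = np.array([0.2, 0.5, 0.8])
        tau, sens, spec = max_sss_threshold(p, p.copy())
        assert sens + spec == pytest.approx(1.0)
        # smallest candidate wins the tie: everything >= 0.2 is presence
        assert (p > tau).all()

    def test_all_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            max_sss_threshold(np.full(5, 0.5), np.full(7, 0.5))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_binary_map_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=15)
        b = rng.uniform(size=25)
        smap = rng.uniform(size=(6, 6))
        m1, _ = binarize(smap, p, b)
        g = lambda x: np.expm1(3 * x)  # strictly increasing
        m2, _ = binarize(g(smap), g(p), g(b))
        assert np.array_equal(m1, m2)


class TestSelectionAndPrediction:
    def test_single_candidate_is_selected(self, small_world, seasonal_sets):
        cfg = ModelSearchConfig(feature_class_combos=("L",),
                                regularization_multipliers=(1.0,))
        model = select_and_fit(seasonal_sets[0], small_world.climate,
                               BackgroundConfig(n_background=800, seed=1), cfg)
        assert model.feature_class_combo == "L"
        assert model.reg_multiplier == 1.0
        assert 0.0 <= model.mean_test_auc <= 1.0

    def test_auc_ties_broken_toward_simpler_smoother_model(self, small_world,
                                                           seasonal_sets,
                                                           monkeypatch):
        # force every candidate to the same AUC so only the tie-break decides
        import cyclecover.enm as enm

        monkeypatch.setattr(enm, "evaluate_auc", lambda p, b: 0.75)
        cfg = ModelSearchConfig(feature_class_combos=("LQH", "L", "LQ"),
                                regularization_multipliers=(0.5, 1.0))
        model = select_and_fit(seasonal_sets[0], small_world.climate,
                               BackgroundConfig(n_background=500, seed=1), cfg)
        assert model.feature_class_combo == "L"
        assert model.reg_multiplier == 1.0

    def test_prediction_is_monotone_in_linear_predictor(self, small_world,
                                                        seasonal_sets):
        cfg = ModelSearchConfig(feature_class_combos=("L",),
                                regularization_multipliers=(1.0,))
        model = select_and_fit(seasonal_sets[0], small_world.climate,
                               BackgroundConfig(n_background=800, seed=1), cfg)
        suit = predict_suitability(model, small_world.climate)
        cells = small_world.climate.valid_cells()
        X = small_world.climate.values_at(cells, model.expansion.covariate_names)
        eta, _ = model.linear_predictor(X)
        s = suit[cells[:, 0], cells[:, 1]]
        order = np.argsort(eta)
        assert (np.diff(s[order]) >= -1e-12).all()
        assert ((s > 0) & (s < 1)).all()

    def test_uniform_two_cell_background_entropy_is_ln2(self):
        assert gibbs_entropy(np.array([1.3, 1.3])) == pytest.approx(np.log(2))

    def test_zero_coefficients_give_constant_map(self, small_world):
        from cyclecover.enm import FeatureExpansion, NicheModel
        from cyclecover import Season

        exp = FeatureExpansion(classes="L", covariate_names=["bio01"],
                               lower=np.array([-3.0]), upper=np.array([3.0]),
                               hinge_knots=np.array([0.5]),
                               threshold_knots=np.array([0.5]))
        model = NicheModel(species="s", season=Season.S1, expansion=exp,
                           beta=np.zeros(1), log_z=0.0, entropy=np.log(100),
                           reg_multiplier=1.0, fold_aucs=[0.5], mean_test_auc=0.5,
                           threshold=0.5, threshold_sensitivity=1.0,
                           threshold_specificity=0.0)
        suit = predict_suitability(model, small_world.climate.subset(["bio01"]))
        vals = suit[np.isfinite(suit)]
        assert np.allclose(vals, vals[0])

    def test_model_json_roundtrip(self, small_world, seasonal_sets, tmp_path):
        cfg = ModelSearchConfig(feature_class_combos=("LQ",),
                                regularization_multipliers=(1.0,))
        model = select_and_fit(seasonal_sets[0], small_world.climate,
                               BackgroundConfig(n_background=500, seed=2), cfg)
        path = tmp_path / "model.json"
        model.to_json(path)
        from cyclecover import NicheModel

        back = NicheModel.from_json(path)
        suit1 = predict_suitability(model, small_world.climate)
        suit2 = predict_suitability(back, small_world.climate)
        assert np.allclose(suit1, suit2, equal_nan=True)
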