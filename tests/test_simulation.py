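"""Predictor simulation: data generation, L1 solver, CV selection, summary."""

import numpy as np
import pytest

from dcis_cna._l1 import fit_l1_fixed, fit_l1_path, l1_objective, lambda_max
from dcis_cna.simulation import (
    FREQ_CLASSES,
    FeatureClass,
    SimDesign,
    auc_score,
    default_roster,
    fit_l1_cv,
    generate_sim_dataset,
    run_simulation,
)

# a separable 2-feature toy: feature 1 tracks the label exactly
SEPARABLE_X = np.array(
    [[1, 0], [1, 1], [1, 0], [1, 1], [0, 1], [0, 0], [0, 1], [0, 0]], dtype=float
)
SEPARABLE_Y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)


class TestRoster:
    def test_default_composition(self):
        roster = default_roster()
        assert len(roster) == 22
        by_freq = {f: sum(fc.freq == f for fc in roster) for f in FREQ_CLASSES}
        assert by_freq == {"LF": 10, "MF": 6, "HF": 6}
        differential = [fc for fc in roster if fc.diff != "ND"]
        assert len(differential) == 9
        cells = {(fc.freq, fc.diff) for fc in differential}
        assert cells == {
            (f, d) for f in ("LF", "MF", "HF") for d in ("LD", "MD", "HD")
        }

    def test_case_frequency_is_fold_times_base_capped(self):
        assert FeatureClass("HF", "HD").case_freq == pytest.approx(0.90)
        assert FeatureClass("LF", "MD").case_freq == pytest.approx(0.075)
        assert FeatureClass("MF", "ND").case_freq == pytest.approx(0.15)

    def test_invalid_classes_raise(self):
        with pytest.raises(ValueError):
            FeatureClass("XF", "HD")
        with pytest.raises(ValueError):
            FeatureClass("LF", "XX")


class TestGenerateDataset:
    def test_empirical_frequencies(self):
        design = SimDesign(n_cases=50_000, n_controls=50_000)
        X, y = generate_sim_dataset(design, rng=3)
        for j, fc in enumerate(design.features):
            for label, expect in ((1.0, fc.case_freq), (0.0, fc.control_freq)):
                obs = X[y == label, j].mean()
                se = np.sqrt(expect * (1 - expect) / 50_000)
                assert abs(obs - expect) < 3.5 * se, (j, fc.label, label)

    def test_all_controls_when_no_cases(self):
        X, y = generate_sim_dataset(SimDesign(n_cases=0, n_controls=30), rng=0)
        assert (y == 0).all() and X.shape == (30, 22)

    def test_deterministic_given_seed(self):
        d = SimDesign()
        X1, _ = generate_sim_dataset(d, rng=9)
        X2, _ = generate_sim_dataset(d, rng=9)
        assert np.array_equal(X1, X2)


class TestAucScore:
    def test_perfect_and_reversed(self):
        y = np.array([0, 0, 1, 1.0])
        assert auc_score(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert auc_score(y, np.array([0.9, 0.8, 0.2, 0.1])) == 0.0

    def test_ties_give_half_credit(self):
        y = np.array([0, 1.0])
        assert auc_score(y, np.array([0.5, 0.5])) == 0.5

    def test_single_class_is_nan(self):
        assert np.isnan(auc_score(np.ones(4), np.arange(4.0)))

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            y = (rng.random(60) < 0.4).astype(float)
            if y.sum() in (0, 60):
                continue
            s = rng.normal(size=60).round(1)  # induce ties
            assert auc_score(y, s) == pytest.approx(sk.roc_auc_score(y, s))


class TestL1Solver:
    def test_full_shrinkage_at_lambda_max(self):
        X, y = generate_sim_dataset(SimDesign(), rng=2)
        lam = lambda_max(X, y)
        b0, b = fit_l1_fixed(X, y, lam * 1.0001)
        assert np.count_nonzero(b) == 0
        assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-5)

    def test_just_below_lambda_max_activates_a_feature(self):
        X, y = generate_sim_dataset(SimDesign(), rng=2)
        lam = lambda_max(X, y)
        _, b = fit_l1_fixed(X, y, lam * 0.95)
        assert np.count_nonzero(b) >= 1

    def test_separable_toy_unpenalized(self):
        b0, b = fit_l1_fixed(SEPARABLE_X, SEPARABLE_Y, 1e-6)
        assert b[0] > 0  # the informative feature is active
        eta = b0 + SEPARABLE_X @ b
        assert auc_score(SEPARABLE_Y, eta) == 1.0

    def test_matches_brute_force_grid_search(self, rng):
        """Coordinate descent equals an exhaustive penalized-likelihood
        search over a refined coefficient grid on 2-feature problems."""
        for seed in (3, 4):
            r = np.random.default_rng(seed)
            X = (r.random((100, 2)) < 0.3).astype(float)
            eta = -0.5 + X @ np.array([1.5, -0.4])
            y = (r.random(100) < 1 / (1 + np.exp(-eta))).astype(float)
            lam = 0.4 * lambda_max(X, y)
            b0, b = fit_l1_fixed(X, y, lam)
            center = np.r_[b0, b] * 0.0  # start the search blind at zero
            width = 2.5
            for _ in range(30):  # iterative grid refinement
                grids = [np.linspace(c - width, c + width, 11) for c in center]
                best, best_val = None, np.inf
                for g0 in grids[0]:
                    for g1 in grids[1]:
                        for g2 in grids[2]:
                            val = l1_objective(X, y, g0, np.array([g1, g2]), lam)
                            if val < best_val:
                                best, best_val = (g0, g1, g2), val
                center = np.array(best)
                width *= 0.35
            assert b0 == pytest.approx(center[0], abs=1e-4)
            assert b == pytest.approx(center[1:], abs=1e-4)
            assert l1_objective(X, y, b0, b, lam) == pytest.approx(
                best_val, abs=1e-8
            )

    def test_matches_sklearn_l1_path_point(self):
        import warnings

        lm = pytest.importorskip("sklearn.linear_model")
        X, y = generate_sim_dataset(SimDesign(n_cases=100, n_controls=100), rng=6)
        lam = 0.3 * lambda_max(X, y)
        b0, b = fit_l1_fixed(X, y, lam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # saga leaves the intercept unpenalized, matching our objective
            clf = lm.LogisticRegression(
                penalty="l1",
                C=1.0 / (len(y) * lam),
                solver="saga",
                tol=1e-10,
                max_iter=100_000,
            ).fit(X, y)
        assert b == pytest.approx(clf.coef_[0], abs=1e-6)
        assert b0 == pytest.approx(clf.intercept_[0], abs=1e-6)

    def test_warm_start_path_consistent_with_cold_fits(self):
        X, y = generate_sim_dataset(SimDesign(), rng=8)
        lam_max = lambda_max(X, y)
        grid = np.geomspace(lam_max, lam_max / 100, 8)
        _, path = fit_l1_path(X, y, grid)
        for i in (0, 3, 7):
            _, cold = fit_l1_fixed(X, y, grid[i])
            assert path[i] == pytest.approx(cold, abs=1e-4)


class TestFitL1CV:
    def test_degenerate_labels_raise(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            fit_l1_cv(X, np.ones(10), rng=0)

    def test_selected_lambda_in_grid_and_active_set_consistent(self):
        X, y = generate_sim_dataset(SimDesign(), rng=4)
        res = fit_l1_cv(X, y, rng=4)
        assert res.selected_lambda in res.lambda_grid
        assert res.n_active == np.count_nonzero(res.coef)
        assert 0.0 <= res.heldout_auc <= 1.0

    def test_deterministic_given_rng_seed(self):
        X, y = generate_sim_dataset(SimDesign(), rng=4)
        a = fit_l1_cv(X, y, rng=11)
        b = fit_l1_cv(X, y, rng=11)
        assert a.selected_lambda == b.selected_lambda
        assert np.array_equal(a.active, b.active)
        assert a.heldout_auc == b.heldout_auc


class TestRunSimulation:
    def test_full_determinism(self):
        design = SimDesign(n_iterations=8, seed=21)
        s1 = run_simulation(design)
        s2 = run_simulation(design)
        assert s1.selection_proportion.equals(s2.selection_proportion)
        assert np.array_equal(s1.auc, s2.auc)

    def test_null_design_auc_near_half(self):
        """With every feature nondifferential the predictor has nothing to
        learn: held-out AUC centres near 0.5 and features within a frequency
        class (which are exchangeable by construction) are selected at
        matching rates.  Selection does still rise with base frequency even
        under the null — higher-variance features yield larger spurious
        score correlations — so no across-class equality is asserted."""
        roster = tuple(
            FeatureClass(f, "ND")
            for f, k in (("LF", 10), ("MF", 6), ("HF", 6))
            for _ in range(k)
        )
        design = SimDesign(features=roster, n_iterations=150, seed=5)
        s = run_simulation(design)
        assert 0.45 <= s.auc.mean() <= 0.55
        rates = s.feature_selection_rate
        for block in (rates[:10], rates[10:16], rates[16:]):
            assert block.max() - block.min() < 0.15

    def test_differential_classes_selected_more_than_null_peers(self):
        design = SimDesign(n_iterations=60, seed=17)
        s = run_simulation(design)
        sel = s.selection_proportion
        for f in ("MF", "HF"):
            assert sel[(f, "HD")] >= sel[(f, "ND")]
            assert sel[(f, "HD")] > 0.9
        assert sel[("LF", "HD")] > sel[("LF", "LD")]

    def test_json_round_trip_keys(self):
        import json

        design = SimDesign(n_iterations=4, seed=2)
        payload = json.loads(run_simulation(design).to_json())
        assert payload["n_iterations"] == 4
        assert "LFxHD" in payload["selection_proportion"]
        assert "mean" in payload["auc"]
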