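"""RR-BLUP core, cross-validation schemes, hold-out parents and the frontier."""

import numpy as np
import pandas as pd
import pytest

from milletgs.errors import AlignmentError, ModelError, ParameterError
from milletgs.genomic_prediction import (
    SchemeConfig,
    compare_schemes,
    default_marker_counts,
    holdout_parent_cv,
    pareto_frontier,
    predict,
    predict_all_hybrids,
    rrblup_fit,
    run_scheme,
)
from milletgs.experiments import scheme_accuracies, simulate_prediction_study


class TestRRBlupCore:
    def test_fixed_lambda_matches_closed_form_ridge(self, rng):
        X = pd.DataFrame(rng.integers(0, 3, (6, 3)).astype(float),
                         index=list("abcdef"), columns=["m1", "m2", "m3"])
        y = pd.Series(rng.normal(0, 1, 6), index=X.index)
        model = rrblup_fit(X, y, lambda_=1.0)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        expected = np.linalg.solve(Xc.T @ Xc + np.eye(3),
                                   Xc.T @ (y.to_numpy() - y.mean()))
        np.testing.assert_allclose(model.effects.to_numpy(), expected, atol=1e-12)
        assert model.mu == pytest.approx(y.mean())

    def test_marker_and_kernel_spaces_agree(self, rng):
        for _ in range(5):
            X = pd.DataFrame(rng.choice([0.0, 0.5, 1.0, 1.5, 2.0], size=(20, 500)))
            y = pd.Series(rng.normal(0, 1, 20))
            model = rrblup_fit(X, y)  # kernel path (n < k)
            Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
            dual = np.linalg.solve(Xc.T @ Xc + model.lambda_ * np.eye(500),
                                   Xc.T @ (y.to_numpy() - y.mean()))
            assert np.max(np.abs(model.effects.to_numpy() - dual)) < 1e-8

    def test_large_lambda_shrinks_to_mean(self, rng):
        X = pd.DataFrame(rng.integers(0, 3, (15, 40)).astype(float))
        y = pd.Series(rng.normal(5, 1, 15))
        model = rrblup_fit(X, y, lambda_=1e12)
        assert np.max(np.abs(model.effects)) < 1e-6
        np.testing.assert_allclose(predict(model, X), y.mean(), atol=1e-4)

    def test_constant_response_warns_and_zeroes(self, rng):
        X = pd.DataFrame(rng.integers(0, 3, (8, 5)).astype(float))
        with pytest.warns(UserWarning, match="constant"):
            model = rrblup_fit(X, pd.Series(np.full(8, 3.0)))
        assert (model.effects == 0).all() and model.mu == 3.0

    def test_training_row_prediction_equals_fit(self, rng):
        X = pd.DataFrame(rng.integers(0, 3, (30, 80)).astype(float))
        y = pd.Series(rng.normal(0, 1, 30))
        model = rrblup_fit(X, y)
        p1 = predict(model, X)
        p2 = predict(model, X.iloc[[4]])
        assert p2.iloc[0] == pytest.approx(p1.iloc[4])

    def test_projected_half_dosages_accepted(self, rng):
        X = pd.DataFrame(rng.choice([0.0, 0.5, 1.0, 1.5, 2.0], size=(12, 30)))
        y = pd.Series(rng.normal(0, 1, 12))
        assert np.isfinite(predict(rrblup_fit(X, y), X)).all()

    def test_marker_mismatch_raises(self, rng):
        X = pd.DataFrame(rng.integers(0, 3, (6, 4)).astype(float),
                         columns=list("wxyz"))
        model = rrblup_fit(X, pd.Series(rng.normal(0, 1, 6)))
        with pytest.raises(AlignmentError):
            predict(model, X[["w", "x"]])

    def test_reml_recovers_signal_ratio_order(self, rng):
        # strong-signal trait gets smaller lambda than pure-noise trait
        X = pd.DataFrame(rng.integers(0, 3, (120, 60)).astype(float))
        beta = rng.normal(0, 1, 60)
        y_sig = pd.Series(X.to_numpy() @ beta + rng.normal(0, 1, 120))
        y_noise = pd.Series(rng.normal(0, 1, 120))
        assert rrblup_fit(X, y_sig).lambda_ < rrblup_fit(X, y_noise).lambda_


class TestSchemeMachinery:
    def test_config_validation(self):
        with pytest.raises(ParameterError):
            SchemeConfig(schemes=("M9",))
        with pytest.raises(ParameterError):
            SchemeConfig(n_folds=1)

    def test_default_marker_ladder(self):
        assert default_marker_counts(300) == [64, 128, 256, "all"]

    def test_reproducible_under_fixed_seed(self, small_study):
        cfg = SchemeConfig(schemes=("M2", "M3B"), n_repetitions=2,
                           marker_counts=(64, "all"), seed=33)
        a = run_scheme(cfg, small_study.parents, small_study.hybrids,
                       small_study.inbred_values, small_study.hybrid_values)
        b = run_scheme(cfg, small_study.parents, small_study.hybrids,
                       small_study.inbred_values, small_study.hybrid_values)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_marker_count_exceeding_panel_rejected(self, small_study):
        cfg = SchemeConfig(schemes=("M2",), n_repetitions=1, marker_counts=(4096,))
        with pytest.raises(ParameterError):
            run_scheme(cfg, None, small_study.hybrids, None,
                       small_study.hybrid_values)

    def test_m1_requires_inbreds(self, small_study):
        cfg = SchemeConfig(schemes=("M1",), n_repetitions=1)
        with pytest.raises(ModelError):
            run_scheme(cfg, None, small_study.hybrids, None,
                       small_study.hybrid_values)

    def test_accuracy_counts_and_range(self, small_study):
        cfg = SchemeConfig(n_repetitions=3, marker_counts=("all",), seed=1)
        cv = run_scheme(cfg, small_study.parents, small_study.hybrids,
                        small_study.inbred_values, small_study.hybrid_values)
        acc = cv.accuracies()
        assert len(acc) == 4 * 3  # schemes x repetitions
        assert acc["accuracy"].between(-1, 1).all()

    def test_additive_trait_m2_and_m3a_equivalent(self):
        """Without dominance or pool shifts, adding inbred data never hurts:
        M2 and M3A track each other closely (the low-heterosis regime)."""
        # inbreds kept a small fraction of the training pool, as in a hybrid
        # programme where most records come from hybrid trials
        study = simulate_prediction_study(
            n_b=12, n_r=12, n_hybrids=130, n_markers=400, dominance_ratio=0.0,
            h2=0.8, seed=21,
        )
        acc = scheme_accuracies(study, schemes=("M2", "M3A"), n_repetitions=8, seed=21)
        assert abs(acc["M3A"].mean() - acc["M2"].mean()) < 0.05

    def test_more_markers_help_until_plateau(self):
        study = simulate_prediction_study(
            n_hybrids=200, n_markers=1024, n_qtl=60, dominance_ratio=0.0,
            h2=0.8, seed=31,
        )
        cfg = SchemeConfig(schemes=("M2",), n_repetitions=6,
                           marker_counts=(64, 256, 1024), seed=31)
        cv = run_scheme(cfg, None, study.hybrids, None, study.hybrid_values)
        means = cv.summary().set_index("marker_count")["mean"]
        assert means[64] < means[1024]
        # even 64 random markers carry real signal on a linked architecture
        assert means[64] > 0.2


class TestHoldoutParent:
    def test_training_pool_structurally_disjoint(self, small_study):
        plan = small_study.plan
        b = plan.table["female_id"].iloc[0]
        r = plan.table["male_id"].iloc[0]
        held = plan.offspring_of(b).union(plan.offspring_of(r))
        cfg = SchemeConfig(schemes=("M2",), n_repetitions=1, seed=3)
        cv = holdout_parent_cv(cfg, small_study.hybrids, small_study.hybrid_values,
                               plan, b, r)
        assert np.isfinite(cv.table["r"]).all()
        assert held.intersection(small_study.hybrids.entry_ids).size > 0

    def test_unknown_parent_raises(self, small_study):
        cfg = SchemeConfig(schemes=("M2",), n_repetitions=1)
        with pytest.raises(ModelError):
            holdout_parent_cv(cfg, small_study.hybrids, small_study.hybrid_values,
                              small_study.plan, "ghost", "ghoul")

    def test_holding_out_all_parents_empties_training(self):
        study = simulate_prediction_study(n_b=1, n_r=1, n_hybrids=1,
                                          n_markers=50, n_qtl=20, seed=4)
        cfg = SchemeConfig(schemes=("M2",), n_repetitions=1)
        with pytest.raises(ModelError, match="empty"):
            holdout_parent_cv(cfg, study.hybrids, study.hybrid_values,
                              study.plan, "B001", "R001")


class TestExhaustivePrediction:
    def test_toy_plan_hand_check(self, rng):
        study = simulate_prediction_study(n_b=3, n_r=3, n_hybrids=9,
                                          n_markers=60, n_qtl=20, seed=9)
        model = rrblup_fit(study.hybrids, study.hybrid_values)
        gebv = predict_all_hybrids({"y": model}, study.full_plan, study.parents,
                                   chunk_size=4)
        assert len(gebv) == 9
        # tested hybrids' GEBVs equal their fitted values
        fitted = predict(model, study.hybrids)
        np.testing.assert_allclose(gebv.loc[fitted.index, "y"], fitted, atol=1e-10)


class TestParetoFrontier:
    def test_single_point_is_its_own_frontier(self):
        tab = pd.DataFrame({"yield": [1.0], "flower": [2.0]}, index=["h"])
        assert list(pareto_frontier(tab, "yield", "flower").index) == ["h"]

    def test_dominated_point_removed(self):
        tab = pd.DataFrame({"yield": [5.0, 4.0], "flower": [2.0, 3.0]},
                           index=["good", "bad"])
        assert list(pareto_frontier(tab, "yield", "flower").index) == ["good"]

    def test_matches_brute_force_on_random_points(self, rng):
        tab = pd.DataFrame(
            {"yield": rng.normal(0, 1, 20), "flower": rng.normal(0, 1, 20)},
            index=[f"h{i}" for i in range(20)],
        )
        frontier = set(pareto_frontier(tab, "yield", "flower").index)
        brute = set()
        for i in tab.index:
            yi, fi = tab.loc[i, "yield"], tab.loc[i, "flower"]
            dominated = any(
                (tab.loc[j, "yield"] >= yi and tab.loc[j, "flower"] <= fi
                 and (tab.loc[j, "yield"] > yi or tab.loc[j, "flower"] < fi))
                for j in tab.index if j != i
            )
            if not dominated:
                brute.add(i)
        assert frontier == brute

    def test_sorted_by_minimised_trait(self, rng):
        tab = pd.DataFrame(
            {"yield": rng.normal(0, 1, 50), "flower": rng.normal(0, 1, 50)},
            index=[f"h{i}" for i in range(50)],
        )
        fr = pareto_frontier(tab, "yield", "flower")
        assert fr["flower"].is_monotonic_increasing
        assert fr["yield"].is_monotonic_increasing  # frontier trade-off shape


class TestCompareSchemes:
    @staticmethod
    def _cv_from(acc_by_scheme: dict):
        rows = []
        for scheme, accs in acc_by_scheme.items():
            for rep, a in enumerate(accs):
                rows.append({"scheme": scheme, "trait": "y", "marker_count": "all",
                             "repetition": rep, "fold": 0, "r": a})
        from milletgs.genomic_prediction import CVResult
        return CVResult(pd.DataFrame(rows))

    def test_identical_results_give_p_one(self):
        accs = list(np.linspace(0.4, 0.6, 20))
        out = compare_schemes(self._cv_from({"M2": accs, "M3B": accs}))
        assert out["difference"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == 1.0

    def test_constant_shift_detected(self):
        base = list(np.linspace(0.4, 0.6, 20))
        shifted = [a + 0.05 for a in base]
        out = compare_schemes(self._cv_from({"M2": base, "M3B": shifted}))
        assert out["difference"].iloc[0] == pytest.approx(0.05)
        assert out["p_value"].iloc[0] < 0.05

    def test_single_repetition_gives_nan(self):
        out = compare_schemes(self._cv_from({"M2": [0.5], "M3B": [0.6]}))
        assert np.isnan(out["p_value"].iloc[0])
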