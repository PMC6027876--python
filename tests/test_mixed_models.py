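"""REML variance components, heritability, heterosis and population centring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milletgs.containers import CrossPlan
from milletgs.errors import ModelError
from milletgs.mixed_models import (
    HeritabilityInput,
    TraitBLUPs,
    VarianceComponents,
    center_by_population,
    fit_random_model,
    heritability,
    heterosis_median,
    midparent_heterosis,
)
from milletgs.reml import RandomTerm, reml_fit, reml_loglik_direct
from milletgs.synthetic_data import TraitArchitecture, simulate_field_book


def _noise_arch(**kw):
    base = dict(qtl_indices=[0], additive_effects=[0.0], dominance_effects=[0.0])
    return TraitArchitecture(**base, **kw)


class TestREMLEngine:
    def test_mme_loglik_matches_direct_dense_formula(self):
        rng = np.random.default_rng(0)
        g = np.repeat(np.arange(6), 6)
        l = np.tile(np.repeat(np.arange(3), 2), 6)
        gl = g * 3 + l
        y = (rng.normal(0, 1, 36) + rng.normal(0, 1.5, 6)[g]
             + rng.normal(0, 0.8, 3)[l] + rng.normal(0, 0.6, 18)[gl])
        terms = [RandomTerm("g", g, np.arange(6)),
                 RandomTerm("l", l, np.arange(3)),
                 RandomTerm("gl", gl, np.arange(18))]
        res = reml_fit(y, terms)
        assert res.converged
        assert res.loglik == pytest.approx(
            reml_loglik_direct(y, terms, res.sigma2), abs=1e-9
        )

    def test_balanced_design_matches_anova_estimators(self):
        """On balanced data REML coincides with the method-of-moments
        (expected-mean-squares) solution when all estimates are interior."""
        rng = np.random.default_rng(314)
        G, L, R = 8, 4, 3
        g = np.repeat(np.arange(G), L * R)
        l = np.tile(np.repeat(np.arange(L), R), G)
        gl = g * L + l
        y = (rng.normal(0, 2.0, G)[g] + rng.normal(0, 1.5, L)[l]
             + rng.normal(0, 1.0, G * L)[gl] + rng.normal(0, 1.0, G * L * R) + 10.0)
        df = pd.DataFrame({"g": g, "l": l, "gl": gl, "y": y})
        grand = y.mean()
        mg = df.groupby("g")["y"].mean()
        ml = df.groupby("l")["y"].mean()
        mgl = df.groupby("gl")["y"].mean()
        ssg = L * R * ((mg - grand) ** 2).sum()
        ssl = G * R * ((ml - grand) ** 2).sum()
        ssgl = R * ((mgl - grand) ** 2).sum() - ssg - ssl
        sse = ((y - mgl[gl].to_numpy()) ** 2).sum()
        msg, msl = ssg / (G - 1), ssl / (L - 1)
        msgl = ssgl / ((G - 1) * (L - 1))
        mse = sse / (G * L * (R - 1))
        anova = {
            "g": (msg - msgl) / (L * R),
            "l": (msl - msgl) / (G * R),
            "gl": (msgl - mse) / R,
            "residual": mse,
        }
        terms = [RandomTerm("g", g, np.arange(G)),
                 RandomTerm("l", l, np.arange(L)),
                 RandomTerm("gl", gl, np.arange(G * L))]
        res = reml_fit(y, terms, tol=1e-12, max_iter=500)
        for k, v in anova.items():
            assert res.sigma2[k] == pytest.approx(v, abs=1e-6)

    def test_constant_response_rejected(self):
        terms = [RandomTerm("g", np.array([0, 0, 1, 1]), np.arange(2))]
        with pytest.raises(ModelError):
            reml_fit(np.ones(4), terms)


class TestFitRandomModel:
    @staticmethod
    def _book(seed=77):
        rng = np.random.default_rng(2024)
        entries = [f"E{i:02d}" for i in range(24)] + ["C1", "C2"]
        tv = pd.Series(rng.normal(20.0, 1.5, 26), index=entries, name="y")
        arch = _noise_arch(loc_sd=0.8, gxe_sd=0.6, rep_sd=0.4, block_sd=0.3,
                           resid_sd=0.9)
        return simulate_field_book(tv, 3, 2, 5, arch, ["C1", "C2"], seed=seed)

    def test_matches_lme4_reference_fit(self):
        """Components, intercept, logLik and BLUPs frozen from an independent
        R lme4 fit (bobyqa, REML) of the identical seeded field book."""
        vc, blups, res = fit_random_model(self._book(), "y")
        assert vc.v_g == pytest.approx(2.403260906, rel=1e-5)
        assert vc.v_l == pytest.approx(2.690449192, rel=1e-5)
        assert vc.v_gxl == pytest.approx(0.230744104, rel=1e-4)
        assert vc.v_rep == pytest.approx(0.024277274, rel=1e-3)
        assert vc.v_block == pytest.approx(0.032517154, rel=1e-3)
        assert vc.v_resid == pytest.approx(0.900533131, rel=1e-5)
        assert res.mu == pytest.approx(20.81733, abs=1e-4)
        assert res.loglik == pytest.approx(-389.0691, abs=1e-3)
        assert blups.values["C1"] == pytest.approx(-0.7589914, abs=1e-5)
        assert blups.values["C2"] == pytest.approx(-0.3137214, abs=1e-5)
        assert blups.values["E00"] == pytest.approx(0.7088886, abs=1e-5)

    def test_blups_center_near_zero_and_shrink_with_noise(self):
        rng = np.random.default_rng(5)
        entries = [f"E{i:03d}" for i in range(102)] + ["C1", "C2"]
        tv = pd.Series(rng.normal(0.0, 1.0, 104), index=entries, name="y")
        quiet = simulate_field_book(tv, 3, 2, 5, _noise_arch(resid_sd=0.2),
                                    ["C1", "C2"], seed=1)
        _, bq, _ = fit_random_model(quiet, "y")
        assert abs(bq.values.sum()) < 1e-6
        # shrinkage: BLUP spread collapses as residual noise dominates
        # (mean over field-noise seeds to damp variance-estimate sampling)
        ratios = []
        for seed in (1, 2, 3):
            noisy = simulate_field_book(tv, 3, 2, 5, _noise_arch(resid_sd=6.0),
                                        ["C1", "C2"], seed=seed)
            _, bn, _ = fit_random_model(noisy, "y")
            ratios.append(bn.values.var() / bq.values.var())
        assert np.mean(ratios) < 0.5

    def test_null_heritability_limit(self):
        rng = np.random.default_rng(8)
        entries = [f"E{i:02d}" for i in range(24)] + ["C1", "C2"]
        tv = pd.Series(np.zeros(26), index=entries, name="y")
        book = simulate_field_book(tv, 3, 2, 5, _noise_arch(resid_sd=1.0),
                                   ["C1", "C2"], seed=2)
        vc, blups, _ = fit_random_model(book, "y")
        h2 = heritability(vc, HeritabilityInput(3, 2))
        assert h2 < 0.15
        assert blups.values.abs().max() < 0.5

    def test_single_location_is_degenerate(self):
        book = self._book()
        with pytest.raises(ModelError, match="location"):
            fit_random_model(book[book["location"] == "loc1"], "y")

    def test_unreplicated_design_is_degenerate(self):
        book = self._book().drop_duplicates("entry_id")
        with pytest.raises(ModelError):
            fit_random_model(book, "y")


class TestHeritability:
    @pytest.mark.parametrize(
        "vg, vgxl, ve, nl, nr, expected",
        [
            (1.0, 0.0, 0.0, 4, 2, 1.0),
            (0.0, 1.0, 0.0, 4, 2, 0.0),
            (1.0, 4.0, 8.0, 4, 2, 1.0 / 3.0),
        ],
    )
    def test_formula_arithmetic(self, vg, vgxl, ve, nl, nr, expected):
        vc = VarianceComponents(vg, 9.0, vgxl, 9.0, 9.0, ve)
        assert heritability(vc, HeritabilityInput(nl, nr)) == pytest.approx(expected)

    def test_location_rep_block_variance_do_not_enter(self):
        a = VarianceComponents(1.0, 0.0, 2.0, 0.0, 0.0, 3.0)
        b = VarianceComponents(1.0, 99.0, 2.0, 42.0, 7.0, 3.0)
        d = HeritabilityInput(4, 2)
        assert heritability(a, d) == heritability(b, d)

    def test_degenerate_zero_components_give_nan(self):
        vc = VarianceComponents(0.0, 1.0, 0.0, 1.0, 1.0, 0.0)
        assert np.isnan(heritability(vc, HeritabilityInput(4, 2)))

    @settings(derandomize=True, max_examples=200)
    @given(
        vg=st.floats(0.0, 50.0), vgxl=st.floats(0.0, 50.0), ve=st.floats(0.0, 50.0),
        nl=st.integers(1, 10), nr=st.integers(1, 10),
    )
    def test_bounded_in_unit_interval(self, vg, vgxl, ve, nl, nr):
        vc = VarianceComponents(vg, 0.0, vgxl, 0.0, 0.0, ve)
        h2 = heritability(vc, HeritabilityInput(nl, nr))
        if not np.isnan(h2):
            assert 0.0 <= h2 <= 1.0

    def test_monotone_in_components(self):
        d = HeritabilityInput(4, 2)
        grid = np.linspace(0.1, 5.0, 8)
        base = VarianceComponents(1.0, 0.0, 1.0, 0.0, 0.0, 1.0)
        h_vg = [heritability(VarianceComponents(v, 0, 1, 0, 0, 1), d) for v in grid]
        h_gxl = [heritability(VarianceComponents(1, 0, v, 0, 0, 1), d) for v in grid]
        h_ve = [heritability(VarianceComponents(1, 0, 1, 0, 0, v), d) for v in grid]
        assert np.all(np.diff(h_vg) > 0)
        assert np.all(np.diff(h_gxl) < 0)
        assert np.all(np.diff(h_ve) < 0)


class TestHeterosis:
    @staticmethod
    def _blups(values: dict, populations: dict, mean=0.0):
        v = pd.Series(values, dtype=float)
        p = pd.Series(populations)
        return TraitBLUPs("y", v, p, grand_mean=mean)

    def test_simple_ratio(self):
        bl = self._blups({"h": 1.5, "f": 1.0, "m": 1.0},
                         {"h": "hybrid", "f": "inbred", "m": "inbred"})
        plan = CrossPlan(pd.DataFrame([["h", "f", "m"]],
                                      columns=["hybrid_id", "female_id", "male_id"]))
        het = midparent_heterosis(bl, plan)
        assert het["heterosis"].iloc[0] == pytest.approx(0.5)

    def test_hybrid_equal_to_midparent_is_zero(self):
        bl = self._blups({"h": 2.0, "f": 1.0, "m": 3.0},
                         {"h": "hybrid", "f": "inbred", "m": "inbred"})
        plan = CrossPlan(pd.DataFrame([["h", "f", "m"]],
                                      columns=["hybrid_id", "female_id", "male_id"]))
        assert midparent_heterosis(bl, plan)["heterosis"].iloc[0] == pytest.approx(0.0)

    def test_five_hybrid_fixture_median_matches_hand_computation(self):
        parents = {f"f{i}": 10.0 + i for i in range(5)}
        parents.update({f"m{i}": 12.0 + i for i in range(5)})
        hybrids = {f"h{i}": 14.0 + 2 * i for i in range(5)}
        values = {**parents, **hybrids}
        pops = {k: ("hybrid" if k.startswith("h") else "inbred") for k in values}
        plan = CrossPlan(pd.DataFrame(
            [[f"h{i}", f"f{i}", f"m{i}"] for i in range(5)],
            columns=["hybrid_id", "female_id", "male_id"],
        ))
        het = midparent_heterosis(self._blups(values, pops), plan)
        # hand computation: mid-parent_i = 11+i, hybrid_i = 14+2i
        expected = [(14 + 2 * i - (11 + i)) / (11 + i) for i in range(5)]
        np.testing.assert_allclose(het["heterosis"], expected)
        assert heterosis_median(het) == pytest.approx(np.median(expected))

    def test_nonpositive_midparent_flagged_and_excluded(self):
        values = {"h1": 1.0, "h2": 5.0, "f1": -2.0, "m1": 2.0, "f2": 4.0, "m2": 4.0}
        pops = {k: ("hybrid" if k.startswith("h") else "inbred") for k in values}
        plan = CrossPlan(pd.DataFrame(
            [["h1", "f1", "m1"], ["h2", "f2", "m2"]],
            columns=["hybrid_id", "female_id", "male_id"],
        ))
        het = midparent_heterosis(self._blups(values, pops), plan)
        assert list(het["valid"]) == [False, True]
        assert heterosis_median(het) == pytest.approx(0.25)

    def test_blup_and_restored_modes_agree_in_sign(self, small_study):
        """On simulated data with positive dominance both evaluation scales
        place the bulk of hybrids above their mid-parent."""
        st_ = small_study
        vals = pd.concat([st_.inbred_values, st_.hybrid_values])
        pops = pd.Series(
            ["inbred"] * len(st_.inbred_values) + ["hybrid"] * len(st_.hybrid_values),
            index=vals.index,
        )
        bl = TraitBLUPs("y", vals - vals.mean(), pops, grand_mean=float(vals.mean()))
        restored = midparent_heterosis(bl, st_.plan, mode="mean_restored")
        raw = midparent_heterosis(bl, st_.plan, mode="blup")
        assert heterosis_median(restored) > 0
        # sign of the numerator is scale-free: compare hybrid minus mid-parent
        num_restored = restored["heterosis"] * restored["mid_parent"]
        num_raw = raw["heterosis"] * raw["mid_parent"]
        np.testing.assert_allclose(num_restored, num_raw, atol=1e-9)


class TestCenterByPopulation:
    def test_tabulated_example(self):
        bl = TraitBLUPs(
            "y",
            pd.Series({"i1": 1.0, "i2": 3.0, "h1": 10.0, "h2": 14.0}),
            pd.Series({"i1": "inbred", "i2": "inbred", "h1": "hybrid", "h2": "hybrid"}),
            grand_mean=0.0,
        )
        out = center_by_population(bl)
        assert out.values.to_dict() == {"i1": -1.0, "i2": 1.0, "h1": -2.0, "h2": 2.0}
        assert abs(out.population_means(restored=False)).max() < 1e-10

    def test_already_centered_unchanged(self):
        bl = TraitBLUPs(
            "y",
            pd.Series({"i1": -1.0, "i2": 1.0, "h1": -2.0, "h2": 2.0}),
            pd.Series({"i1": "inbred", "i2": "inbred", "h1": "hybrid", "h2": "hybrid"}),
            grand_mean=0.0,
        )
        out = center_by_population(bl)
        pd.testing.assert_series_equal(out.values, bl.values)

    def test_single_entry_population_maps_to_zero(self):
        bl = TraitBLUPs(
            "y",
            pd.Series({"i1": 7.0, "h1": 1.0, "h2": 3.0}),
            pd.Series({"i1": "inbred", "h1": "hybrid", "h2": "hybrid"}),
            grand_mean=2.0,
        )
        out = center_by_population(bl)
        assert out.values["i1"] == 0.0
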