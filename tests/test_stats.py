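"""Regression layer: linear/weighted fits, LMM, cloglog GLMM, partial
predictions and completeness sensitivity."""

import numpy as np
import pandas as pd
import pytest

import phylonat as pn
from phylonat._lme4 import lme4_available
from phylonat.stats import fit_lmm_climate

HAVE_LME4 = lme4_available()


class TestWeightedLinear:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = pn.fit_weighted_linear(2 * x + 1, {"x": x})
        assert fit.coef.loc["x", "estimate"] == pytest.approx(2.0)
        assert fit.coef.loc["Intercept", "estimate"] == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_duplicate_equals_weight_two(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        # duplicate the first observation
        xd = np.concatenate([[x[0]], x])
        yd = np.concatenate([[y[0]], y])
        w = np.ones(30)
        w[0] = 2.0
        dup = pn.fit_weighted_linear(yd, {"x": xd})
        wtd = pn.fit_weighted_linear(y, {"x": x}, weights=w)
        np.testing.assert_allclose(
            dup.coef["estimate"], wtd.coef["estimate"], rtol=1e-10
        )

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = -x + rng.normal(size=40)
        w = rng.uniform(0.5, 2.0, 40)
        a = pn.fit_weighted_linear(y, {"x": x}, weights=w)
        b = pn.fit_weighted_linear(y, {"x": x}, weights=17.0 * w)
        np.testing.assert_allclose(
            a.coef["estimate"], b.coef["estimate"], rtol=1e-10
        )
        np.testing.assert_allclose(a.coef["se"], b.coef["se"], rtol=1e-8)

    def test_rank_deficiency_names_alias(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="aliased"):
            pn.fit_weighted_linear(x, {"a": x, "b": 2 * x})

    def test_slope_recovery_coverage(self):
        """Fitted slope lands within 2 SE of the generating slope at
        roughly nominal coverage."""
        rng = np.random.default_rng(7)
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            lat = rng.uniform(0, 60, 50)
            y = 0.5 - 0.02 * lat + rng.normal(0, 0.3, 50)
            fit = pn.fit_weighted_linear(y, {"lat": lat})
            est = fit.coef.loc["lat", "estimate"]
            se = fit.coef.loc["lat", "se"]
            if abs(est - (-0.02)) < 2 * se:
                hits += 1
        assert hits >= int(0.90 * n_runs)


class TestInteractionModel:
    def test_centering_leaves_interaction_unchanged(self):
        rng = np.random.default_rng(2)
        lat = rng.uniform(0, 60, 80)
        hm = rng.uniform(0, 1, 80)
        y = 1 + 0.02 * lat - 0.5 * hm - 0.03 * lat * hm + rng.normal(
            0, 0.1, 80
        )
        raw = pn.fit_interaction_model(y, lat, hm)
        cen = pn.fit_interaction_model(y, lat - lat.mean(),
                                       hm - hm.mean())
        assert raw.coef.loc["latitude:hm", "estimate"] == pytest.approx(
            cen.coef.loc["latitude:hm", "estimate"], rel=1e-8
        )
        assert raw.coef.loc["latitude", "estimate"] != pytest.approx(
            cen.coef.loc["latitude", "estimate"], rel=1e-3
        )

    def test_interaction_sign_calibration(self):
        rng = np.random.default_rng(3)
        zero_hits = neg_hits = 0
        n_runs = 150
        for _ in range(n_runs):
            lat = rng.uniform(0, 60, 60)
            hm = rng.uniform(0, 1, 60)
            y0 = 0.5 - 0.01 * lat + 0.2 * hm + rng.normal(0, 0.2, 60)
            fit0 = pn.fit_interaction_model(y0, lat, hm)
            est = fit0.coef.loc["latitude:hm", "estimate"]
            se = fit0.coef.loc["latitude:hm", "se"]
            if abs(est) < 2 * se:
                zero_hits += 1
            y1 = y0 - 0.04 * lat * hm
            fit1 = pn.fit_interaction_model(y1, lat, hm)
            if fit1.coef.loc["latitude:hm", "estimate"] < 0:
                neg_hits += 1
        assert zero_hits >= int(0.88 * n_runs)
        assert neg_hits >= int(0.95 * n_runs)


class TestClimateLmm:
    def _data(self, n=160, tau=0.5, seed=0, n_groups=4):
        rng = np.random.default_rng(seed)
        pc_t = rng.normal(size=n)
        pc_p = rng.normal(size=n)
        hm = rng.uniform(0, 1, n)
        groups = np.array(
            [f"C{i % n_groups}" for i in range(n)]
        )
        u = {g: rng.normal(0, tau) for g in np.unique(groups)}
        y = (
            0.3 * pc_t + 0.2 * pc_p - 0.4 * hm + 0.25 * pc_t * hm
            + np.array([u[g] for g in groups])
            + rng.normal(0, 0.3, n)
        )
        return y, pc_t, pc_p, hm, groups

    def test_single_group_reduces_to_wls(self):
        y, pc_t, pc_p, hm, _ = self._data()
        groups = np.repeat("C0", len(y))
        lmm = fit_lmm_climate(y, pc_t, pc_p, hm, groups,
                              standardize=False)
        assert lmm.method == "wls"
        assert any("single group" in n for n in lmm.notes)
        wls = pn.fit_weighted_linear(
            y, {"pc_temp": pc_t, "pc_prec": pc_p, "hm": hm}
        )
        assert lmm.coef.loc["pc_temp", "estimate"] == pytest.approx(
            lmm.coef.loc["pc_temp", "estimate"]
        )
        assert wls.converged

    def test_zero_group_variance_estimated_near_zero(self):
        y, pc_t, pc_p, hm, groups = self._data(n=400, tau=0.0, seed=4,
                                               n_groups=8)
        fit = fit_lmm_climate(y, pc_t, pc_p, hm, groups,
                              standardize=False)
        if fit.method == "lmm":
            total = np.var(y)
            assert fit.re_var["continent_intercept_var"] < 0.1 * total

    def test_fixed_effects_recovered(self):
        hits = total = 0
        for seed in range(25):
            y, pc_t, pc_p, hm, groups = self._data(seed=seed, tau=0.3)
            fit = fit_lmm_climate(y, pc_t, pc_p, hm, groups,
                                  standardize=False)
            est = fit.coef.loc["pc_temp", "estimate"]
            se = fit.coef.loc["pc_temp", "se"]
            total += 1
            if abs(est - 0.3) < 2.5 * se:
                hits += 1
        assert hits >= int(0.85 * total)

    def test_weighted_lmm_weight_rescaling_invariance(self):
        y, pc_t, pc_p, hm, groups = self._data(seed=9)
        w = np.random.default_rng(9).uniform(0.5, 2.0, len(y))
        a = fit_lmm_climate(y, pc_t, pc_p, hm, groups, weights=w,
                            standardize=False)
        b = fit_lmm_climate(y, pc_t, pc_p, hm, groups, weights=3.0 * w,
                            standardize=False)
        np.testing.assert_allclose(
            a.coef["estimate"], b.coef["estimate"], rtol=1e-5
        )

    def test_standardized_effects_present(self):
        y, pc_t, pc_p, hm, groups = self._data(seed=5)
        fit = fit_lmm_climate(y, pc_t, pc_p, hm, groups)
        assert "std_estimate" in fit.coef.columns
        assert np.isfinite(fit.coef["std_estimate"]).all()


def _glmm_table(n_species=40, n_regions=20, sd_species=0.0,
                sd_region=0.0, beta_int=-0.5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    u = rng.normal(0, sd_species, n_species)
    v = rng.normal(0, sd_region, n_regions)
    lat = rng.uniform(0, 60, n_regions)
    for i in range(n_species):
        mpd = rng.normal(10, 2, n_regions)
        zm = (mpd - 10) / 2
        zl = (lat - 30) / 17.3
        eta = -2.0 + 0.2 * zm + beta_int * zm * zl + u[i] + v
        p = 1 - np.exp(-np.exp(eta))
        y = (rng.random(n_regions) < p).astype(int)
        for j in range(n_regions):
            rows.append(
                {
                    "species": f"S{i}",
                    "region_id": f"R{j}",
                    "mpd_to_natives": mpd[j],
                    "abs_latitude": lat[j],
                    "naturalized": y[j],
                }
            )
    return pd.DataFrame(rows)


class TestGlmmNaturalization:
    def test_all_one_class_raises(self):
        tab = _glmm_table()
        tab["naturalized"] = 0
        with pytest.raises(ValueError, match="both outcome classes"):
            pn.fit_glmm_naturalization(tab)

    def test_glm_backend_recovers_interaction_sign(self):
        tab = _glmm_table(seed=1)
        fit = pn.fit_glmm_naturalization(tab, backend="glm")
        assert fit.method == "glm-cloglog"
        assert fit.coef.loc["mpd:abs_latitude", "estimate"] < 0
        assert fit.coef.loc["mpd:abs_latitude", "pvalue"] < 0.05

    @pytest.mark.skipif(not HAVE_LME4, reason="R lme4 not runnable")
    def test_zero_variance_glmm_matches_plain_glm(self):
        """With no true random-effect variance the mixed model's fixed
        effects agree with a plain cloglog regression."""
        tab = _glmm_table(seed=2, sd_species=0.0, sd_region=0.0)
        glm = pn.fit_glmm_naturalization(tab, backend="glm")
        glmm = pn.fit_glmm_naturalization(
            tab, random_structure="intercepts_only", backend="lme4"
        )
        assert glmm.method.startswith("glmm-cloglog-lme4")
        for term in ("mpd", "abs_latitude", "mpd:abs_latitude"):
            diff = abs(
                glmm.coef.loc[term, "estimate"]
                - glm.coef.loc[term, "estimate"]
            )
            assert diff < 2 * glm.coef.loc[term, "se"]

    @pytest.mark.skipif(not HAVE_LME4, reason="R lme4 not runnable")
    def test_full_structure_fits_or_falls_back(self):
        tab = _glmm_table(seed=3, sd_species=0.4, sd_region=0.3)
        fit = pn.fit_glmm_naturalization(tab, random_structure="full")
        assert fit.method.startswith("glmm-cloglog-lme4")
        assert fit.coef.loc["mpd:abs_latitude", "estimate"] < 0
        assert fit.re_var is not None

    def test_predictions_are_probabilities(self):
        tab = _glmm_table(seed=4)
        fit = pn.fit_glmm_naturalization(tab, backend="glm")
        p = fit.predict(tab.head(50))
        assert np.all((p > 0) & (p < 1))


class TestPartialPredictions:
    def test_irrelevant_fix_gives_identical_curves(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        z = rng.normal(size=60)
        fit = pn.fit_weighted_linear(2 * x, {"x": x, "z": z})
        c10 = pn.partial_predictions(fit, "x", fix={"z": 0.1})
        c90 = pn.partial_predictions(fit, "x", fix={"z": 0.9})
        np.testing.assert_allclose(
            c10["prediction"], c90["prediction"], atol=1e-8
        )

    def test_interaction_slope_gap_identity(self):
        rng = np.random.default_rng(1)
        lat = rng.uniform(0, 60, 100)
        hm = rng.uniform(0, 1, 100)
        y = 1 - 0.01 * lat + 0.3 * hm - 0.02 * lat * hm + rng.normal(
            0, 0.05, 100
        )
        fit = pn.fit_interaction_model(y, lat, hm)
        q10 = pn.partial_predictions(fit, "latitude", fix={"hm": 0.1},
                                     grid=2)
        q90 = pn.partial_predictions(fit, "latitude", fix={"hm": 0.9},
                                     grid=2)

        def slope(cur):
            return (
                (cur["prediction"].iloc[1] - cur["prediction"].iloc[0])
                / (cur["latitude"].iloc[1] - cur["latitude"].iloc[0])
            )

        gap = slope(q90) - slope(q10)
        expected = (
            np.quantile(hm, 0.9) - np.quantile(hm, 0.1)
        ) * fit.coef.loc["latitude:hm", "estimate"]
        assert gap == pytest.approx(expected, rel=1e-6)

    def test_mean_fix_matches_fitted_values(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        y = 1 + x - z + rng.normal(0, 0.1, 50)
        fit = pn.fit_weighted_linear(y, {"x": x, "z": z})
        cur = pn.partial_predictions(fit, "x", grid=3)
        manual = (
            fit.coef.loc["Intercept", "estimate"]
            + fit.coef.loc["x", "estimate"] * cur["x"]
            + fit.coef.loc["z", "estimate"] * z.mean()
        )
        np.testing.assert_allclose(cur["prediction"], manual, rtol=1e-10)

    def test_unknown_predictor_raises(self):
        x = np.arange(10.0)
        fit = pn.fit_weighted_linear(x, {"x": x})
        with pytest.raises(KeyError):
            pn.partial_predictions(fit, "zzz")


class TestCompletenessRefit:
    def test_full_completeness_equals_unweighted(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(0, 0.1, 40)
        sub, wtd = pn.completeness_weighted_refit(
            y, {"x": x}, np.ones(40)
        )
        base = pn.fit_weighted_linear(y, {"x": x})
        for fit in (sub, wtd):
            np.testing.assert_allclose(
                fit.coef["estimate"], base.coef["estimate"], rtol=1e-10
            )

    def test_subset_equals_indicator_weights(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = -x + rng.normal(0, 0.2, 50)
        comp = rng.uniform(0, 1, 50)
        sub, _ = pn.completeness_weighted_refit(
            y, {"x": x}, comp, min_completeness=0.5
        )
        keep = comp > 0.5
        manual = pn.fit_weighted_linear(y[keep], {"x": x[keep]})
        np.testing.assert_allclose(
            sub.coef["estimate"], manual.coef["estimate"], rtol=1e-10
        )

    def test_downweighting_outlier_recovers_clean_slope(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 30)
        y = 2 * x + rng.normal(0, 0.05, 30)
        y[-1] += 5.0  # planted outlier in a low-completeness region
        comp = np.ones(30)
        comp[-1] = 0.05
        naive = pn.fit_weighted_linear(y, {"x": x})
        _, wtd = pn.completeness_weighted_refit(y, {"x": x}, comp)
        clean = pn.fit_weighted_linear(y[:-1], {"x": x[:-1]})
        target = clean.coef.loc["x", "estimate"]
        assert abs(wtd.coef.loc["x", "estimate"] - target) < abs(
            naive.coef.loc["x", "estimate"] - target
        )

    def test_invalid_completeness_raises(self):
        with pytest.raises(ValueError):
            pn.completeness_weighted_refit(
                [1.0, 2.0], {"x": [0.0, 1.0]}, [0.5, 1.2]
            )
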