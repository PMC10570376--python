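"""Climate transforms, PCA, AUC/threshold oracles and envelope models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import phylonat as pn
from phylonat.climate import (
    SDM_VARS,
    TransformSpec,
    fit_envelope_model,
    region_scores_frame,
)


class TestTransforms:
    def test_identity(self):
        x = np.array([3.0, -1.0, 2.5])
        spec = TransformSpec("identity")
        np.testing.assert_array_equal(
            pn.transform_variable(x, spec), x
        )

    def test_log1p_shift_known_values(self):
        x = np.array([0.0, np.e - 1.0])
        spec = TransformSpec("log1p_shift", {"shift": 0.0})
        np.testing.assert_allclose(
            pn.transform_variable(x, spec), [0.0, 1.0], atol=1e-12
        )

    def test_shift_fitted_and_reused(self):
        x = np.array([-5.0, 0.0, 3.0])
        spec = TransformSpec("sqrt_shift")
        pn.transform_variable(x, spec)
        assert spec.params["shift"] == pytest.approx(5.0)
        # reuse on new data applies the recorded shift
        out = pn.transform_variable(np.array([4.0]), spec)
        assert out[0] == pytest.approx(3.0)

    def test_power_transform_tames_lognormal_skew(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0.0, 1.0, 4000)
        spec = TransformSpec("power")
        y = pn.transform_variable(x, spec)
        assert abs(sps.skew(y)) < 0.5
        assert abs(sps.skew(x)) > 2.0

    def test_nonfinite_output_names_variable(self):
        x = np.array([1.0, np.nan])
        with pytest.raises(ValueError, match="bio9"):
            pn.transform_variable(x, TransformSpec("identity"),
                                  variable="bio9")


def _toy_grid(n=60, seed=0, corr=True):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = 2.0 * a if corr else rng.normal(size=n)
    return pd.DataFrame(
        {
            "region_id": [f"R{i % 6}" for i in range(n)],
            "cell_id": [f"c{i}" for i in range(n)],
            "bio1": a,
            "bio2": b,
        }
    )


class TestClimatePca:
    def test_perfectly_correlated_pair_one_axis(self):
        grid = _toy_grid(corr=True)
        pca = pn.fit_climate_pca(
            grid, variables=["bio1", "bio2"],
            transforms={
                "bio1": TransformSpec("identity"),
                "bio2": TransformSpec("identity"),
            },
        )
        assert pca.explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_independent_pair_splits_variance(self):
        grid = _toy_grid(n=4000, corr=False)
        pca = pn.fit_climate_pca(
            grid, variables=["bio1", "bio2"],
            transforms={
                "bio1": TransformSpec("identity"),
                "bio2": TransformSpec("identity"),
            },
        )
        assert pca.explained[0] == pytest.approx(0.5, abs=0.05)

    def test_reconstruction_with_all_axes(self, small_world):
        pca = pn.fit_climate_pca(small_world.climate)
        X = pca.standardize(small_world.climate)
        scores = pca.scores(small_world.climate)
        np.testing.assert_allclose(
            scores @ pca.components, X, atol=1e-8
        )

    def test_explained_fractions_valid(self, small_world):
        pca = pn.fit_climate_pca(small_world.climate)
        assert np.all(np.diff(pca.explained) <= 1e-12)
        assert pca.explained.sum() <= 1.0 + 1e-9

    def test_zero_variance_variable_raises(self):
        grid = _toy_grid()
        grid["bio2"] = 1.0
        with pytest.raises(ValueError, match="bio2"):
            pn.fit_climate_pca(
                grid, variables=["bio1", "bio2"],
                transforms={
                    "bio1": TransformSpec("identity"),
                    "bio2": TransformSpec("identity"),
                },
            )

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError, match="20"):
            pn.fit_climate_pca(_toy_grid(n=10), variables=["bio1", "bio2"])

    def test_pc_temp_tracks_latitude(self, small_world):
        """Axis 1 is a temperature axis: strongly negative correlation
        with absolute latitude in a latitude-driven climate."""
        pca = pn.fit_climate_pca(small_world.climate)
        scores = region_scores_frame(pca, small_world.climate)
        alat = {
            r.region_id: abs(r.latitude) for r in small_world.regions
        }
        r = np.corrcoef(
            scores["pc_temp"],
            [alat[rid] for rid in scores["region_id"]],
        )[0, 1]
        assert r < -0.8

    def test_region_modes_differ_but_correlate(self, small_world):
        cell = pn.fit_climate_pca(small_world.climate, mode="cell")
        region = pn.fit_climate_pca(small_world.climate, mode="region")
        a = region_scores_frame(cell, small_world.climate)["pc_temp"]
        b = region_scores_frame(region, small_world.climate)["pc_temp"]
        assert abs(np.corrcoef(a, b)[0, 1]) > 0.9


class TestRegionScores:
    def test_single_cell_region(self):
        grid = _toy_grid()
        pca = pn.fit_climate_pca(
            grid, variables=["bio1", "bio2"],
            transforms={
                "bio1": TransformSpec("identity"),
                "bio2": TransformSpec("identity"),
            },
        )
        single = grid.iloc[[0]].assign(region_id="solo")
        grid2 = pd.concat([grid, single], ignore_index=True)
        pc1, pc2 = pn.region_pc_scores(pca, grid2, "solo")
        cell_scores = pca.scores(single)
        assert pc1 == pytest.approx(cell_scores[0, 0])

    def test_unknown_region_raises(self):
        grid = _toy_grid()
        pca = pn.fit_climate_pca(
            grid, variables=["bio1", "bio2"],
            transforms={"bio1": TransformSpec("identity"),
                        "bio2": TransformSpec("identity")},
        )
        with pytest.raises(KeyError):
            pn.region_pc_scores(pca, grid, "nowhere")

    def test_mean_score_vs_score_of_mean_non_commutation(self,
                                                         small_world):
        """With nonlinear transforms, averaging cell scores differs from
        scoring per-variable region means (documented non-commutation)."""
        grid = small_world.climate
        pca = pn.fit_climate_pca(grid)
        mean_scores = region_scores_frame(pca, grid)
        region_means = grid.groupby("region_id", as_index=False)[
            pca.variables
        ].mean()
        scored_means = pca.scores(region_means)
        diff = np.abs(
            mean_scores["pc_temp"].to_numpy() - scored_means[:, 0]
        )
        assert diff.max() > 1e-6  # they do differ...
        assert np.corrcoef(
            mean_scores["pc_temp"], scored_means[:, 0]
        )[0, 1] > 0.99  # ...but only slightly


class TestAuc:
    def test_known_values(self):
        assert pn.evaluate_auc([0.9, 0.8], [0.2, 0.1]) == 1.0
        assert pn.evaluate_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pn.evaluate_auc([], [0.1])

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_pair_enumeration(self, data):
        pos = data.draw(
            st.lists(st.integers(0, 10), min_size=1, max_size=20)
        )
        neg = data.draw(
            st.lists(st.integers(0, 10), min_size=1, max_size=20)
        )
        wins = sum(
            1.0 if p > n else (0.5 if p == n else 0.0)
            for p in pos for n in neg
        )
        assert pn.evaluate_auc(pos, neg) == pytest.approx(
            wins / (len(pos) * len(neg))
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        pos, neg = rng.normal(1, 1, 50), rng.normal(0, 1, 70)
        base = pn.evaluate_auc(pos, neg)
        for f in (np.exp, lambda x: x**3, lambda x: 2 * x - 7):
            assert pn.evaluate_auc(f(pos), f(neg)) == pytest.approx(base)


class TestMaxSss:
    def test_known_case(self):
        thr = pn.max_sss_threshold(
            [0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]
        )
        assert thr == pytest.approx(0.8)

    def test_separable_gives_smallest_presence_score(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0.6, 1.0, 30)
        neg = rng.uniform(0.0, 0.5, 40)
        thr = pn.max_sss_threshold(
            np.concatenate([pos, neg]),
            np.concatenate([np.ones(30, bool), np.zeros(40, bool)]),
        )
        assert thr == pytest.approx(pos.min())

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            pn.max_sss_threshold([0.1, 0.2], [1, 1])

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_bruteforce(self, data):
        n = data.draw(st.integers(4, 25))
        scores = data.draw(
            st.lists(
                st.floats(0, 1, allow_nan=False), min_size=n, max_size=n
            )
        )
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n)
        )
        if all(labels) or not any(labels):
            return
        s, y = np.asarray(scores), np.asarray(labels)
        best_val, best_thr = -1.0, None
        for t in sorted(set(scores)):
            sens = np.mean(s[y] >= t)
            spec = np.mean(s[~y] < t)
            val = sens + spec
            if val > best_val - 1e-12 and (
                val > best_val + 1e-12 or t > best_thr
            ):
                best_val, best_thr = max(val, best_val), t
        assert pn.max_sss_threshold(s, y) == pytest.approx(best_thr)

    def test_maximizer_dominates_all_candidates(self):
        rng = np.random.default_rng(4)
        s = rng.random(60)
        y = rng.random(60) < 0.4
        if not y.any() or y.all():
            y[0], y[1] = True, False
        thr = pn.max_sss_threshold(s, y)

        def sss(t):
            return np.mean(s[y] >= t) + np.mean(s[~y] < t)

        for t in np.unique(s):
            assert sss(thr) >= sss(t) - 1e-12


class TestEnvelopeModel:
    def _cells(self, rng, n, mean, spread=1.0):
        X = rng.normal(mean, spread, size=(n, len(SDM_VARS)))
        return pd.DataFrame(X, columns=SDM_VARS)

    def test_score_is_one_at_mean(self):
        rng = np.random.default_rng(0)
        pres = self._cells(rng, 40, 0.0)
        bg = self._cells(rng, 80, 3.0)
        model = fit_envelope_model(pres, bg, species="sp", seed=1)
        at_mean = model.score(
            pd.DataFrame([model.mean], columns=SDM_VARS)
        )
        assert at_mean[0] == pytest.approx(1.0)

    def test_scores_decrease_along_ray(self):
        rng = np.random.default_rng(0)
        model = fit_envelope_model(
            self._cells(rng, 40, 0.0), self._cells(rng, 80, 3.0),
            seed=1,
        )
        direction = np.ones(len(SDM_VARS))
        pts = pd.DataFrame(
            [model.mean + t * direction for t in (0.0, 0.5, 1.0, 2.0)],
            columns=SDM_VARS,
        )
        s = model.score(pts)
        assert np.all(np.diff(s) < 0)

    def test_separable_synthetic_set_has_auc_one(self):
        rng = np.random.default_rng(5)
        pres = self._cells(rng, 30, 0.0, spread=0.5)
        bg = self._cells(rng, 60, 8.0, spread=0.5)
        model = fit_envelope_model(pres, bg, seed=2)
        assert model.auc_test == pytest.approx(1.0)
        assert model.retained

    def test_too_few_presences_skipped(self):
        rng = np.random.default_rng(1)
        with pytest.raises(pn.climate.TooFewOccurrences):
            fit_envelope_model(
                self._cells(rng, 15, 0.0), self._cells(rng, 40, 2.0)
            )

    def test_suitable_regions_monotone_in_threshold(self, small_world):
        w = small_world
        suit, report = pn.suitability_table(
            w.occurrences, w.climate,
            species_list=sorted(w.registry.naturalized_anywhere())[:40],
            seed=0,
        )
        retained = report[report["status"] == "retained"]
        assert len(retained) > 0
        sp = retained.iloc[0]["species"]
        cells = set(
            w.occurrences.loc[w.occurrences["species"] == sp, "cell_id"]
        )
        pres = w.climate[w.climate["cell_id"].isin(cells)]
        bg = w.climate[~w.climate["cell_id"].isin(cells)]
        model = fit_envelope_model(pres, bg, species=sp, seed=3)
        model.retained = True
        prev = None
        for thr in (0.9, 0.6, 0.3, 0.05):
            model.threshold = thr
            regions = pn.suitable_regions(model, w.climate)
            if prev is not None:
                assert prev <= regions
            prev = regions

    def test_region_with_presence_cell_is_suitable(self, small_world):
        """A region holding training presences scores at or above the
        training max-SSS threshold in at least one cell."""
        w = small_world
        suit, report = pn.suitability_table(
            w.occurrences, w.climate,
            species_list=sorted(w.registry.naturalized_anywhere())[:60],
            seed=0,
        )
        checked = hits = 0
        occ = w.occurrences.groupby("species")["cell_id"]
        cell_region = dict(
            zip(w.climate["cell_id"], w.climate["region_id"])
        )
        for sp, regions in suit.items():
            pres_regions = {
                cell_region[c] for c in occ.get_group(sp)
            }
            hits += len(pres_regions & regions)
            checked += len(pres_regions)
        assert checked and hits / checked > 0.8
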