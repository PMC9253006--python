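"""Establishment stage: thinning, screening, the suitability model, zonal stats."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import paninvasion as pv
from paninvasion.establishment import _rank_auc


class TestThinning:
    def test_two_points_same_cell(self):
        occ = pv.OccurrenceSet("sp", [(0.1, 0.1), (0.2, 0.2)])
        assert len(pv.thin_occurrences(occ, cellsize=1.0)) == 1

    def test_distinct_cells_all_kept(self):
        occ = pv.OccurrenceSet("sp", [(0.5, 0.5), (1.5, 0.5), (2.5, 0.5)])
        assert len(pv.thin_occurrences(occ, cellsize=1.0)) == 3

    def test_exact_duplicates_removed_first(self):
        occ = pv.OccurrenceSet("sp", [(0.5, 0.5), (0.5, 0.5)])
        assert len(pv.thin_occurrences(occ, cellsize=1.0)) == 1

    def test_empty_input_ok(self):
        out = pv.thin_occurrences(pv.OccurrenceSet("sp", np.empty((0, 2))), 1.0)
        assert len(out) == 0

    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, size=(40, 2))
        occ = pv.OccurrenceSet("sp", pts)
        once = pv.thin_occurrences(occ, cellsize=1.0)
        twice = pv.thin_occurrences(once, cellsize=1.0)
        assert len(once) <= len(occ)
        cells = {(int(np.floor((x + 180) / 1.0)), int(np.floor((90 - y) / 1.0))) for x, y in pts}
        assert len(once) <= len(cells)
        np.testing.assert_array_equal(
            np.sort(once.points, axis=0), np.sort(twice.points, axis=0)
        )


class TestScreening:
    def test_identical_covariates_reduced_to_one(self):
        g = pv.Grid(np.random.default_rng(0).normal(size=(10, 10)), (0.0, 10.0), 1.0)
        g2 = pv.Grid(g.values.copy(), g.origin, g.cellsize)
        stack = pv.CovariateStack(["a", "b"], [g, g2])
        assert len(pv.screen_covariates(stack, 0.7)) == 1

    def test_uncorrelated_all_retained(self, small_stack):
        kept = pv.screen_covariates(small_stack, 0.99)
        assert kept == small_stack.names

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        g = pv.Grid(rng.normal(size=(8, 8)), (0.0, 8.0), 1.0)
        c = pv.Grid(np.ones((8, 8)), (0.0, 8.0), 1.0)
        with pytest.warns(UserWarning, match="constant"):
            kept = pv.screen_covariates(pv.CovariateStack(["g", "c"], [g, c]), 0.7)
        assert kept == ["g"]

    def test_retained_set_valid_and_matches_bruteforce_on_triples(self):
        """Greedy keeps all pairwise |r| <= threshold and, on constructed
        triples, retains as many covariates as exhaustive search."""
        rng = np.random.default_rng(7)
        base = rng.normal(size=(12, 12))
        indep = rng.normal(size=(12, 12))
        near_copy = base + 0.05 * rng.normal(size=(12, 12))
        stack = pv.CovariateStack(
            ["base", "copy", "indep"],
            [pv.Grid(v, (0.0, 12.0), 1.0) for v in (base, near_copy, indep)],
        )
        threshold = 0.7
        kept = pv.screen_covariates(stack, threshold)
        flat = {n: stack[n].values.ravel() for n in stack.names}

        def valid(subset):
            return all(
                abs(np.corrcoef(flat[a], flat[b])[0, 1]) <= threshold
                for a, b in itertools.combinations(subset, 2)
            )

        assert valid(kept)
        best = max(
            (s for r in range(1, 4) for s in itertools.combinations(stack.names, r) if valid(s)),
            key=len,
        )
        assert len(kept) == len(best)


class TestBackground:
    def test_distinct_centers(self, small_stack):
        pts = pv.sample_background(small_stack, 5, seed=0)
        assert len(np.unique(pts, axis=0)) == 5

    def test_seed_reproducible(self, small_stack):
        a = pv.sample_background(small_stack, 10, seed=4)
        b = pv.sample_background(small_stack, 10, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_too_many_rejected(self, small_stack):
        with pytest.raises(ValueError, match="valid pixels"):
            pv.sample_background(small_stack, 30 * 30 + 1, seed=0)


def _presences_where_high(stack, name, n, seed=0):
    """Sample presence points preferentially where one covariate is high."""
    rng = np.random.default_rng(seed)
    vals = stack[name].values
    w = np.exp(2.0 * vals).ravel()
    idx = rng.choice(w.size, size=n, p=w / w.sum())
    rows, cols = np.unravel_index(idx, stack.shape)
    west, north = stack.origin
    lon = west + (cols + 0.5) * stack.cellsize
    lat = north - (rows + 0.5) * stack.cellsize
    return pv.OccurrenceSet("sp", np.column_stack([lon, lat]))


class TestSuitabilityModel:
    def test_positive_coefficient_on_driving_covariate(self, small_stack):
        occ = _presences_where_high(small_stack, "cov0", 150, seed=1)
        bg = pv.sample_background(small_stack, 400, seed=2)
        model = pv.fit_suitability(occ, bg, small_stack)
        assert model.coefficients[small_stack.names.index("cov0")] > 0

    def test_scores_in_unit_interval(self, small_stack):
        occ = _presences_where_high(small_stack, "cov0", 60, seed=3)
        bg = pv.sample_background(small_stack, 200, seed=4)
        model = pv.fit_suitability(occ, bg, small_stack)
        suit = pv.predict_suitability(model, small_stack)
        valid = suit.values[~np.isnan(suit.values)]
        assert valid.min() >= 0 and valid.max() <= 1

    def test_uninformative_presences_near_chance(self, small_stack):
        rng = np.random.default_rng(5)
        bg = pv.sample_background(small_stack, 500, seed=5)
        occ = pv.OccurrenceSet("sp", bg[rng.choice(500, 300, replace=False)])
        model = pv.fit_suitability(occ, bg, small_stack)
        auc = _rank_auc(model.score(_cov(occ.points, small_stack)), model.score(_cov(bg, small_stack)))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_nodata_presences_dropped(self, small_stack):
        vals = small_stack.grids[0].values.copy()
        vals[0, 0] = np.nan
        stack = pv.CovariateStack(
            small_stack.names,
            [pv.Grid(vals, small_stack.origin, small_stack.cellsize)]
            + small_stack.grids[1:],
        )
        occ = _presences_where_high(stack, "cov1", 50, seed=6)
        west, north = stack.origin
        bad = [west + 0.5 * stack.cellsize, north - 0.5 * stack.cellsize]
        occ = pv.OccurrenceSet("sp", np.vstack([occ.points, bad]))
        bg = pv.sample_background(stack, 100, seed=7)
        with pytest.warns(UserWarning, match="nodata"):
            pv.fit_suitability(occ, bg, stack)

    def test_monotone_gradient_prediction(self, gradient_stack):
        occ = _presences_where_high(gradient_stack, "grad", 80, seed=8)
        bg = pv.sample_background(gradient_stack, 200, seed=9)
        model = pv.fit_suitability(occ, bg, gradient_stack, features=("linear",))
        suit = pv.predict_suitability(model, gradient_stack)
        row = suit.values[0]
        assert (np.diff(row) > 0).all()  # increases along the gradient

    def test_missing_covariate_rejected(self, small_stack):
        occ = _presences_where_high(small_stack, "cov0", 60, seed=10)
        bg = pv.sample_background(small_stack, 100, seed=10)
        model = pv.fit_suitability(occ, bg, small_stack)
        partial = small_stack.subset(small_stack.names[:2])
        with pytest.raises(ValueError, match="missing"):
            pv.predict_suitability(model, partial)


def _cov(points, stack):
    from paninvasion.establishment import _extract_covariates

    x = _extract_covariates(points, stack)
    return x[~np.isnan(x).any(axis=1)]


class TestHostChained:
    def test_positive_response_to_host(self, small_stack):
        occ = _presences_where_high(small_stack, "cov0", 120, seed=11)
        bg = pv.sample_background(small_stack, 300, seed=12)
        host_model = pv.fit_suitability(occ, bg, small_stack)
        host = pv.predict_suitability(host_model, small_stack)
        pest = _presences_where_high(small_stack, "cov0", 100, seed=13)
        chained = pv.fit_host_chained(pest, host, bg)
        assert chained.coefficients[0] > 0
        assert not chained.degenerate

    def test_constant_host_flagged(self, small_stack):
        host = pv.SuitabilityGrid(
            np.full(small_stack.shape, 0.5), small_stack.origin, small_stack.cellsize
        )
        pest = _presences_where_high(small_stack, "cov0", 60, seed=14)
        bg = pv.sample_background(small_stack, 100, seed=15)
        chained = pv.fit_host_chained(pest, host, bg)
        assert chained.degenerate


class TestEnsembleMean:
    def geometry(self):
        return (0.0, 3.0), 1.0

    def grid(self, vals):
        origin, cs = self.geometry()
        return pv.SuitabilityGrid(np.asarray(vals, dtype=float), origin, cs)

    def test_per_pixel_mean(self):
        out = pv.ensemble_mean(
            [self.grid([[0.2]]), self.grid([[0.4]]), self.grid([[0.6]])]
        )
        assert out.values[0, 0] == pytest.approx(0.4)

    def test_single_grid_identity(self):
        g = self.grid([[0.3, 0.7]])
        np.testing.assert_array_equal(pv.ensemble_mean([g]).values, g.values)

    def test_any_nodata_propagates(self):
        out = pv.ensemble_mean([self.grid([[0.2]]), self.grid([[np.nan]])])
        assert np.isnan(out.values[0, 0])

    def test_bounded_by_member_envelope(self):
        rng = np.random.default_rng(16)
        grids = [self.grid(rng.uniform(size=(3, 1)).T) for _ in range(4)]
        arr = np.stack([g.values for g in grids])
        out = pv.ensemble_mean(grids).values
        assert (out >= arr.min(axis=0)).all() and (out <= arr.max(axis=0)).all()

    def test_shape_mismatch_rejected(self):
        a = self.grid([[0.1]])
        b = pv.SuitabilityGrid(np.array([[0.1, 0.2]]), (0.0, 3.0), 1.0)
        with pytest.raises(ValueError, match="geometry"):
            pv.ensemble_mean([a, b])


class TestZonal:
    def test_small_examples(self):
        suit = pv.SuitabilityGrid(np.array([[0.2, 0.9]]), (0.0, 1.0), 1.0)
        zones = pv.RegionGrid(np.array([["A", "A"]], dtype=object), (0.0, 1.0), 1.0)
        assert pv.zonal_potential(suit, zones, "max")["establishment"].iloc[0] == 0.9
        assert pv.zonal_potential(suit, zones, "mean")["establishment"].iloc[0] == pytest.approx(0.55)

    def test_matches_loop_oracle_on_random_grids(self):
        rng = np.random.default_rng(17)
        suit_vals = rng.uniform(size=(50, 50))
        suit_vals[rng.uniform(size=(50, 50)) < 0.1] = np.nan
        labels = rng.choice(["A", "B", "C", "D", None], size=(50, 50)).astype(object)
        suit = pv.SuitabilityGrid(suit_vals, (0.0, 50.0), 1.0)
        zones = pv.RegionGrid(labels, (0.0, 50.0), 1.0)
        for stat, fn in [("max", np.nanmax), ("mean", np.nanmean), ("median", np.nanmedian)]:
            out = pv.zonal_potential(suit, zones, stat).set_index("region")["establishment"]
            for region in "ABCD":
                pix = suit_vals[labels == region]
                assert out[region] == pytest.approx(fn(pix))

    def test_max_at_least_mean(self):
        rng = np.random.default_rng(18)
        suit = pv.SuitabilityGrid(rng.uniform(size=(20, 20)), (0.0, 20.0), 1.0)
        zones = pv.RegionGrid(
            rng.choice(["A", "B"], size=(20, 20)).astype(object), (0.0, 20.0), 1.0
        )
        mx = pv.zonal_potential(suit, zones, "max").set_index("region")["establishment"]
        mn = pv.zonal_potential(suit, zones, "mean").set_index("region")["establishment"]
        assert (mx >= mn).all()

    def test_empty_region_missing(self):
        suit = pv.SuitabilityGrid(np.array([[np.nan, 0.5]]), (0.0, 1.0), 1.0)
        zones = pv.RegionGrid(np.array([["A", "B"]], dtype=object), (0.0, 1.0), 1.0)
        out = pv.zonal_potential(suit, zones, "max").set_index("region")["establishment"]
        assert np.isnan(out["A"]) and out["B"] == 0.5

    def test_unknown_stat_rejected(self):
        suit = pv.SuitabilityGrid(np.array([[0.5]]), (0.0, 1.0), 1.0)
        zones = pv.RegionGrid(np.array([["A"]], dtype=object), (0.0, 1.0), 1.0)
        with pytest.raises(ValueError, match="statistic"):
            pv.zonal_potential(suit, zones, "mode")


class TestRankAUC:
    def test_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            pos = rng.normal(0.3, 1, size=rng.integers(3, 40))
            neg = rng.normal(0, 1, size=rng.integers(3, 40))
            pairs = np.mean(
                [
                    1.0 if p > q else (0.5 if p == q else 0.0)
                    for p in pos
                    for q in neg
                ]
            )
            assert _rank_auc(pos, neg) == pytest.approx(pairs, abs=1e-12)


class TestKFold:
    def test_separable_auc_one_and_zero_omission(self, gradient_stack):
        # presences strictly on the high half, background on the low half
        west, north = gradient_stack.origin
        cs = gradient_stack.cellsize
        pres = np.array(
            [[west + (c + 0.5) * cs, north - (r + 0.5) * cs] for r in range(20) for c in range(15, 20)]
        )
        bg = np.array(
            [[west + (c + 0.5) * cs, north - (r + 0.5) * cs] for r in range(20) for c in range(0, 5)]
        )
        ev = pv.evaluate_kfold(
            pv.OccurrenceSet("sp", pres), bg, gradient_stack, k=5, seed=0,
            features=("linear",),
        )
        assert ev.auc == 1.0
        assert ev.omission_rate == 0.0

    def test_random_labels_near_chance(self, small_stack):
        # presences drawn from the background distribution, independently of
        # the evaluation background sample (a shared subset would bias AUC low)
        rng = np.random.default_rng(20)
        bg = pv.sample_background(small_stack, 500, seed=21)
        rows, cols = rng.integers(0, 30, 250), rng.integers(0, 30, 250)
        west, north = small_stack.origin
        cs = small_stack.cellsize
        pres = np.column_stack(
            [west + (cols + 0.5) * cs, north - (rows + 0.5) * cs]
        )
        ev = pv.evaluate_kfold(pv.OccurrenceSet("sp", pres), bg, small_stack, k=5, seed=22)
        assert ev.auc == pytest.approx(0.5, abs=0.05)

    def test_k_exceeding_presences_rejected(self, small_stack):
        occ = pv.OccurrenceSet("sp", pv.sample_background(small_stack, 3, seed=0))
        with pytest.raises(ValueError, match="exceeds"):
            pv.evaluate_kfold(occ, occ.points, small_stack, k=5)
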