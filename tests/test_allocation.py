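"""Risk mapping, MDG ranking and weighted pixel allocation."""

import numpy as np
import pytest

from hfld import allocation as al
from hfld.errors import DegenerateTrainingError, SaturationError, SchemaError


def _stack_from(layers, pixel_size=30.0):
    return al.CovariateStack(layers=dict(layers), pixel_size=pixel_size)


class TestDistanceStack:
    def test_on_feature_distance_zero(self, small_landscape):
        stack = small_landscape.covariates()
        assert (stack.layers["dist_road"][small_landscape.roads] == 0).all()

    def test_single_feature_pythagoras(self):
        roads = np.zeros((20, 20), dtype=bool)
        roads[5, 5] = True
        stack = al.distance_stack(roads, np.zeros((20, 20), bool),
                                  np.zeros((20, 20), np.int16),
                                  np.zeros((20, 20), bool), 30.0)
        # (3, 4) pixels away -> 5 px = 150 m
        assert stack.layers["dist_road"][8, 9] == pytest.approx(150.0)

    def test_matches_bruteforce_nearest_feature(self, rng):
        feat = np.zeros((50, 50), dtype=bool)
        feat.ravel()[rng.choice(2500, size=15, replace=False)] = True
        stack = al.distance_stack(feat, np.zeros((50, 50), bool),
                                  np.zeros((50, 50), np.int16),
                                  np.zeros((50, 50), bool), 30.0)
        rr, cc = np.nonzero(feat)
        gi, gj = np.meshgrid(np.arange(50), np.arange(50), indexing="ij")
        brute = np.min(np.sqrt((gi[..., None] - rr)**2 + (gj[..., None] - cc)**2),
                       axis=-1) * 30.0
        np.testing.assert_allclose(stack.layers["dist_road"], brute, rtol=1e-9)

    def test_empty_layer_gets_sentinel_and_flag(self):
        stack = al.distance_stack(np.zeros((10, 10), bool), np.zeros((10, 10), bool),
                                  np.zeros((10, 10), np.int16),
                                  np.zeros((10, 10), bool), 30.0)
        assert "dist_road" in stack.empty_layers
        assert (stack.layers["dist_road"] == 30.0 * 20).all()

    def test_streams_split_by_strahler_class(self):
        streams = np.zeros((10, 10), dtype=np.int16)
        streams[2, 2] = 2    # small
        streams[7, 7] = 5    # intermediate
        stack = al.distance_stack(np.zeros((10, 10), bool), np.zeros((10, 10), bool),
                                  streams, np.zeros((10, 10), bool), 30.0)
        assert stack.layers["dist_stream_small"][2, 2] == 0
        assert stack.layers["dist_stream_mid"][7, 7] == 0
        assert stack.layers["dist_stream_small"][7, 7] > 0
        assert "dist_stream_large" in stack.empty_layers


def _toy_stack(rng, n=40):
    grad = np.tile(np.arange(n, dtype=float) * 30.0, (n, 1))
    layers = {"protected": np.zeros((n, n)),
              "dist_road": grad,
              "dist_greenstone": rng.uniform(0, 3000, (n, n)),
              "dist_stream_small": rng.uniform(0, 3000, (n, n)),
              "dist_stream_mid": rng.uniform(0, 3000, (n, n)),
              "dist_stream_large": rng.uniform(0, 3000, (n, n))}
    return _stack_from(layers)


class TestTrainAndPredict:
    def test_separable_labels_give_top_mdg_and_perfect_heldout(self, rng):
        stack = _toy_stack(rng)
        labels = stack.layers["dist_road"] < 300.0  # first 10 columns
        forest = np.ones_like(labels, dtype=bool)
        model = al.train_location_model(stack, labels, forest, seed=0)
        assert model.top_covariate() == "dist_road"
        risk = al.predict_risk(model, stack, forest)
        assert ((risk > 0.5) == labels).mean() > 0.99

    def test_uninformative_labels_near_chance_accuracy(self, rng):
        stack = _toy_stack(rng)
        labels = np.zeros((40, 40), dtype=bool)
        labels.ravel()[rng.choice(1600, size=400, replace=False)] = True
        # hold out a quarter of the grid entirely
        train_zone = np.ones((40, 40), dtype=bool)
        train_zone[:, 30:] = False
        model = al.train_location_model(stack, labels & train_zone, train_zone, seed=1)
        risk = al.predict_risk(model, stack, ~train_zone)
        held_labels = labels[~train_zone]
        acc = ((risk[~train_zone] > 0.5) == held_labels).mean()
        base = max(held_labels.mean(), 1 - held_labels.mean())
        se = np.sqrt(0.25 / held_labels.size)
        assert acc <= base + 3 * se

    def test_single_class_labels_rejected(self, rng):
        stack = _toy_stack(rng)
        with pytest.raises(DegenerateTrainingError):
            al.train_location_model(stack, np.zeros((40, 40), bool),
                                    np.ones((40, 40), bool))

    def test_risk_zero_outside_mask_and_bounded(self, rng):
        stack = _toy_stack(rng)
        labels = stack.layers["dist_road"] < 300.0
        model = al.train_location_model(stack, labels, np.ones((40, 40), bool), seed=2)
        empty = al.predict_risk(model, stack, np.zeros((40, 40), bool))
        assert not empty.any()
        mask = np.zeros((40, 40), dtype=bool)
        mask[::2] = True
        risk = al.predict_risk(model, stack, mask)
        assert risk.min() >= 0 and risk.max() <= 1
        assert not risk[~mask].any()

    def test_covariate_name_mismatch_rejected(self, rng):
        stack = _toy_stack(rng)
        labels = stack.layers["dist_road"] < 300.0
        model = al.train_location_model(stack, labels, np.ones((40, 40), bool), seed=3)
        other = _stack_from({"odd_name": np.zeros((40, 40))})
        with pytest.raises(SchemaError):
            al.predict_risk(model, other, np.ones((40, 40), bool))

    def test_monotone_risk_along_distance_transect(self, rng):
        stack = _toy_stack(rng)
        labels = stack.layers["dist_road"] < 450.0
        forest = np.ones((40, 40), dtype=bool)
        model = al.train_location_model(stack, labels, forest, seed=4)
        risk = al.predict_risk(model, stack, forest)
        transect = risk.mean(axis=0)  # columns = increasing road distance
        assert np.all(np.diff(transect) <= 0.02)


class TestAllocate:
    def test_zero_demand_empty(self):
        r, c = al.allocate(np.ones((5, 5)) * 0.5, 0.0, 0.09, seed=0)
        assert len(r) == 0 and len(c) == 0

    def test_exact_pixel_count(self, rng):
        risk = rng.random((30, 30))
        for ha in (0.09, 1.0, 13.5, 45.0):
            r, _ = al.allocate(risk, ha, 0.09, seed=1)
            assert len(r) == round(ha / 0.09)

    def test_exhaustion_takes_every_pixel(self):
        risk = np.full((6, 6), 0.3)
        r, c = al.allocate(risk, 36 * 0.09, 0.09, seed=2)
        assert len(r) == 36

    def test_demand_beyond_pool_rejected(self):
        with pytest.raises(SaturationError):
            al.allocate(np.full((3, 3), 0.5), 10 * 0.09, 0.09, seed=0)

    def test_two_pixel_frequencies_match_weights(self):
        risk = np.array([[0.9, 0.1]])
        rng = np.random.default_rng(99)
        hits = sum(al.allocate(risk, 0.09, 0.09, rng)[1][0] == 0
                   for _ in range(20_000))
        assert hits / 20_000 == pytest.approx(0.9, abs=0.01)


class TestProjectMaps:
    def test_zero_trajectory_empty_maps(self):
        forest = np.ones((10, 10), dtype=bool)
        proj = al.project_maps({"all": np.zeros(35)}, {"all": np.ones((10, 10))},
                               forest, 0.09, seed=0)
        assert not proj.any()

    def test_erb_deforests_exactly_unprotected_forest(self, rng):
        forest = np.ones((40, 40), dtype=bool)
        protected = np.zeros((40, 40), dtype=bool)
        protected[:, :10] = True  # 25 %
        available_px = int((forest & ~protected).sum())
        annual = np.full(35, available_px * 0.09 / 35)
        proj = al.project_maps({"all": annual}, {"all": rng.random((40, 40))},
                               forest, 0.09, seed=3, allowed_mask=~protected)
        assert not (proj[protected] > 0).any()
        remaining = (forest & ~protected & (proj == 0)).sum()
        assert remaining <= 35  # at most one rounding pixel per year

    def test_gold_only_split_draws_from_gold_risk(self):
        forest = np.ones((20, 20), dtype=bool)
        gold_risk = np.zeros((20, 20)); gold_risk[:, :5] = 1.0
        dem_risk = np.ones((20, 20))
        annual = {"gold": np.full(35, 2 * 0.09), "dem": np.zeros(35)}
        proj = al.project_maps(annual, {"gold": gold_risk, "dem": dem_risk},
                               forest, 0.09, seed=4)
        r, c = np.nonzero(proj)
        assert len(r) == 70
        assert (c < 5).all()

    def test_measure_preserving_per_year(self, rng):
        forest = np.ones((30, 30), dtype=bool)
        annual = rng.uniform(0.0, 2.0, size=35)
        proj = al.project_maps({"all": annual}, {"all": rng.random((30, 30))},
                               forest, 0.09, seed=5)
        for t, year in enumerate(2016 + np.arange(35)):
            assert (proj == year).sum() == round(annual[t] / 0.09)

    def test_saturating_demand_caps_with_warning(self):
        forest = np.ones((5, 5), dtype=bool)
        annual = np.zeros(35); annual[0] = 100.0  # far beyond 25 px
        with pytest.warns(UserWarning, match="capped"):
            proj = al.project_maps({"all": annual}, {"all": np.ones((5, 5))},
                                   forest, 0.09, seed=6)
        assert (proj > 0).sum() == 25

    def test_hotspot_share_convention(self):
        forest = np.ones((20, 20), dtype=bool)
        proj = np.zeros((20, 20), dtype=np.uint16)
        proj[:10, :4] = 2030  # 40 % of the first 10x10 block
        flags = al.hotspot_share(proj, forest, cell=10, threshold=0.30)
        assert flags[0, 0] and not flags[0, 1] and not flags[1, 0]
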