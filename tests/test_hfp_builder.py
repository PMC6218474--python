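import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfprisk.grid import Grid, GridMismatchError
from hfprisk.hfp_builder import (
    HFP_MAX,
    LAYER_NAMES,
    NODATA,
    ROAD_DECAY,
    WATERWAY_DECAY,
    DecayParams,
    HFPMap,
    PressureStack,
    build_hfp,
    distance_decay_score,
    hfp_change,
    standardize_layer,
)

from conftest import empty_layers, hfp_from_values, make_stack


class TestStandardizeLayer:
    def test_built_scores_10(self, grid5):
        raw = np.zeros(grid5.shape, dtype=bool)
        raw[2, 2] = True
        scored = standardize_layer("built", raw, grid5).scores
        assert scored[2, 2] == 10.0
        assert scored[0, 0] == 0.0

    @pytest.mark.parametrize(
        "name,score", [("built", 10.0), ("crop", 7.0), ("pasture", 4.0)]
    )
    def test_landuse_binary_scores(self, grid5, name, score):
        raw = np.ones(grid5.shape, dtype=bool)
        assert set(np.unique(standardize_layer(name, raw, grid5).scores)) == {score}

    def test_popdensity_zero_scores_zero(self, grid5):
        raw = np.zeros(grid5.shape)
        assert standardize_layer("popdensity", raw, grid5).scores.max() == 0.0

    def test_popdensity_log_scale(self, grid5):
        # oracle: 3.333 * log10(100 + 1) = 6.680403...
        raw = np.full(grid5.shape, 100.0)
        expected = 3.333 * math.log10(101.0)
        got = standardize_layer("popdensity", raw, grid5).scores[0, 0]
        assert got == pytest.approx(expected)
        assert got == pytest.approx(6.68, abs=5e-3)

    def test_popdensity_above_cutoff_scores_10(self, grid5):
        raw = np.full(grid5.shape, 1500.0)
        assert standardize_layer("popdensity", raw, grid5).scores[0, 0] == 10.0

    def test_popdensity_negative_rejected(self, grid5):
        raw = np.full(grid5.shape, -1.0)
        with pytest.raises(ValueError, match="non-negative"):
            standardize_layer("popdensity", raw, grid5)

    def test_nightlights_deciles(self):
        # 100 lit cells 1..100 -> ten cells per decile, scores 1..10
        grid = Grid(rows=10, cols=10)
        raw = np.arange(1.0, 101.0).reshape(10, 10)
        scored = standardize_layer("nightlights", raw, grid).scores
        counts = {s: int((scored == s).sum()) for s in range(1, 11)}
        assert counts == {s: 10 for s in range(1, 11)}

    def test_nightlights_unlit_zero_and_ties_lower(self):
        grid = Grid(rows=1, cols=10)
        raw = np.array([[0, 0, 0, 0, 0, 5, 5, 5, 5, 5]], dtype=float)
        scored = standardize_layer("nightlights", raw, grid).scores
        assert (scored[0, :5] == 0).all()
        # all lit values tie: every boundary equals 5, ties take the lower decile
        assert (scored[0, 5:] == 1).all()

    def test_rail_direct_buffer_only(self, grid5):
        raw = np.full(grid5.shape, 0.6)
        raw[1, 1] = 0.4
        scored = standardize_layer("railways", raw, grid5).scores
        assert scored[1, 1] == 8.0
        assert scored[0, 0] == 0.0  # no indirect impact beyond 500 m

    def test_unknown_layer_rejected(self, grid5):
        with pytest.raises(ValueError, match="unknown pressure layer"):
            standardize_layer("mines", np.zeros(grid5.shape), grid5)

    def test_non_boolean_landuse_rejected(self, grid5):
        with pytest.raises(ValueError, match="boolean"):
            standardize_layer("crop", np.full(grid5.shape, 0.5), grid5)

    def test_nan_propagates(self, grid5):
        raw = np.zeros(grid5.shape)
        raw[0, 0] = np.nan
        assert np.isnan(standardize_layer("popdensity", raw, grid5).scores[0, 0])

    @given(st.integers(0, 10_000))
    def test_scores_bounded(self, density):
        grid = Grid(rows=1, cols=1)
        scored = standardize_layer(
            "popdensity", np.full(grid.shape, float(density)), grid
        ).scores
        assert 0.0 <= scored[0, 0] <= 10.0


class TestDistanceDecay:
    def test_road_direct_buffer(self):
        assert distance_decay_score(0.3, ROAD_DECAY) == 8.0

    def test_road_beyond_max(self):
        assert distance_decay_score(20.0, ROAD_DECAY) == 0.0

    def test_road_midpoint_closed_form(self):
        # oracle: indirect_score0 * exp(-k * 7.25) with k = ln(16)/14.5
        d = 0.5 + (15.0 - 0.5) / 2.0
        k = math.log(4.0 / 0.25) / 14.5
        expected = 4.0 * math.exp(-k * 7.25)
        assert distance_decay_score(d, ROAD_DECAY) == pytest.approx(expected)

    def test_tabulated_curve(self):
        # independent tabulation of the closed form on a coarse distance grid
        k = math.log(16.0) / 14.5
        for d in (0.6, 1.0, 2.5, 5.0, 10.0, 14.9):
            expected = 4.0 * math.exp(-k * (d - 0.5))
            assert distance_decay_score(d, ROAD_DECAY) == pytest.approx(expected)

    def test_waterway_bank_scores_4(self):
        assert distance_decay_score(0.0, WATERWAY_DECAY) == 4.0

    def test_score_at_max_dist_rounds_to_zero(self):
        for params in (ROAD_DECAY, WATERWAY_DECAY):
            assert distance_decay_score(params.max_dist_km, params) < 0.5

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            distance_decay_score(-1.0, ROAD_DECAY)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            DecayParams(20.0, 8.0, 4.0, 15.0)

    @given(st.floats(0.0, 30.0))
    def test_nonincreasing_in_distance(self, d):
        nearer = distance_decay_score(max(d - 0.1, 0.0), ROAD_DECAY)
        assert distance_decay_score(d, ROAD_DECAY) <= nearer + 1e-12


class TestBuildHfp:
    def test_all_zero(self, grid5):
        assert build_hfp(make_stack(grid5)).values.max() == 0

    def test_cropland_only_scores_7(self, grid5):
        crop = np.zeros(grid5.shape, dtype=bool)
        crop[1, 1] = True
        hfp = build_hfp(make_stack(grid5, crop=crop))
        assert hfp.values[1, 1] == 7
        assert hfp.values[0, 0] == 0

    def test_maximum_is_50(self, grid5):
        built = np.ones(grid5.shape, dtype=bool)
        lights = np.arange(1.0, 26.0).reshape(grid5.shape)
        stack = make_stack(
            grid5,
            built=built,
            popdensity=np.full(grid5.shape, 2000.0),
            nightlights=lights,
            railways=np.zeros(grid5.shape),
            roads=np.zeros(grid5.shape),
            waterways=np.zeros(grid5.shape),
        )
        hfp = build_hfp(stack)
        # the top night-light decile cell carries every maximal pressure
        top_cell = np.unravel_index(lights.argmax(), grid5.shape)
        assert hfp.values[top_cell] == 50
        assert hfp.values.max() == 50

    def test_rounding_half_up(self, grid5):
        # density giving a 0.5 score: 10^(0.5/3.333) - 1
        d = 10 ** (0.5 / 3.333) - 1.0
        stack = make_stack(grid5, popdensity=np.full(grid5.shape, d))
        assert build_hfp(stack).values[0, 0] == 1  # 0.5 rounds up, not to even

    def test_missing_layer_rejected(self, grid5):
        layers = empty_layers(grid5)
        del layers["roads"]
        stack = PressureStack(grid=grid5, epoch=1993, layers=layers)
        with pytest.raises(ValueError, match="missing layers"):
            build_hfp(stack)

    def test_exclusivity_enforced(self, grid5):
        layers = empty_layers(grid5)
        layers["built"][0, 0] = True
        layers["crop"] = layers["built"].copy()
        with pytest.raises(ValueError, match="mutually exclusive"):
            PressureStack(grid=grid5, epoch=1993, layers=layers)

    def test_grid_mismatch_rejected(self, grid5):
        layers = empty_layers(grid5)
        layers["roads"] = np.full((3, 3), np.inf)
        with pytest.raises(GridMismatchError):
            PressureStack(grid=grid5, epoch=1993, layers=layers)

    def test_nodata_propagates(self, grid5):
        pop = np.zeros(grid5.shape)
        pop[2, 3] = np.nan
        hfp = build_hfp(make_stack(grid5, popdensity=pop))
        assert hfp.values[2, 3] == NODATA
        assert (hfp.values != NODATA).sum() == grid5.n_cells - 1

    def test_monotone_in_raw_layers(self):
        rng = np.random.default_rng(11)
        grid = Grid(rows=8, cols=8)
        pop = rng.uniform(0, 500, grid.shape)
        stack = make_stack(grid, popdensity=pop)
        base = build_hfp(stack).values
        for _ in range(20):
            r, c = rng.integers(0, 8, size=2)
            bumped = pop.copy()
            bumped[r, c] *= 3.0
            raised = build_hfp(make_stack(grid, popdensity=bumped)).values
            assert raised[r, c] >= base[r, c]

    def test_brute_force_equivalence(self):
        """Cell-by-cell recomputation of the eight scores matches build_hfp."""
        rng = np.random.default_rng(5)
        grid = Grid(rows=20, cols=20)
        lu = rng.integers(0, 4, grid.shape)  # 0 none, 1 built, 2 crop, 3 pasture
        layers = {
            "built": lu == 1,
            "crop": lu == 2,
            "pasture": lu == 3,
            "popdensity": rng.uniform(0, 1500, grid.shape),
            "nightlights": np.where(
                rng.uniform(size=grid.shape) < 0.5,
                rng.uniform(1, 100, grid.shape),
                0.0,
            ),
            "railways": rng.uniform(0, 3, grid.shape),
            "roads": rng.uniform(0, 20, grid.shape),
            "waterways": rng.uniform(0, 20, grid.shape),
        }
        stack = PressureStack(grid=grid, epoch=1993, layers=layers)
        got = build_hfp(stack).values

        lights = layers["nightlights"]
        edges = np.quantile(lights[lights > 0], np.linspace(0.1, 0.9, 9))
        k_road = math.log(16.0) / 14.5
        k_water = math.log(16.0) / 15.0
        for r in range(grid.rows):
            for c in range(grid.cols):
                s = 0.0
                s += 10.0 if layers["built"][r, c] else 0.0
                s += 7.0 if layers["crop"][r, c] else 0.0
                s += 4.0 if layers["pasture"][r, c] else 0.0
                d = layers["popdensity"][r, c]
                s += 10.0 if d > 1000 else min(3.333 * math.log10(d + 1), 10.0)
                v = lights[r, c]
                s += 0.0 if v <= 0 else 1.0 + sum(v > e for e in edges)
                s += 8.0 if layers["railways"][r, c] <= 0.5 else 0.0
                dr = layers["roads"][r, c]
                if dr <= 0.5:
                    s += 8.0
                elif dr <= 15.0:
                    s += 4.0 * math.exp(-k_road * (dr - 0.5))
                dw = layers["waterways"][r, c]
                if dw <= 15.0:
                    s += 4.0 * math.exp(-k_water * dw)
                expected = min(int(math.floor(s + 0.5)), 50)
                assert got[r, c] == expected, (r, c)

    def test_values_are_bounded_integers(self, small_bundle):
        for hfp in (small_bundle.hfp93, small_bundle.hfp09):
            valid = hfp.values[hfp.values != NODATA]
            assert np.issubdtype(hfp.values.dtype, np.integer)
            assert valid.min() >= 0 and valid.max() <= HFP_MAX


class TestHfpChange:
    def test_identical_maps_diagonal_only(self):
        vals = np.array([[1, 2], [3, 4]])
        change = hfp_change(hfp_from_values(vals, 1993), hfp_from_values(vals, 2009))
        assert (change.delta == 0).all()
        off_diag = change.matrix - np.diag(np.diag(change.matrix))
        assert off_diag.sum() == 0

    def test_decrease_clamped_to_no_change(self):
        a = hfp_from_values([[4]], 1993)
        b = hfp_from_values([[2]], 2009)
        change = hfp_change(a, b, clamp_decreases=True)
        assert change.delta[0, 0] == 0
        assert change.matrix[4, 4] == 1
        assert change.matrix[4, 2] == 0

    def test_unclamped_keeps_decrease(self):
        a = hfp_from_values([[4]], 1993)
        b = hfp_from_values([[2]], 2009)
        change = hfp_change(a, b, clamp_decreases=False)
        assert change.delta[0, 0] == -2
        assert change.matrix[4, 2] == 1

    def test_3x3_toy_matches_hand_count(self):
        a = np.array([[0, 1, 2], [3, 4, 5], [0, 0, 1]])
        b = np.array([[0, 2, 2], [1, 6, 5], [3, 0, 0]])
        change = hfp_change(
            hfp_from_values(a, 1993), hfp_from_values(b, 2009), clamp_decreases=False
        )
        expected = np.zeros((51, 51), dtype=int)
        for init, final in zip(a.ravel(), b.ravel()):
            expected[init, final] += 1
        assert (change.matrix == expected).all()
        assert change.matrix.sum() == 9

    def test_clamp_zero_mass_below_diagonal(self):
        rng = np.random.default_rng(3)
        a = hfp_from_values(rng.integers(0, 51, (30, 30)), 1993)
        b = hfp_from_values(rng.integers(0, 51, (30, 30)), 2009)
        change = hfp_change(a, b, clamp_decreases=True)
        assert (np.tril(change.matrix, k=-1) == 0).all()
        assert (change.delta[~np.isnan(change.delta)] >= 0).all()

    def test_matrix_total_counts_valid_cells(self):
        a = np.array([[1, 2], [NODATA, 4]])
        b = np.array([[1, 3], [2, NODATA]])
        change = hfp_change(
            HFPMap(grid=Grid(2, 2), epoch=1993, values=a),
            HFPMap(grid=Grid(2, 2), epoch=2009, values=b),
        )
        assert change.matrix.sum() == 2  # only the two cells valid in both

    def test_grid_and_epoch_mismatch_rejected(self):
        a = hfp_from_values(np.zeros((2, 2), dtype=int), 1993)
        with pytest.raises(GridMismatchError):
            hfp_change(a, hfp_from_values(np.zeros((3, 3), dtype=int), 2009))
        with pytest.raises(GridMismatchError, match="epoch"):
            hfp_change(a, hfp_from_values(np.zeros((2, 2), dtype=int), 1993))


class TestHFPMapInvariants:
    def test_rejects_non_integer(self):
        with pytest.raises(ValueError, match="integer"):
            HFPMap(grid=Grid(1, 1), epoch=1993, values=np.array([[1.5]]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 50\]"):
            HFPMap(grid=Grid(1, 1), epoch=1993, values=np.array([[51]]))

    def test_layer_names_fixed(self):
        assert len(LAYER_NAMES) == 8
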