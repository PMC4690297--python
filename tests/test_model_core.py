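"""Decision-tree probabilities, relative grids, optimum search, CSV export."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coolernudge import (
    DegenerateReferenceError,
    GroupName,
    ModelParams,
    ParameterError,
    PlacementEffects,
    PlacementLocation,
    PreferenceGroup,
    PurchaseGrid,
    ShopperType,
    absolute_grid,
    default_params,
    find_optimal,
    group_purchase_probability,
    location_share,
    purchase_probability,
    relative_grid,
    stratified_relative_grid,
)
from coolernudge.model_core import GridMode

from _oracles import enumerate_tree_probability
from conftest import all_locations


def zero_preference_params():
    """Defaults with every base range collapsed to [0, 0]: nobody buys non-SSBs."""
    base = default_params()
    return ModelParams(
        groups=tuple(PreferenceGroup(g.name, (0.0, 0.0), g.loyalty) for g in base.groups),
        conv_baseline=base.conv_baseline,
        effects=base.effects,
    )


class TestLocationShare:
    def test_convenience_never_reaches_back_coolers(self, params):
        for shelf in range(1, 7):
            assert location_share(
                PlacementLocation(3, shelf), ShopperType.CONVENIENCE, params.effects
            ) == 0.0

    def test_convenience_uses_vertical_share_at_front_cooler(self, params):
        got = location_share(
            PlacementLocation(1, 6), ShopperType.CONVENIENCE, params.effects
        )
        assert got == pytest.approx(0.155, abs=1e-12)

    def test_browser_multiplies_axes(self, params):
        got = location_share(PlacementLocation(1, 2), ShopperType.BROWSER, params.effects)
        assert got == pytest.approx(0.179 * 0.172, rel=1e-12)

    def test_out_of_range_location_rejected(self, params):
        with pytest.raises(ParameterError):
            location_share(PlacementLocation(7, 1), ShopperType.BROWSER, params.effects)
        with pytest.raises(ParameterError):
            location_share(PlacementLocation(1, 7), ShopperType.CONVENIENCE, params.effects)


class TestPurchaseProbability:
    def test_always_group_never_buys(self, params):
        g = params.group(GroupName.ALWAYS_SSB)
        for loc in all_locations(params):
            assert group_purchase_probability(g, loc, params) == 0.0

    def test_group_value_assembles_all_factors(self, params):
        # rarely/never at the worst slot: base 0.772, conv 0.326*0.27, browser path only
        got = group_purchase_probability(
            params.group(GroupName.RARELY_NEVER_SSB), PlacementLocation(6, 6), params
        )
        conv = 0.326 * 0.27
        expected = 0.772 * (1 - conv) * 0.154 * 0.155
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_tree_enumeration_everywhere(self, params):
        for loc in all_locations(params):
            assert purchase_probability(loc, params) == pytest.approx(
                enumerate_tree_probability(loc, params), abs=1e-12
            )

    def test_frozen_key_cells(self, params):
        # values computed once from the tree-enumeration oracle and frozen
        assert purchase_probability(PlacementLocation(6, 6), params) == pytest.approx(
            0.0065087675268, rel=1e-10
        )
        assert purchase_probability(PlacementLocation(1, 2), params) == pytest.approx(
            0.01862042752432, rel=1e-10
        )

    def test_zero_preference_population_never_buys(self):
        p = zero_preference_params()
        assert all(purchase_probability(loc, p) == 0.0 for loc in all_locations(p))

    @given(
        conv=st.floats(0, 1, allow_nan=False),
        raw_h=st.lists(st.floats(5, 30), min_size=6, max_size=6),
        raw_v=st.lists(st.floats(5, 30), min_size=6, max_size=6),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_closed_form_equals_enumeration_for_arbitrary_params(self, conv, raw_h, raw_v):
        base = default_params()
        h = tuple(x * 100.0 / sum(raw_h) for x in raw_h)
        v = tuple(x * 100.0 / sum(raw_v) for x in raw_v)
        p = ModelParams(
            groups=base.groups,
            conv_baseline=conv,
            effects=PlacementEffects(horizontal=h, vertical=v),
        )
        for loc in (PlacementLocation(1, 2), PlacementLocation(4, 5), PlacementLocation(6, 6)):
            assert purchase_probability(loc, p) == pytest.approx(
                enumerate_tree_probability(loc, p), abs=1e-12
            )


class TestRelativeGrid:
    def test_reference_cell_exactly_one(self, params, worst):
        assert relative_grid(params, worst).at(worst) == 1.0

    @pytest.mark.parametrize(
        "loc, expected",
        [
            ((1, 2), 2.8608223365867596),  # optimal vs worst; published figure 2.8
            ((1, 6), 2.5780666405287658),  # front-cooler bottom shelf; published 2.5
            ((2, 2), 1.253791369920402),  # second-best; published 1.3
        ],
    )
    def test_frozen_ratios(self, params, worst, loc, expected):
        grid = relative_grid(params, worst)
        assert grid.at(PlacementLocation(*loc)) == pytest.approx(expected, rel=1e-9)

    def test_front_cooler_dominates_all_others(self, params, worst):
        vals = relative_grid(params, worst).values
        assert vals[0].min() > vals[1:].max()

    def test_degenerate_reference_raises(self, worst):
        with pytest.raises(DegenerateReferenceError):
            relative_grid(zero_preference_params(), worst)

    def test_browsers_only_grid_is_separable(self, params, worst):
        p = params.with_conv_baseline(0.0)
        grid = relative_grid(p, worst)
        h, v = p.effects.horizontal, p.effects.vertical
        for loc in all_locations(p):
            expected = (h[loc.cooler - 1] * v[loc.shelf - 1]) / (h[5] * v[5])
            assert grid.at(loc) == pytest.approx(expected, rel=1e-12)

    def test_uniform_shares_and_no_convenience_flatten_grid(self, worst):
        base = default_params()
        flat = ModelParams(
            groups=base.groups,
            conv_baseline=0.0,
            effects=PlacementEffects(horizontal=(100 / 6.0,) * 6, vertical=(100 / 6.0,) * 6),
        )
        assert np.allclose(relative_grid(flat, worst).values, 1.0, atol=1e-12)

    @pytest.mark.parametrize("shelf", range(1, 7))
    def test_contrast_strictly_increases_with_convenience(self, params, worst, shelf):
        ratios = [
            relative_grid(params.with_conv_baseline(c), worst).at(PlacementLocation(1, shelf))
            for c in (0.1, 0.326, 0.652)
        ]
        assert ratios[0] < ratios[1] < ratios[2]


class TestStratifiedGrid:
    def test_sometimes_stratum_shows_strongest_effect(self, params, worst, optimal):
        grid = stratified_relative_grid(params.group(GroupName.SOMETIMES_SSB), params, worst)
        assert grid.at(optimal) == pytest.approx(4.775068216936696, rel=1e-9)

    def test_always_stratum_flagged_no_effect(self, params, worst):
        grid = stratified_relative_grid(params.group(GroupName.ALWAYS_SSB), params, worst)
        assert grid.no_effect
        assert np.all(grid.values == 1.0)

    def test_reference_self_ratio(self, params, worst):
        grid = stratified_relative_grid(
            params.group(GroupName.RARELY_NEVER_SSB), params, worst
        )
        assert grid.at(worst) == 1.0
        assert not grid.no_effect

    def test_base_preference_cancels_from_ratios(self, params, worst):
        # usually and sometimes differ only in base level and loyalty; a group's
        # ratio grid must not depend on its base range at all
        g = params.group(GroupName.SOMETIMES_SSB)
        shifted = PreferenceGroup(g.name, (29.0, 40.0), g.loyalty)
        groups = tuple(shifted if x.name is g.name else x for x in params.groups)
        p2 = ModelParams(groups=groups, conv_baseline=params.conv_baseline,
                         effects=params.effects)
        a = stratified_relative_grid(g, params, worst).values
        b = stratified_relative_grid(p2.group(g.name), p2, worst).values
        assert np.allclose(a, b, rtol=1e-12)


class TestFindOptimal:
    def test_front_cooler_eye_level_jointly_optimal(self, params, worst):
        got = find_optimal(relative_grid(params, worst))
        assert got == [PlacementLocation(1, 2), PlacementLocation(1, 3)]

    def test_zero_tolerance_gives_strict_argmax(self, params, worst):
        got = find_optimal(relative_grid(params, worst), tie_tolerance=0.0)
        assert got == [PlacementLocation(1, 2)]

    def test_flat_grid_ties_everywhere(self):
        grid = PurchaseGrid(np.full((6, 6), 0.5), GridMode.ABSOLUTE)
        assert len(find_optimal(grid)) == 36

    def test_negative_tolerance_rejected(self, params, worst):
        with pytest.raises(ValueError):
            find_optimal(relative_grid(params, worst), tie_tolerance=-0.1)


class TestGridContainer:
    def test_relative_mode_requires_exact_reference(self, worst):
        vals = np.ones((6, 6))
        vals[5, 5] = 1.0001
        with pytest.raises(ValueError, match="reference"):
            PurchaseGrid(vals, GridMode.RELATIVE, worst)

    def test_absolute_mode_rejects_non_probabilities(self):
        with pytest.raises(ValueError):
            PurchaseGrid(np.full((6, 6), 1.5), GridMode.ABSOLUTE)

    def test_csv_layout_and_precision(self, params, worst):
        buf = io.StringIO()
        relative_grid(params, worst).to_csv(buf)
        buf.seek(0)
        df = pd.read_csv(buf, index_col=0)
        assert list(df.index) == [f"cooler_{i}" for i in range(1, 7)]
        assert list(df.columns) == [f"shelf_{j}" for j in range(1, 7)]
        assert df.loc["cooler_1", "shelf_2"] == 2.8608  # 4 decimal places
        assert df.loc["cooler_6", "shelf_6"] == 1.0
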