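"""Exact (expectation) purchase probabilities over the cooler x shelf grid.

The model is a decision tree. A shopper belongs to one of four preference
groups (equal weight). Within a group with convenience probability
``conv_g`` and base non-SSB purchase probability ``base_g``, the chance of
buying the non-SSB placed at location (c, s) is::

    P_g(c, s) = base_g * [ conv_g    * share_conv(c, s)
                         + (1-conv_g) * share_browse(c, s) ]

where convenience shoppers only stand at cooler 1 and pick a shelf by the
vertical share, ``share_conv(c, s) = v(s)/100`` if ``c == 1`` else 0, and
browsers weigh both axes, ``share_browse(c, s) = h(c)/100 * v(s)/100``.
Shares are used as printed (each axis sums to 99.9, not 100); the shortfall
is a no-purchase path and cancels from every ratio.

The population probability is the equal-weight mean over groups, and grids
are reported either absolute or relative to a reference cell — by
convention the worst slot, bottom shelf of the cooler farthest from the
entrance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO, Union

import numpy as np
import pandas as pd

from .parameters import (
    BaseRule,
    ModelParams,
    ParameterError,
    PlacementEffects,
    PlacementLocation,
    PreferenceGroup,
    base_preference,
    convenience_probability,
)

__all__ = [
    "ShopperType",
    "GridMode",
    "PurchaseGrid",
    "DegenerateReferenceError",
    "WORST_LOCATION",
    "location_share",
    "group_purchase_probability",
    "purchase_probability",
    "absolute_grid",
    "relative_grid",
    "stratified_relative_grid",
    "find_optimal",
]

#: The normalization reference for relative grids: cooler 6, shelf 6.
WORST_LOCATION = PlacementLocation(6, 6)


class ShopperType(str, enum.Enum):
    CONVENIENCE = "convenience"
    BROWSER = "browser"


class GridMode(str, enum.Enum):
    ABSOLUTE = "absolute"
    RELATIVE = "relative"


class DegenerateReferenceError(ValueError):
    """The reference cell has zero purchase probability; ratios are undefined."""


@dataclass(frozen=True)
class PurchaseGrid:
    """A cooler x shelf matrix of purchase probabilities or ratios.

    ``values[c-1, s-1]`` is the probability (absolute mode) or the ratio to
    the reference cell (relative mode) for cooler ``c``, shelf ``s``.
    ``no_effect`` flags a stratified grid for a stratum placement cannot
    influence (every cell reported as 1.0).
    """

    values: np.ndarray
    mode: GridMode
    reference: PlacementLocation | None = None
    no_effect: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.size == 0:
            raise ValueError("grid values must be a non-empty 2-D matrix")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mode", GridMode(self.mode))
        if self.mode is GridMode.ABSOLUTE and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("absolute-mode cells must be probabilities in [0, 1]")
        if self.mode is GridMode.RELATIVE:
            if self.reference is None:
                raise ValueError("relative-mode grid requires a reference location")
            ref = vals[self.reference.cooler - 1, self.reference.shelf - 1]
            if ref != 1.0:
                raise ValueError(f"reference cell must be exactly 1.0, got {ref!r}")

    @property
    def n_coolers(self) -> int:
        return self.values.shape[0]

    @property
    def n_shelves(self) -> int:
        return self.values.shape[1]

    def at(self, loc: PlacementLocation) -> float:
        """Value at a 1-based (cooler, shelf) location."""
        if not (1 <= loc.cooler <= self.n_coolers and 1 <= loc.shelf <= self.n_shelves):
            raise ParameterError(f"location {loc} outside grid")
        return float(self.values[loc.cooler - 1, loc.shelf - 1])

    def to_dataframe(self) -> pd.DataFrame:
        """Grid as a DataFrame: rows cooler_1..n (1 = entrance), columns shelf_1..n (1 = top)."""
        return pd.DataFrame(
            self.values,
            index=[f"cooler_{i}" for i in range(1, self.n_coolers + 1)],
            columns=[f"shelf_{j}" for j in range(1, self.n_shelves + 1)],
        )

    def to_csv(self, target: Union[str, Path, TextIO]) -> None:
        """Write the grid as CSV with 4-decimal cells."""
        self.to_dataframe().to_csv(target, float_format="%.4f", index_label="")


def location_share(
    loc: PlacementLocation, shopper: ShopperType, effects: PlacementEffects
) -> float:
    """Probability that a shopper of the given type picks the slot ``loc``.

    Convenience shoppers never leave cooler 1; browsers combine the
    horizontal and vertical shares multiplicatively.
    """
    shopper = ShopperType(shopper)
    n_c, n_s = len(effects.horizontal), len(effects.vertical)
    if loc.cooler > n_c or loc.shelf > n_s:
        raise ParameterError(f"location {loc} outside the {n_c}x{n_s} layout")
    v = effects.vertical[loc.shelf - 1] / 100.0
    if shopper is ShopperType.CONVENIENCE:
        return v if loc.cooler == 1 else 0.0
    h = effects.horizontal[loc.cooler - 1] / 100.0
    return h * v


def group_purchase_probability(
    group: PreferenceGroup, loc: PlacementLocation, params: ModelParams
) -> float:
    """Probability a member of ``group`` buys the non-SSB placed at ``loc``.

    Expectation over shopper type of the slot-selection share, gated by the
    group's base preference (midpoint rule, so the value is deterministic).
    """
    params.validate_location(loc)
    base = base_preference(group, BaseRule.MIDPOINT)
    conv = convenience_probability(group, params)
    s_conv = location_share(loc, ShopperType.CONVENIENCE, params.effects)
    s_brow = location_share(loc, ShopperType.BROWSER, params.effects)
    return base * (conv * s_conv + (1.0 - conv) * s_brow)


def purchase_probability(loc: PlacementLocation, params: ModelParams) -> float:
    """Population purchase probability at ``loc``: equal-weight mean over groups."""
    w = params.group_weight
    return sum(w * group_purchase_probability(g, loc, params) for g in params.groups)


def _grid_values(params: ModelParams, group: PreferenceGroup | None) -> np.ndarray:
    vals = np.empty((params.n_coolers, params.n_shelves))
    for c in range(1, params.n_coolers + 1):
        for s in range(1, params.n_shelves + 1):
            loc = PlacementLocation(c, s)
            if group is None:
                vals[c - 1, s - 1] = purchase_probability(loc, params)
            else:
                vals[c - 1, s - 1] = group_purchase_probability(group, loc, params)
    return vals


def absolute_grid(params: ModelParams, group: PreferenceGroup | None = None) -> PurchaseGrid:
    """Absolute purchase-probability grid, population-level or for one stratum."""
    return PurchaseGrid(_grid_values(params, group), GridMode.ABSOLUTE)


def _to_relative(vals: np.ndarray, reference: PlacementLocation) -> np.ndarray:
    ref = vals[reference.cooler - 1, reference.shelf - 1]
    out = vals / ref
    out[reference.cooler - 1, reference.shelf - 1] = 1.0  # exact, not merely approximate
    return out


def relative_grid(
    params: ModelParams, reference: PlacementLocation = WORST_LOCATION
) -> PurchaseGrid:
    """Grid of purchase-probability ratios to the reference (worst) location."""
    params.validate_location(reference)
    vals = _grid_values(params, None)
    if vals[reference.cooler - 1, reference.shelf - 1] == 0.0:
        raise DegenerateReferenceError(
            f"purchase probability at reference {reference} is zero"
        )
    return PurchaseGrid(_to_relative(vals, reference), GridMode.RELATIVE, reference)


def stratified_relative_grid(
    group: PreferenceGroup,
    params: ModelParams,
    reference: PlacementLocation = WORST_LOCATION,
) -> PurchaseGrid:
    """Relative grid for a single preference stratum.

    A stratum that never buys a non-SSB anywhere (always-SSB drinkers) has no
    placement effect; rather than a 0/0 error, every cell is reported as 1.0
    with the ``no_effect`` flag set.
    """
    params.validate_location(reference)
    vals = _grid_values(params, group)
    if np.all(vals == 0.0):
        return PurchaseGrid(
            np.ones_like(vals), GridMode.RELATIVE, reference, no_effect=True
        )
    if vals[reference.cooler - 1, reference.shelf - 1] == 0.0:
        raise DegenerateReferenceError(
            f"stratum probability at reference {reference} is zero"
        )
    return PurchaseGrid(_to_relative(vals, reference), GridMode.RELATIVE, reference)


def find_optimal(grid: PurchaseGrid, tie_tolerance: float = 0.01) -> list[PlacementLocation]:
    """Locations within ``tie_tolerance`` (relative) of the grid maximum.

    The default 1% tolerance reports near-eye-level shelves of the front
    cooler jointly optimal, matching their sub-percent analytic separation.
    Results are in row-major order (by cooler, then shelf).
    """
    if tie_tolerance < 0:
        raise ValueError("tie_tolerance must be non-negative")
    best = float(grid.values.max())
    cutoff = best * (1.0 - tie_tolerance)
    return [
        PlacementLocation(c + 1, s + 1)
        for c in range(grid.n_coolers)
        for s in range(grid.n_shelves)
        if grid.values[c, s] >= cutoff
    ]
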