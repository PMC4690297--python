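"""Model parameters: preference groups, placement effects, and config I/O.

The model describes adolescents buying beverages in a corner store with a
bank of six coolers, each holding six shelves. Every parameter here is a
published point value or quartile range:

* Four *beverage preference groups* partition shoppers by the proportion of
  non-sugar-sweetened beverages (non-SSBs) among their purchases — from
  "always SSB" drinkers (who never buy a non-SSB) to "rarely/never SSB"
  drinkers. Each group carries a quartile range of non-SSB purchase
  probability and a brand-loyalty weight.
* A *baseline convenience-shopper probability* (0.326): the chance a shopper
  only visits the cooler nearest the entrance rather than browsing all six.
  The effective per-group probability is baseline x loyalty.
* *Placement effects*: per-cooler ("horizontal") and per-shelf ("vertical")
  selection shares in percent, decreasing with distance from the entrance
  and peaking near eye level respectively.

All probabilities are stored as proportions in [0, 1]; shares are kept in
percent as published. Parameters round-trip through a YAML config file.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TextIO, Union

import numpy as np
import yaml

__all__ = [
    "GroupName",
    "BaseRule",
    "PreferenceGroup",
    "PlacementEffects",
    "PlacementLocation",
    "ModelParams",
    "ParameterError",
    "ConfigError",
    "default_params",
    "base_preference",
    "convenience_probability",
    "load_params",
    "loads_params",
    "save_params",
    "dumps_params",
]


class ParameterError(ValueError):
    """A parameter value violates a model invariant."""


class ConfigError(ValueError):
    """A config document could not be parsed or has the wrong shape."""


class GroupName(str, enum.Enum):
    """The four SSB-preference quartile groups."""

    ALWAYS_SSB = "always_ssb"
    USUALLY_SSB = "usually_ssb"
    SOMETIMES_SSB = "sometimes_ssb"
    RARELY_NEVER_SSB = "rarely_never_ssb"


class BaseRule(str, enum.Enum):
    """How a point purchase probability is taken from a group's quartile range.

    ``midpoint`` uses the range midpoint (the expectation of a uniform draw,
    so analytic results coincide with the mean of the stochastic mode);
    ``uniform_draw`` samples uniformly within the range per individual.
    """

    MIDPOINT = "midpoint"
    UNIFORM_DRAW = "uniform_draw"


@dataclass(frozen=True)
class PreferenceGroup:
    """One SSB-preference segment.

    Parameters
    ----------
    name
        Which quartile group this is.
    base_range
        Closed interval ``(lo, hi)`` of non-SSB purchase probability, in
        percent of purchases (0-100).
    loyalty
        Brand-loyalty weight in [0, 1]; multiplies the baseline
        convenience-shopper probability for this group.
    """

    name: GroupName
    base_range: tuple[float, float]
    loyalty: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", GroupName(self.name))
        lo, hi = self.base_range
        object.__setattr__(self, "base_range", (float(lo), float(hi)))
        if not (0.0 <= lo <= hi <= 100.0):
            raise ParameterError(
                f"base_range must satisfy 0 <= lo <= hi <= 100, got ({lo}, {hi})"
            )
        if not (0.0 <= self.loyalty <= 1.0):
            raise ParameterError(f"loyalty must lie in [0, 1], got {self.loyalty}")

    @property
    def midpoint(self) -> float:
        """Range midpoint as a proportion in [0, 1]."""
        lo, hi = self.base_range
        return (lo + hi) / 2.0 / 100.0


@dataclass(frozen=True)
class PlacementEffects:
    """Per-cooler (horizontal) and per-shelf (vertical) selection shares.

    Shares are percentages as published; index 0 is the cooler nearest the
    entrance / the top shelf. Each list must sum to approximately 100 (the
    published defaults sum to 99.9); shares are used as printed, never
    renormalized.
    """

    horizontal: tuple[float, ...]
    vertical: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "horizontal", tuple(float(x) for x in self.horizontal))
        object.__setattr__(self, "vertical", tuple(float(x) for x in self.vertical))
        for label, shares in (("horizontal", self.horizontal), ("vertical", self.vertical)):
            if not shares:
                raise ParameterError(f"{label} share list is empty")
            if any(not (0.0 < s < 100.0) for s in shares):
                raise ParameterError(f"every {label} share must lie in (0, 100): {shares}")
            total = sum(shares)
            if not (99.0 <= total <= 101.0):
                raise ParameterError(
                    f"{label} shares must sum to ~100 (99.0-101.0), got {total:.4g}"
                )


@dataclass(frozen=True)
class PlacementLocation:
    """A (cooler, shelf) slot; cooler 1 is nearest the entrance, shelf 1 the top."""

    cooler: int
    shelf: int

    def __post_init__(self) -> None:
        if self.cooler < 1 or self.shelf < 1:
            raise ParameterError(
                f"cooler and shelf indices are 1-based, got ({self.cooler}, {self.shelf})"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"(cooler {self.cooler}, shelf {self.shelf})"


#: Order in which the four groups are stored and reported.
GROUP_ORDER: tuple[GroupName, ...] = (
    GroupName.ALWAYS_SSB,
    GroupName.USUALLY_SSB,
    GroupName.SOMETIMES_SSB,
    GroupName.RARELY_NEVER_SSB,
)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter bundle for the placement model.

    The four groups carry equal population weight (they are quartiles of the
    underlying sample). Layout dimensions are implied by the share lists.
    """

    groups: tuple[PreferenceGroup, ...]
    conv_baseline: float
    effects: PlacementEffects
    base_rule: BaseRule = BaseRule.MIDPOINT

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "base_rule", BaseRule(self.base_rule))
        if len(self.groups) != 4:
            raise ParameterError(f"expected 4 preference groups, got {len(self.groups)}")
        names = [g.name for g in self.groups]
        if set(names) != set(GROUP_ORDER):
            raise ParameterError(f"groups must cover each quartile exactly once, got {names}")
        if not (0.0 <= self.conv_baseline <= 1.0):
            raise ParameterError(
                f"conv_baseline must lie in [0, 1], got {self.conv_baseline}"
            )
        # Quartile intervals may touch at a boundary (and a degenerate point
        # interval may sit inside another), but two non-degenerate ranges must
        # not overlap in their interiors.
        spans = sorted(
            (g.base_range for g in self.groups if g.base_range[0] < g.base_range[1])
        )
        for (lo_a, hi_a), (lo_b, _) in zip(spans, spans[1:]):
            if lo_b < hi_a:
                raise ParameterError(
                    f"preference ranges overlap: ({lo_a}, {hi_a}) and lo {lo_b}"
                )

    @property
    def n_coolers(self) -> int:
        return len(self.effects.horizontal)

    @property
    def n_shelves(self) -> int:
        return len(self.effects.vertical)

    @property
    def group_weight(self) -> float:
        """Population weight per group (quartiles: 1/4 each)."""
        return 1.0 / len(self.groups)

    def group(self, name: GroupName | str) -> PreferenceGroup:
        name = GroupName(name)
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)  # pragma: no cover - unreachable after validation

    def validate_location(self, loc: PlacementLocation) -> None:
        if loc.cooler > self.n_coolers or loc.shelf > self.n_shelves:
            raise ParameterError(
                f"location {loc} outside the {self.n_coolers}x{self.n_shelves} layout"
            )

    def with_conv_baseline(self, value: float) -> "ModelParams":
        return replace(self, conv_baseline=value)


def default_params() -> ModelParams:
    """Published default parameter bundle.

    Base preference ranges are quartiles of the proportion of non-SSB
    beverages purchased; the "always SSB" group never buys a non-SSB and the
    open-ended top quartile (>54.4) is closed at 100 (a proportion of
    purchases cannot exceed 100%). Loyalty percentages are stored as
    proportions.
    """
    groups = (
        PreferenceGroup(GroupName.ALWAYS_SSB, (0.0, 0.0), 0.27),
        PreferenceGroup(GroupName.USUALLY_SSB, (0.0, 28.4), 0.75),
        PreferenceGroup(GroupName.SOMETIMES_SSB, (28.5, 54.4), 1.00),
        PreferenceGroup(GroupName.RARELY_NEVER_SSB, (54.4, 100.0), 0.27),
    )
    effects = PlacementEffects(
        horizontal=(17.9, 17.4, 16.9, 16.4, 15.9, 15.4),
        vertical=(17.0, 17.2, 17.1, 16.8, 16.3, 15.5),
    )
    return ModelParams(groups=groups, conv_baseline=0.326, effects=effects)


def base_preference(
    group: PreferenceGroup,
    rule: BaseRule = BaseRule.MIDPOINT,
    rng: np.random.Generator | None = None,
) -> float:
    """Point probability of purchasing a non-SSB for one group, as a proportion.

    With ``midpoint`` this is deterministic; with ``uniform_draw`` a value is
    sampled uniformly within the group's range and ``rng`` is required.
    A degenerate range (always-SSB drinkers) returns exactly its point value
    under either rule.
    """
    rule = BaseRule(rule)
    lo, hi = group.base_range
    if rule is BaseRule.MIDPOINT or lo == hi:
        return group.midpoint
    if rng is None:
        raise ValueError("uniform_draw requires a random generator")
    return float(rng.uniform(lo, hi)) / 100.0


def convenience_probability(group: PreferenceGroup, params: ModelParams) -> float:
    """Probability a member of ``group`` is a convenience shopper.

    Product of the baseline convenience-shopper probability and the group's
    brand-loyalty weight, clipped to [0, 1] (the clip guards user overrides;
    defaults never reach it).
    """
    return min(1.0, params.conv_baseline * group.loyalty)


# ---------------------------------------------------------------------------
# Config I/O (YAML)
# ---------------------------------------------------------------------------

def _params_to_dict(params: ModelParams) -> dict:
    return {
        "conv_baseline": params.conv_baseline,
        "base_rule": params.base_rule.value,
        "n_coolers": params.n_coolers,
        "n_shelves": params.n_shelves,
        "effects": {
            "horizontal": list(params.effects.horizontal),
            "vertical": list(params.effects.vertical),
        },
        "groups": {
            g.name.value: {"base_range": list(g.base_range), "loyalty": g.loyalty}
            for g in params.groups
        },
    }


def _params_from_dict(doc: dict) -> ModelParams:
    defaults = default_params()
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    unknown = set(doc) - {
        "conv_baseline", "base_rule", "effects", "groups", "n_coolers", "n_shelves",
    }
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    conv = doc.get("conv_baseline", defaults.conv_baseline)
    try:
        rule = BaseRule(doc.get("base_rule", defaults.base_rule))
    except ValueError as exc:
        raise ConfigError(str(exc)) from None

    eff_doc = doc.get("effects", {}) or {}
    if not isinstance(eff_doc, dict):
        raise ConfigError("'effects' must be a mapping with horizontal/vertical lists")
    try:
        effects = PlacementEffects(
            horizontal=tuple(eff_doc.get("horizontal", defaults.effects.horizontal)),
            vertical=tuple(eff_doc.get("vertical", defaults.effects.vertical)),
        )
    except TypeError as exc:
        raise ConfigError(f"bad effects lists: {exc}") from None
    n_coolers = doc.get("n_coolers", len(defaults.effects.horizontal))
    n_shelves = doc.get("n_shelves", len(defaults.effects.vertical))
    if len(effects.horizontal) != n_coolers:
        raise ParameterError(
            f"expected {n_coolers} horizontal shares, got {len(effects.horizontal)}"
        )
    if len(effects.vertical) != n_shelves:
        raise ParameterError(
            f"expected {n_shelves} vertical shares, got {len(effects.vertical)}"
        )

    grp_doc = doc.get("groups", {}) or {}
    if not isinstance(grp_doc, dict):
        raise ConfigError("'groups' must be a mapping keyed by group name")
    groups = []
    for g in defaults.groups:
        override = grp_doc.get(g.name.value, {})
        if not isinstance(override, dict):
            raise ConfigError(f"group '{g.name.value}' must be a mapping")
        groups.append(
            PreferenceGroup(
                name=g.name,
                base_range=tuple(override.get("base_range", g.base_range)),
                loyalty=override.get("loyalty", g.loyalty),
            )
        )
    bad = set(grp_doc) - {g.name.value for g in defaults.groups}
    if bad:
        raise ConfigError(f"unknown group names: {sorted(bad)}")

    return ModelParams(
        groups=tuple(groups), conv_baseline=conv, effects=effects, base_rule=rule
    )


def loads_params(text: str) -> ModelParams:
    """Parse a YAML config document; omitted keys fall back to defaults."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config: {exc}") from None
    if doc is None:
        return default_params()
    return _params_from_dict(doc)


def load_params(source: Union[str, Path, TextIO]) -> ModelParams:
    """Read a YAML config from a path or open text stream."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return loads_params(fh.read())
    return loads_params(source.read())


def dumps_params(params: ModelParams) -> str:
    """Serialize parameters to canonical YAML (bit-stable round trip)."""
    return yaml.safe_dump(_params_to_dict(params), sort_keys=True, default_flow_style=None)


def save_params(params: ModelParams, target: Union[str, Path, TextIO]) -> None:
    """Write parameters as YAML to a path or open text stream."""
    text = dumps_params(params)
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        target.write(text)
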