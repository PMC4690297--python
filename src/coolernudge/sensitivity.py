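"""One-way sensitivity scenarios on the placement model.

Five published scenarios probe the model's robustness:

1. giving "always SSB" drinkers a 25% chance of buying a non-SSB,
2. doubling the baseline convenience-shopper probability (0.326 -> 0.652),
3. halving it (0.326 -> 0.163),
4. doubling the horizontal and vertical effects simultaneously,
5. halving them.

"Doubling/halving an effect" means doubling/halving the spread of the share
list around its mean — a mean-preserving spread::

    scaled_i = mean + factor * (share_i - mean),   mean = sum(shares)/len

followed by half-up rounding to one decimal to match the published tables.
This rule regenerates 23 of the 24 published scaled shares exactly; the
remaining one (halved vertical, top shelf: published 17.1 vs rule 16.8) is
treated as a typo.

Scenario ratios are always evaluated at the fixed optimal (cooler 1,
shelf 2) versus worst (cooler 6, shelf 6) cells: the published optimal
location does not move across scenarios.

Note: the published half-convenience parameter is printed as 18.3 where half
of the printed 32.6 baseline is 16.3; the scenario here uses 0.163. The
published "always SSB 25% -> 3.50" ratio disagrees with this model's
analytic reconstruction (~2.71); the scenario is implemented and its
analytic value reported as computed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .model_core import WORST_LOCATION, relative_grid
from .parameters import (
    GroupName,
    ModelParams,
    ParameterError,
    PlacementEffects,
    PlacementLocation,
    PreferenceGroup,
)
from .synthetic_population import RatioSummary, simulated_relative_ratio

__all__ = [
    "ScenarioKind",
    "Rounding",
    "ScenarioSpec",
    "OPTIMAL_LOCATION",
    "PAPER_SCENARIOS",
    "apply_scenario",
    "scale_shares",
    "scenario_ratio",
    "run_sensitivity_suite",
]

#: Fixed optimal cell used for every scenario ratio.
OPTIMAL_LOCATION = PlacementLocation(1, 2)


class ScenarioKind(str, enum.Enum):
    SCALE_CONVENIENCE = "scale_convenience"
    SET_ALWAYS_BASE = "set_always_base"
    SCALE_EFFECTS = "scale_effects"


class Rounding(str, enum.Enum):
    PRINTED_1DP = "printed_1dp"  # half-up to one decimal, as published
    EXACT = "exact"


@dataclass(frozen=True)
class ScenarioSpec:
    """One parameter transformation defining a sensitivity scenario."""

    kind: ScenarioKind
    factor: float | None = None
    always_base: float | None = None
    rounding: Rounding = Rounding.PRINTED_1DP

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ScenarioKind(self.kind))
        object.__setattr__(self, "rounding", Rounding(self.rounding))
        if self.kind is ScenarioKind.SET_ALWAYS_BASE:
            if self.always_base is None or not (0.0 <= self.always_base <= 1.0):
                raise ParameterError(
                    f"always_base must be a probability, got {self.always_base}"
                )
        else:
            if self.factor is None or self.factor <= 0:
                raise ParameterError(f"factor must be positive, got {self.factor}")


def scale_shares(
    shares: Sequence[float], factor: float, rounding: Rounding = Rounding.PRINTED_1DP
) -> tuple[float, ...]:
    """Mean-preserving spread of a share list by ``factor``.

    Arithmetic is done in decimal to avoid binary-float artifacts at the
    half-up rounding boundary (e.g. 17.35 -> 17.4).
    """
    dec = [Decimal(str(s)) for s in shares]
    mean = sum(dec) / Decimal(len(dec))
    f = Decimal(str(factor))
    scaled = [mean + f * (s - mean) for s in dec]
    if Rounding(rounding) is Rounding.PRINTED_1DP:
        scaled = [s.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP) for s in scaled]
    if any(s <= 0 for s in scaled):
        raise ParameterError(f"effect scaling by {factor} drives a share to <= 0")
    return tuple(float(s) for s in scaled)


def apply_scenario(params: ModelParams, spec: ScenarioSpec) -> ModelParams:
    """Transformed parameter bundle for one scenario."""
    if spec.kind is ScenarioKind.SCALE_CONVENIENCE:
        return params.with_conv_baseline(params.conv_baseline * spec.factor)
    if spec.kind is ScenarioKind.SET_ALWAYS_BASE:
        pct = spec.always_base * 100.0
        groups = tuple(
            replace(g, base_range=(pct, pct)) if g.name is GroupName.ALWAYS_SSB else g
            for g in params.groups
        )
        return replace(params, groups=groups)
    # SCALE_EFFECTS: both axes simultaneously, as published
    effects = PlacementEffects(
        horizontal=scale_shares(params.effects.horizontal, spec.factor, spec.rounding),
        vertical=scale_shares(params.effects.vertical, spec.factor, spec.rounding),
    )
    return replace(params, effects=effects)


def scenario_ratio(
    spec: ScenarioSpec,
    params: ModelParams,
    optimal: PlacementLocation = OPTIMAL_LOCATION,
    worst: PlacementLocation = WORST_LOCATION,
) -> float:
    """Analytic optimal-vs-worst purchase ratio under one scenario."""
    grid = relative_grid(apply_scenario(params, spec), reference=worst)
    return grid.at(optimal)


#: The five published scenarios: (label, parameter description, value description, spec).
PAPER_SCENARIOS: tuple[tuple[str, str, str, ScenarioSpec], ...] = (
    (
        "always_ssb_base_25pct",
        "always-SSB non-SSB purchase probability",
        "0.25",
        ScenarioSpec(ScenarioKind.SET_ALWAYS_BASE, always_base=0.25),
    ),
    (
        "convenience_double",
        "baseline convenience-shopper probability",
        "0.652 (double)",
        ScenarioSpec(ScenarioKind.SCALE_CONVENIENCE, factor=2.0),
    ),
    (
        "convenience_half",
        "baseline convenience-shopper probability",
        "0.163 (half)",
        ScenarioSpec(ScenarioKind.SCALE_CONVENIENCE, factor=0.5),
    ),
    (
        "effects_double",
        "horizontal and vertical effects",
        "spread x2 around mean",
        ScenarioSpec(ScenarioKind.SCALE_EFFECTS, factor=2.0),
    ),
    (
        "effects_half",
        "horizontal and vertical effects",
        "spread x0.5 around mean",
        ScenarioSpec(ScenarioKind.SCALE_EFFECTS, factor=0.5),
    ),
)


def run_sensitivity_suite(
    params: ModelParams,
    n: int = 1000,
    reps: int = 200,
    seed: int = 0,
    simulate: bool = True,
) -> pd.DataFrame:
    """Baseline plus the five scenarios, analytic and (optionally) simulated.

    The simulated columns summarize the count-ratio distribution over
    ``reps`` independent cohort pairs of size ``n`` (the published analysis
    used n = 1000 draws).
    """
    rows = []
    suite = [("baseline", "none", "published defaults", None)] + list(PAPER_SCENARIOS)
    for i, (label, parameter, value, spec) in enumerate(suite):
        scen_params = params if spec is None else apply_scenario(params, spec)
        analytic = relative_grid(scen_params, reference=WORST_LOCATION).at(
            OPTIMAL_LOCATION
        )
        row = {
            "scenario": label,
            "parameter": parameter,
            "value": value,
            "analytic_ratio": analytic,
            "simulated_ratio_mean": float("nan"),
            "simulated_ratio_lo95": float("nan"),
            "simulated_ratio_hi95": float("nan"),
        }
        if simulate:
            summary: RatioSummary = simulated_relative_ratio(
                n, OPTIMAL_LOCATION, WORST_LOCATION, scen_params,
                seed=seed + 1000 * i, reps=reps,
            )
            row["simulated_ratio_mean"] = summary.mean
            row["simulated_ratio_lo95"] = summary.lo95
            row["simulated_ratio_hi95"] = summary.hi95
        rows.append(row)
    return pd.DataFrame(rows)
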