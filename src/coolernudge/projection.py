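"""City-level projection of additional non-SSB purchases.

Extrapolates a per-visit purchase-probability difference between two
placements to an annual count over a population:

    additional = population x visits_per_year x [P(to) - P(from)]

Population size and the mean number of beverage-purchase store visits per
adolescent per year are required inputs — the model does not hard-code
them, because they are survey- and census-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .model_core import purchase_probability
from .parameters import ModelParams, ParameterError, PlacementLocation

__all__ = ["ProjectionInputs", "project_additional_purchases", "projection_to_csv"]


@dataclass(frozen=True)
class ProjectionInputs:
    """Scenario for moving a non-SSB between two slots, scaled to a population."""

    population: int
    visits_per_year: float
    move_from: PlacementLocation
    move_to: PlacementLocation

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ParameterError(f"population must be >= 0, got {self.population}")
        if self.visits_per_year < 0:
            raise ParameterError(
                f"visits_per_year must be >= 0, got {self.visits_per_year}"
            )


def project_additional_purchases(inputs: ProjectionInputs, params: ModelParams) -> int:
    """Annual additional non-SSB purchases from moving the product.

    Rounded to the nearest integer; negative when the move is adverse.
    """
    delta = purchase_probability(inputs.move_to, params) - purchase_probability(
        inputs.move_from, params
    )
    return round(inputs.population * inputs.visits_per_year * delta)


def projection_to_csv(
    inputs: ProjectionInputs, params: ModelParams, target: Union[str, Path]
) -> None:
    """One-row CSV: inputs plus the projected additional purchases."""
    pd.DataFrame(
        [
            {
                "population": inputs.population,
                "visits_per_year": inputs.visits_per_year,
                "from_cooler": inputs.move_from.cooler,
                "from_shelf": inputs.move_from.shelf,
                "to_cooler": inputs.move_to.cooler,
                "to_shelf": inputs.move_to.shelf,
                "additional_purchases": project_additional_purchases(inputs, params),
            }
        ]
    ).to_csv(target, index=False)
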