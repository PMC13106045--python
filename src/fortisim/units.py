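"""Per-nutrient intake-unit registry.

Fortification standards are always expressed in mg of nutrient per kg of food
vehicle, while habitual-intake distributions, average requirements and
tolerable upper levels are reported in a nutrient-specific daily unit:
micrograms per day for the trace nutrients (iodine, vitamin A as retinol
activity equivalents, folate as dietary folate equivalents, vitamin B12,
selenium) and milligrams per day for everything else.  The registry pins that
unit once per nutrient so every intake-side quantity in the pipeline is
unit-checked at table load and the mg-per-kg standards are converted exactly
once, inside the contribution equation.
"""

from __future__ import annotations

from .errors import ConfigurationError

MG = "mg"
UG = "ug"

#: Daily intake unit per nutrient for the 13 modelled micronutrients.
DEFAULT_UNITS: dict[str, str] = {
    "vitamin_a": UG,
    "folate": UG,
    "vitamin_b12": UG,
    "iodine": UG,
    "selenium": UG,
    "calcium": MG,
    "iron": MG,
    "zinc": MG,
    "thiamin": MG,
    "riboflavin": MG,
    "niacin": MG,
    "vitamin_b6": MG,
    "vitamin_e": MG,
}


class UnitsRegistry:
    """Maps each nutrient to its daily intake unit (``mg`` or ``ug``)."""

    def __init__(self, units: dict[str, str] | None = None) -> None:
        units = dict(DEFAULT_UNITS if units is None else units)
        for nutrient, unit in units.items():
            if unit not in (MG, UG):
                raise ConfigurationError(
                    f"unknown unit {unit!r} for nutrient {nutrient!r}; expected 'mg' or 'ug'"
                )
        self._units = units

    def unit(self, nutrient: str) -> str:
        try:
            return self._units[nutrient]
        except KeyError:
            raise ConfigurationError(f"nutrient {nutrient!r} has no registered intake unit")

    def mg_to_intake_unit(self, nutrient: str) -> float:
        """Multiplier converting a quantity in mg/day to the nutrient's unit."""
        return 1000.0 if self.unit(nutrient) == UG else 1.0

    def nutrients(self) -> list[str]:
        return sorted(self._units)

    def __contains__(self, nutrient: str) -> bool:
        return nutrient in self._units
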