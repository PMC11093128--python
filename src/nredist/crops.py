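"""Crop-level constants: energy densities, nitrogen-rate bounds, unit conversions.

All masses are kilograms and all energies gigacalories internally; teragram
and petacalorie conversions happen only at I/O and reporting boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError

#: kg per teragram
TG = 1.0e9
#: Gcal per petacalorie
PCAL = 1.0e6

#: upper end of the valid total-nitrogen domain of every response function (kg/ha)
N_DOMAIN_MAX = 200.0


@dataclass(frozen=True)
class CropParams:
    """Per-crop conversion and bound constants.

    ``rate_min_total``/``rate_max_total`` bound *total* nitrogen (synthetic
    fertilizer plus biological fixation) in kg/ha.  Rice carries a higher
    floor because paddy systems receive biologically fixed nitrogen that
    cannot be reallocated.
    """

    name: str
    calorie_coeff: float  # Gcal per t DM
    rate_min_total: float  # kg N/ha
    rate_max_total: float  # kg N/ha


CROPS: dict[str, CropParams] = {
    "maize": CropParams("maize", 4.05, 10.0, 200.0),
    "rice": CropParams("rice", 3.22, 33.0, 200.0),
    "winter_wheat": CropParams("winter_wheat", 3.68, 10.0, 200.0),
    "spring_wheat": CropParams("spring_wheat", 3.80, 10.0, 200.0),
}

WATER_REGIMES = ("rainfed", "irrigated")


def get_crop(name: str) -> CropParams:
    try:
        return CROPS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown crop {name!r}; known crops: {sorted(CROPS)}"
        ) from None
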