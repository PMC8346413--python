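"""Person, environment, and activity inputs to the thermoregulatory model."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

#: Documented default basal metabolic rate, W/m2.
BASAL_MET_RATE = 45.0

#: Heat of vaporization of sweat, J/g.
LATENT_HEAT_SWEAT = 2430.0


def saturation_vapor_pressure(t_celsius: float) -> float:
    """Saturation vapor pressure over water (Pa), Antoine form.

    log10(P_mmHg) = 8.07131 - 1730.63 / (233.426 + T).  Good to ~1% over the
    physiological and meteorological range used here.
    """
    p_mmhg = 10.0 ** (8.07131 - 1730.63 / (233.426 + t_celsius))
    return p_mmhg * 133.322


def dubois_area(height_m: float, mass_kg: float) -> float:
    """DuBois body surface area (m2)."""
    return 0.202 * mass_kg ** 0.425 * height_m ** 0.725


@dataclass(frozen=True)
class PersonProfile:
    """Individual characteristics; surface area follows DuBois."""

    height: float = 1.75            # m
    mass: float = 75.0              # kg
    body_fat_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.height <= 0 or self.mass <= 0:
            raise ValidationError("height and mass must be positive")
        if not 0.0 < self.body_fat_fraction < 1.0:
            raise ValidationError("body_fat_fraction must be in (0, 1)")

    @property
    def surface_area(self) -> float:
        return dubois_area(self.height, self.mass)


@dataclass(frozen=True)
class Environment:
    """Ambient conditions: air temperature, humidity, wind, radiant temperature."""

    t_air: float                    # C
    rh: float = 50.0                # %
    v_wind: float = 0.4             # m/s (manikin reference speed)
    t_radiant: float | None = None  # C, defaults to t_air

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh <= 100.0:
            raise ValidationError(f"relative humidity must be in [0, 100], got {self.rh}")
        if self.v_wind < 0:
            raise ValidationError(f"wind speed must be >= 0, got {self.v_wind}")
        if not math.isfinite(self.t_air):
            raise ValidationError("air temperature must be finite")

    @property
    def t_rad(self) -> float:
        return self.t_air if self.t_radiant is None else self.t_radiant

    @property
    def vapor_pressure(self) -> float:
        """Ambient water-vapor pressure, Pa."""
        return saturation_vapor_pressure(self.t_air) * self.rh / 100.0


@dataclass(frozen=True)
class Activity:
    """Metabolic rate (W/m2) and the fraction converted to external work."""

    m_rate: float = BASAL_MET_RATE
    external_work_fraction: float = 0.0
    allow_below_basal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.external_work_fraction <= 0.25:
            raise ValidationError("external_work_fraction must be in [0, 0.25]")
        if self.m_rate < BASAL_MET_RATE and not self.allow_below_basal:
            raise ValidationError(
                f"metabolic rate {self.m_rate} W/m2 is below the basal default "
                f"{BASAL_MET_RATE}; pass allow_below_basal=True to override")

    @property
    def heat_rate(self) -> float:
        """Metabolic heat released inside the body, W/m2."""
        return self.m_rate * (1.0 - self.external_work_fraction)


#: Named activity presets mirroring the GUI pull-down (rest and treadmill
#: walking are the validation-study intensities).
ACTIVITY_PRESETS: dict[str, Activity] = {
    "basal": Activity(m_rate=BASAL_MET_RATE),
    "rest": Activity(m_rate=71.0),
    "walk": Activity(m_rate=171.0),
    "light_work": Activity(m_rate=120.0),
    "heavy_work": Activity(m_rate=250.0),
}
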