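"""Clothing database, ensemble composition, and regional boundary resistances.

A cold-weather ensemble is described per body region by an intrinsic thermal
resistance (m2.C/W) and an intrinsic evaporative resistance (m2.Pa/W),
measured garment-by-garment on regional thermal manikins.  The six regions
are head, torso, arm, hand, leg, and foot.  Ensemble-level intrinsic
resistances are the plain serial sums of the per-item regional values;
adding the wind-dependent surface air layer on top yields the boundary
resistances the thermoregulatory model consumes.

The bundled database (``data/gen3_ecwcs.csv``) holds the regional
resistances of 13 items of the US Army Generation III Extended Cold Weather
Clothing System.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError

log = logging.getLogger(__name__)

#: Canonical region order (matches the database column order).
REGIONS: tuple[str, ...] = ("head", "torso", "arm", "hand", "leg", "foot")

#: The five garment-selection slots of the decision aid.
SLOTS: tuple[str, ...] = ("head", "upper_body", "hand", "lower_body", "foot")

#: 1 clo in m2.C/W (display conversion only; storage is SI).
CLO = 0.155

# Surface air layer model: R_air = 1/(h_c + h_r), a standard ergonomics
# correlation.  h_r is a fixed linearized radiative coefficient; h_c has a
# still-air floor and grows with the square root of wind speed.  The
# evaporative air layer follows from the Lewis relation.
H_RADIATIVE = 4.7       # W/m2/C
H_CONV_MIN = 3.1        # W/m2/C, still-air floor
H_CONV_COEF = 8.3       # W/m2/C per sqrt(m/s)
LEWIS_RATIO = 16.5      # K/kPa

#: A region counts as covered iff its intrinsic thermal resistance exceeds
#: this, so trace spill-over cells (e.g. a trouser's 0.001 leg->torso value)
#: do not mark a region clothed.
COVERED_THRESHOLD = 0.001

_THERMAL_COLS = [f"rt_{r}" for r in REGIONS]
_EVAP_COLS = [f"re_{r}" for r in REGIONS]
_SCHEMA = ["name"] + _THERMAL_COLS + _EVAP_COLS

# Region of maximum thermal resistance -> GUI slot.  The database schema
# carries no slot column; the dominant region identifies the garment zone.
_REGION_TO_SLOT = {
    "head": "head",
    "torso": "upper_body",
    "arm": "upper_body",
    "hand": "hand",
    "leg": "lower_body",
    "foot": "foot",
}


def convective_coefficient(v_wind: float) -> float:
    """Convective heat-transfer coefficient h_c (W/m2/C) at wind speed v (m/s)."""
    if v_wind < 0:
        raise ValidationError(f"wind speed must be >= 0, got {v_wind}")
    return max(H_CONV_MIN, H_CONV_COEF * math.sqrt(v_wind))


def air_layer_resistances(v_wind: float) -> tuple[float, float]:
    """Thermal (m2.C/W) and evaporative (m2.Pa/W) resistance of the surface air layer.

    Thermal: ``1/(h_c + h_r)``.  Evaporative: Lewis relation,
    ``1000/(LR * h_c)`` with LR = 16.5 K/kPa.
    """
    h_c = convective_coefficient(v_wind)
    r_th = 1.0 / (h_c + H_RADIATIVE)
    r_e = 1000.0 / (LEWIS_RATIO * h_c)
    return r_th, r_e


@dataclass(frozen=True)
class ClothingItem:
    """One garment: per-region intrinsic thermal and evaporative resistances."""

    name: str
    slot: str
    r_thermal: Mapping[str, float]  # m2.C/W per region
    r_evap: Mapping[str, float]     # m2.Pa/W per region

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("clothing item name must be non-empty")
        if self.slot not in SLOTS:
            raise ValidationError(
                f"{self.name!r}: slot {self.slot!r} not one of {SLOTS}")
        for label, mapping in (("thermal", self.r_thermal), ("evaporative", self.r_evap)):
            missing = [r for r in REGIONS if r not in mapping]
            if missing:
                raise ValidationError(
                    f"{self.name!r}: missing {label} resistance for regions {missing}")
            for region in REGIONS:
                if mapping[region] < 0:
                    raise ValidationError(
                        f"{self.name!r}: negative {label} resistance for {region}")

    def clo(self, region: str) -> float:
        """Thermal resistance of ``region`` expressed in clo (display only)."""
        return self.r_thermal[region] / CLO


def infer_slot(r_thermal: Mapping[str, float]) -> str:
    """GUI slot inferred from the region carrying the most thermal resistance."""
    dominant = max(REGIONS, key=lambda r: r_thermal[r])
    return _REGION_TO_SLOT[dominant]


def load_items(path: str | Path) -> list[ClothingItem]:
    """Read a clothing database CSV (13-column schema) into validated items.

    Schema: ``name`` then ``rt_<region>`` (m2.C/W) then ``re_<region>``
    (m2.Pa/W) for the six regions, comma-separated, UTF-8, one header row.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"clothing database not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in _SCHEMA if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; expected schema {_SCHEMA}")
    if frame.empty:
        log.warning("%s: clothing database has a header but no items", path)
        return []
    items: list[ClothingItem] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        name = str(row["name"])
        if name in seen:
            raise ValidationError(f"{path} row {idx + 2}: duplicate item name {name!r}")
        seen.add(name)
        r_th = {r: float(row[f"rt_{r}"]) for r in REGIONS}
        r_ev = {r: float(row[f"re_{r}"]) for r in REGIONS}
        for label, mapping in (("thermal", r_th), ("evaporative", r_ev)):
            for region, value in mapping.items():
                if not math.isfinite(value) or value < 0:
                    raise ValidationError(
                        f"{path} row {idx + 2} ({name!r}): invalid {label} "
                        f"resistance {value} for region {region}")
        items.append(ClothingItem(name=name, slot=infer_slot(r_th),
                                  r_thermal=r_th, r_evap=r_ev))
    return items


def write_items(items: Iterable[ClothingItem], path: str | Path) -> None:
    """Write items back to the canonical CSV format (round-trips load_items)."""
    rows = []
    for item in items:
        row: dict[str, object] = {"name": item.name}
        row.update({f"rt_{r}": f"{item.r_thermal[r]:.3f}" for r in REGIONS})
        row.update({f"re_{r}": f"{item.r_evap[r]:.2f}" for r in REGIONS})
        rows.append(row)
    pd.DataFrame(rows, columns=_SCHEMA).to_csv(path, index=False)


def default_database_path() -> Path:
    """Path of the bundled GEN III ECWCS database."""
    return Path(str(resources.files("coweda.data") / "gen3_ecwcs.csv"))


def load_default_database() -> list[ClothingItem]:
    return load_items(default_database_path())


@dataclass
class Ensemble:
    """An ordered stack of clothing items per slot (innermost first).

    Order is documentation only: intrinsic composition is a plain serial sum
    of regional resistances, so it is order-independent.  An optional
    per-layer area factor hook is provided (defaults to 1.0 for every layer).
    """

    items: list[ClothingItem] = field(default_factory=list)
    label: str = ""
    area_factors: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def from_names(cls, names: Iterable[str], database: Iterable[ClothingItem],
                   label: str = "") -> "Ensemble":
        by_name = {item.name: item for item in database}
        items = []
        for name in names:
            if name not in by_name:
                close = _nearest_names(name, by_name)
                raise ValidationError(
                    f"unknown clothing item {name!r}; nearest matches: {close}")
            items.append(by_name[name])
        return cls(items=items, label=label)

    def layers(self, slot: str) -> list[ClothingItem]:
        return [item for item in self.items if item.slot == slot]

    def __add__(self, other: "Ensemble") -> "Ensemble":
        return Ensemble(items=self.items + other.items,
                        label=f"{self.label}+{other.label}".strip("+"))


def _nearest_names(name: str, by_name: Mapping[str, ClothingItem]) -> list[str]:
    import difflib
    return difflib.get_close_matches(name, list(by_name), n=3, cutoff=0.3)


def compose_intrinsic(ensemble: Ensemble) -> dict[str, tuple[float, float]]:
    """Serial-sum intrinsic (thermal, evaporative) resistance per region.

    An empty ensemble legally yields zeros everywhere (bare body).
    """
    out = {}
    for region in REGIONS:
        rt = sum(item.r_thermal[region] * ensemble.area_factors.get(item.name, 1.0)
                 for item in ensemble.items)
        re = sum(item.r_evap[region] * ensemble.area_factors.get(item.name, 1.0)
                 for item in ensemble.items)
        out[region] = (rt, re)
    return out


@dataclass(frozen=True)
class RegionalInsulation:
    """Total (intrinsic + surface air layer) boundary resistances per region."""

    r_thermal_total: Mapping[str, float]  # m2.C/W
    r_evap_total: Mapping[str, float]     # m2.Pa/W
    covered: Mapping[str, bool]

    def __post_init__(self) -> None:
        for mapping, label in ((self.r_thermal_total, "thermal"),
                               (self.r_evap_total, "evaporative"),
                               (self.covered, "covered")):
            missing = [r for r in REGIONS if r not in mapping]
            if missing:
                raise ValidationError(f"insulation missing {label} regions {missing}")

    @classmethod
    def from_totals(cls, r_thermal: Mapping[str, float], r_evap: Mapping[str, float],
                    covered: Mapping[str, bool] | None = None) -> "RegionalInsulation":
        """Expert mode: explicit six-region totals (air layer already included)."""
        if covered is None:
            bare_rt, _ = air_layer_resistances(0.0)
            covered = {r: r_thermal[r] > bare_rt + COVERED_THRESHOLD for r in REGIONS}
        return cls(dict(r_thermal), dict(r_evap), dict(covered))


def total_insulation(ensemble: Ensemble, environment) -> RegionalInsulation:
    """Intrinsic sums plus the wind-dependent surface air layer, per region.

    ``environment`` may be anything with a ``v_wind`` attribute (m/s) or a
    bare wind speed.  Air-layer thermal resistance decreases monotonically
    with wind; only the air layer is wind-corrected (intrinsic values are
    the manikin measurements at 0.4 m/s).
    """
    v_wind = getattr(environment, "v_wind", environment)
    r_air_th, r_air_ev = air_layer_resistances(float(v_wind))
    intrinsic = compose_intrinsic(ensemble)
    r_th = {r: intrinsic[r][0] + r_air_th for r in REGIONS}
    r_ev = {r: intrinsic[r][1] + r_air_ev for r in REGIONS}
    covered = {r: intrinsic[r][0] > COVERED_THRESHOLD for r in REGIONS}
    return RegionalInsulation(r_th, r_ev, covered)
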