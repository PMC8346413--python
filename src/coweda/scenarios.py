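"""Scenario files: one structured-text description of a complete run.

A scenario bundles environment, activity, clothing (by item list, preset
name, or expert-mode explicit resistances), person profile, duration, and
criteria overrides.  ``run_endure`` executes the full pipeline
(database -> composition -> simulation -> metrics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import clothing as cl
from . import metrics, model
from .conditions import ACTIVITY_PRESETS, Activity, Environment, PersonProfile
from .errors import SchemaError, ValidationError
from .metrics import Criteria, EnduranceReport
from .model import SimulationResult
from .params import ModelParameters


def ensemble_presets() -> dict[str, list[str]]:
    with open(str(resources.files("coweda.data") / "ensembles.yaml"),
              encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_preset(name: str, database=None) -> cl.Ensemble:
    presets = ensemble_presets()
    if name not in presets:
        raise ValidationError(
            f"unknown ensemble preset {name!r}; available: {sorted(presets)}")
    database = database or cl.load_default_database()
    return cl.Ensemble.from_names(presets[name], database, label=name)


@dataclass
class Scenario:
    """Validated scenario: everything one endurance run needs."""

    label: str
    environment: Environment
    activity: Activity
    profile: PersonProfile
    duration: float                       # min
    criteria: Criteria
    ensemble: cl.Ensemble | None = None
    resistances: cl.RegionalInsulation | None = None   # expert mode
    extra_intrinsic: dict | None = None   # accessories absent from the DB
    db_path: str | None = None

    def __post_init__(self) -> None:
        if self.ensemble is None and self.resistances is None:
            raise ValidationError(
                "scenario needs an ensemble or a full six-region resistance set")

    def insulation(self) -> cl.RegionalInsulation:
        if self.resistances is not None:
            return self.resistances
        ins = cl.total_insulation(self.ensemble, self.environment)
        if not self.extra_intrinsic:
            return ins
        extra_th = self.extra_intrinsic.get("thermal", {})
        extra_ev = self.extra_intrinsic.get("evaporative", {})
        r_th = {r: ins.r_thermal_total[r] + float(extra_th.get(r, 0.0))
                for r in cl.REGIONS}
        r_ev = {r: ins.r_evap_total[r] + float(extra_ev.get(r, 0.0))
                for r in cl.REGIONS}
        covered = {r: ins.covered[r]
                   or float(extra_th.get(r, 0.0)) > cl.COVERED_THRESHOLD
                   for r in cl.REGIONS}
        return cl.RegionalInsulation(r_th, r_ev, covered)


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"scenario {where}: missing key {key!r}")
    return mapping[key]


def load_scenario(path: str | Path) -> Scenario:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: scenario file must be a mapping")
    where = str(path)

    env_raw = _require(raw, "environment", where)
    environment = Environment(
        t_air=float(_require(env_raw, "t_air", where)),
        rh=float(env_raw.get("rh", 50.0)),
        v_wind=float(env_raw.get("v_wind", 0.4)),
        t_radiant=env_raw.get("t_radiant"))

    act_raw = _require(raw, "activity", where)
    if isinstance(act_raw, str):
        if act_raw not in ACTIVITY_PRESETS:
            raise ValidationError(
                f"{path}: unknown activity preset {act_raw!r}; "
                f"available: {sorted(ACTIVITY_PRESETS)}")
        activity = ACTIVITY_PRESETS[act_raw]
    else:
        activity = Activity(
            m_rate=float(_require(act_raw, "m_rate", where)),
            external_work_fraction=float(act_raw.get("external_work_fraction", 0.0)))

    prof_raw = raw.get("profile", {})
    profile = PersonProfile(
        height=float(prof_raw.get("height", 1.75)),
        mass=float(prof_raw.get("mass", 75.0)),
        body_fat_fraction=float(prof_raw.get("body_fat_fraction", 0.15)))

    crit_raw = raw.get("criteria", {})
    duration = float(raw.get("duration", 480.0))
    criteria = Criteria(
        core_limit=float(crit_raw.get("core_limit", 36.0)),
        extremity_limit=float(crit_raw.get("extremity_limit", 5.0)),
        wettedness_limit=float(crit_raw.get("wettedness_limit", 0.5)),
        horizon=float(crit_raw.get("horizon", duration)))

    ensemble = None
    resistances = None
    db_path = raw.get("clothing_db")
    if "resistances" in raw:
        res_raw = raw["resistances"]
        r_th = {r: float(v) for r, v in _require(res_raw, "thermal", where).items()}
        r_ev = {r: float(v) for r, v in _require(res_raw, "evaporative", where).items()}
        missing = [r for r in cl.REGIONS if r not in r_th or r not in r_ev]
        if missing:
            raise SchemaError(
                f"{path}: expert-mode resistances missing regions {missing}")
        covered = res_raw.get("covered")
        resistances = cl.RegionalInsulation.from_totals(
            r_th, r_ev, {r: bool(covered[r]) for r in cl.REGIONS} if covered else None)
    elif "ensemble" in raw or "ensemble_preset" in raw:
        database = cl.load_items(db_path) if db_path else cl.load_default_database()
        if "ensemble_preset" in raw:
            ensemble = load_preset(raw["ensemble_preset"], database)
        else:
            ensemble = cl.Ensemble.from_names(raw["ensemble"], database,
                                              label=raw.get("label", ""))
    else:
        raise SchemaError(
            f"{path}: scenario needs 'ensemble', 'ensemble_preset', or 'resistances'")

    return Scenario(
        label=str(raw.get("label", path.stem)), environment=environment,
        activity=activity, profile=profile, duration=duration,
        criteria=criteria, ensemble=ensemble, resistances=resistances,
        extra_intrinsic=raw.get("extra_intrinsic"), db_path=db_path)


def bundled_scenario_path(name: str) -> Path:
    return Path(str(resources.files("coweda.data") / "scenarios" / f"{name}.yaml"))


def bundled_scenarios() -> list[str]:
    folder = Path(str(resources.files("coweda.data") / "scenarios"))
    return sorted(p.stem for p in folder.glob("*.yaml"))


def run_endure(scenario: Scenario, params: ModelParameters | None = None,
               dt: float | None = None,
               ) -> tuple[EnduranceReport, SimulationResult, cl.RegionalInsulation]:
    """Execute the full pipeline for one scenario."""
    params = params or ModelParameters.for_person(scenario.profile)
    insulation = scenario.insulation()
    duration = max(scenario.duration, scenario.criteria.horizon)
    result = model.simulate(scenario.profile, scenario.environment,
                            scenario.activity, insulation, params=params,
                            duration=math.ceil(duration), dt=dt)
    report = metrics.endurance_report(result, insulation, scenario.criteria)
    return report, result, insulation
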