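"""Model parameters: loading, person scaling, and thermoneutral calibration.

The parameter file stores fractions, gains, and reference conductances.
:meth:`ModelParameters.for_person` resolves them against a person's DuBois
area and mass, then *calibrates* the remaining free quantities — muscle/fat
set-point temperatures, per-node basal metabolic heat, and the blood-pool
set point — by solving the linear steady-state heat balance of the whole
body at the documented thermoneutral environment (nude, basal activity,
basal vasomotor tone, basal skin wettedness).  The thermoneutral body state
is therefore an exact fixed point of the model by construction.

Calibration unknowns (25): muscle and fat temperature per segment (12),
muscle and core basal heat per segment (12), and the blood temperature (1).
Equations (25): the 24 node balances plus the blood-pool balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .clothing import air_layer_resistances
from .conditions import Environment, PersonProfile, saturation_vapor_pressure
from .errors import CalibrationError, ValidationError

SEGMENTS: tuple[str, ...] = ("head", "torso", "arm", "leg", "hand", "foot")
COMPARTMENTS: tuple[str, ...] = ("core", "muscle", "fat", "skin")
CORE, MUSCLE, FAT, SKIN = range(4)

#: Clothing-region name for each model segment (identical in this layout).
SEGMENT_REGION: dict[str, str] = {s: s for s in SEGMENTS}


def _seg_vector(mapping: Mapping[str, float]) -> np.ndarray:
    missing = [s for s in SEGMENTS if s not in mapping]
    if missing:
        raise ValidationError(f"parameter table missing segments {missing}")
    return np.array([float(mapping[s]) for s in SEGMENTS])


def default_config_path() -> Path:
    return Path(str(resources.files("coweda.data") / "sctm_params.yaml"))


def load_config(path: str | Path | None = None) -> dict:
    with open(path or default_config_path(), "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ModelParameters:
    """Person-resolved, calibrated parameter set (all arrays segment-ordered)."""

    profile: PersonProfile
    area: np.ndarray            # (6,) m2 per segment
    area_fraction: np.ndarray   # (6,)
    capacity: np.ndarray        # (6,4) J/C
    conductance: np.ndarray     # (6,3) W/C: core-muscle, muscle-fat, fat-skin
    bf_basal: np.ndarray        # (6,4) L/h
    q_basal: np.ndarray         # (6,4) W (calibrated)
    set_point: np.ndarray       # (6,4) C (muscle/fat calibrated)
    t_blood_set: float          # C (calibrated)
    blood_capacity: float       # J/C
    beta_per_flow: float        # W/C per L/h
    basal_met_rate: float       # W/m2 (calibrated whole-body basal rate)
    # vasomotor control
    g_dil: float
    g_dil_exercise: float
    g_str_core: float
    g_str_skin: float
    g_str_inhib: float
    g_str_exercise: float
    frac_dil: np.ndarray        # (6,)
    frac_str: np.ndarray        # (6,)
    skbf_min: np.ndarray        # (6,)
    skbf_max: np.ndarray        # (6,)
    deep_str_frac: np.ndarray   # (6,)
    deep_min_flow: float
    # shivering
    g_shiv_prod: float
    g_shiv_skin: float
    shiver_max_wm2: float
    shiver_dist: np.ndarray     # (6,)
    # sweating
    g_sw_core: float
    g_sw_skin: float
    g_sw_inhib: float
    # activity
    work_dist: np.ndarray       # (6,)
    work_perfusion: float       # L/h per W
    # respiration / evaporation
    resp_coef: tuple[float, float]
    w_min: float
    latent_heat: float
    # receptors
    skin_weights: np.ndarray    # (6,), sum 1
    # environment used for calibration
    thermoneutral: Environment
    dt_default: float
    output_interval: float

    # ------------------------------------------------------------------
    @classmethod
    def for_person(cls, profile: PersonProfile | None = None,
                   config: dict | str | Path | None = None,
                   overrides: dict | None = None) -> "ModelParameters":
        """Resolve the parameter file for a person and calibrate.

        ``config`` may be a loaded dict or a YAML path; ``overrides`` is a
        shallow update applied on top (one level of nesting merged).
        """
        profile = profile or PersonProfile()
        if isinstance(config, (str, Path)):
            cfg = load_config(config)
        else:
            cfg = dict(config) if config else load_config()
        if overrides:
            cfg = _merge(cfg, overrides)
        return _resolve(cls, profile, cfg)

    # ------------------------------------------------------------------
    def seg_index(self, segment: str) -> int:
        return SEGMENTS.index(segment)

    def comp_index(self, compartment: str) -> int:
        return COMPARTMENTS.index(compartment)

    @property
    def total_area(self) -> float:
        return float(self.area.sum())


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = {**out[key], **value}
        else:
            out[key] = value
    return out


def _skin_loss_per_area(t_skin: np.ndarray, env: Environment,
                        w: float) -> tuple[np.ndarray, np.ndarray]:
    """Dry and evaporative loss (W/m2) of bare skin at wettedness ``w``."""
    from .clothing import H_RADIATIVE, convective_coefficient
    r_th, r_ev = air_layer_resistances(env.v_wind)
    hc = convective_coefficient(env.v_wind)
    t_op = (H_RADIATIVE * env.t_rad + hc * env.t_air) / (H_RADIATIVE + hc)
    dry = (t_skin - t_op) / r_th
    p_skin = np.array([saturation_vapor_pressure(t) for t in np.atleast_1d(t_skin)])
    evap = np.maximum(0.0, w * (p_skin - env.vapor_pressure) / r_ev)
    return dry, evap


def _resolve(cls, profile: PersonProfile, cfg: dict) -> ModelParameters:
    area_frac = _seg_vector(cfg["area_fraction"])
    if abs(area_frac.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"area fractions must sum to 1 (got {area_frac.sum():.12f})")
    mass_frac = _seg_vector(cfg["mass_fraction"])
    if abs(mass_frac.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"mass fractions must sum to 1 (got {mass_frac.sum():.12f})")

    area = area_frac * profile.surface_area
    seg_mass = mass_frac * profile.mass

    split = np.array([[cfg["compartment_mass_split"][s][c] for c in COMPARTMENTS]
                      for s in SEGMENTS])
    if np.any(np.abs(split.sum(axis=1) - 1.0) > 1e-9):
        raise ValidationError("compartment mass splits must each sum to 1")
    c_p = np.array([cfg["specific_heat"][c] for c in COMPARTMENTS])
    capacity = seg_mass[:, None] * split * c_p[None, :]

    cond = np.column_stack([
        _seg_vector(cfg["conduction"]["core_muscle"]),
        _seg_vector(cfg["conduction"]["muscle_fat"]),
        _seg_vector(cfg["conduction"]["fat_skin"]),
    ])
    if np.any(cond <= 0) or np.any(capacity <= 0):
        raise ValidationError("conductances and capacities must be positive")

    bf = np.column_stack([_seg_vector(cfg["basal_blood_flow"][c]) for c in COMPARTMENTS])
    beta_per_flow = float(cfg["blood_flow_heat_equiv"])

    t_core = _seg_vector(cfg["set_point_core"])
    t_skin = _seg_vector(cfg["set_point_skin"])

    tn = cfg["thermoneutral"]
    env = Environment(t_air=float(tn["t_air"]), rh=float(tn["rh"]),
                      v_wind=float(tn["v_wind"]))

    w_min = float(cfg["wettedness_min"])
    latent = float(cfg["latent_heat"])
    resp_coef = tuple(float(x) for x in cfg["respiration_coefficients"])

    q_skin_fixed = float(cfg["basal_met_skin_per_kg"]) * seg_mass * split[:, SKIN]
    q_fat_fixed = float(cfg["basal_met_fat_per_kg"]) * seg_mass * split[:, FAT]

    set_point, q_basal, t_blood, basal_met = _calibrate(
        area=area, cond=cond, bf=bf, beta=beta_per_flow,
        t_core=t_core, t_skin=t_skin, env=env, w_min=w_min,
        q_skin_fixed=q_skin_fixed, q_fat_fixed=q_fat_fixed,
        resp_coef=resp_coef, total_area=profile.surface_area)

    vm = cfg["vasomotor"]
    sh = cfg["shivering"]
    sw = cfg["sweating"]
    shiver_dist = _seg_vector(sh["distribution"])
    work_dist = _seg_vector(cfg["work_distribution"])
    for name, dist in (("shivering", shiver_dist), ("work", work_dist)):
        if abs(dist.sum() - 1.0) > 1e-9:
            raise ValidationError(f"{name} distribution must sum to 1")

    return cls(
        profile=profile,
        area=area,
        area_fraction=area_frac,
        capacity=capacity,
        conductance=cond,
        bf_basal=bf,
        q_basal=q_basal,
        set_point=set_point,
        t_blood_set=t_blood,
        blood_capacity=float(cfg["blood_heat_capacity"]),
        beta_per_flow=beta_per_flow,
        basal_met_rate=basal_met,
        g_dil=float(vm["g_dil"]),
        g_dil_exercise=float(vm.get("g_dil_exercise", 0.0)),
        g_str_core=float(vm["g_str_core"]),
        g_str_skin=float(vm["g_str_skin"]),
        g_str_inhib=float(vm["g_str_inhib"]),
        g_str_exercise=float(vm.get("g_str_exercise", 0.0)),
        frac_dil=_seg_vector(vm["frac_dil"]),
        frac_str=_seg_vector(vm["frac_str"]),
        skbf_min=_seg_vector(vm["skbf_min"]),
        skbf_max=_seg_vector(vm["skbf_max"]),
        deep_str_frac=_seg_vector(vm["deep_str_frac"]),
        deep_min_flow=float(vm["deep_min_flow"]),
        g_shiv_prod=float(sh["g_prod"]),
        g_shiv_skin=float(sh["g_skin"]),
        shiver_max_wm2=float(sh["max_wm2"]),
        shiver_dist=shiver_dist,
        g_sw_core=float(sw["g_core"]),
        g_sw_skin=float(sw["g_skin"]),
        g_sw_inhib=float(sw["g_inhib"]),
        work_dist=work_dist,
        work_perfusion=float(cfg["work_perfusion"]),
        resp_coef=resp_coef,
        w_min=w_min,
        latent_heat=latent,
        skin_weights=area_frac.copy(),
        thermoneutral=env,
        dt_default=float(cfg["dt_seconds"]),
        output_interval=float(cfg["output_interval_seconds"]),
    )


def _calibrate(*, area, cond, bf, beta, t_core, t_skin, env, w_min,
               q_skin_fixed, q_fat_fixed, resp_coef, total_area):
    """Solve the thermoneutral steady state (see module docstring).

    Returns (set_point (6,4), q_basal (6,4), t_blood, basal_met_rate W/m2).
    Iterates twice because the respiratory loss depends weakly on the total
    basal rate being solved for.
    """
    n = len(SEGMENTS)
    b_flow = bf * beta  # W/C per node
    dry, evap = _skin_loss_per_area(t_skin, env, w_min)
    skin_loss = (dry + evap) * area  # W per segment

    m_total_guess = 45.0 * total_area
    for _ in range(3):
        p_air_kpa = env.vapor_pressure / 1000.0
        q_resp = (resp_coef[0] * (34.0 - env.t_air)
                  + resp_coef[1] * (5.87 - p_air_kpa)) * m_total_guess
        q_resp = max(q_resp, 0.0)

        # Unknowns: x = [T_m (6), T_f (6), q_m (6), q_c (6), T_b]
        size = 4 * n + 1
        A = np.zeros((size, size))
        rhs = np.zeros(size)
        iTm = lambda s: s
        iTf = lambda s: n + s
        iqm = lambda s: 2 * n + s
        iqc = lambda s: 3 * n + s
        iTb = 4 * n

        for s in range(n):
            k1, k2, k3 = cond[s]
            bc, bm, bfat, bs = b_flow[s]
            # skin balance: q_s + k3*(T_f - T_s) + bs*(T_b - T_s) - loss = 0
            row = s
            A[row, iTf(s)] = k3
            A[row, iTb] = bs
            rhs[row] = skin_loss[s] - q_skin_fixed[s] + k3 * t_skin[s] + bs * t_skin[s]
            # fat balance: q_f + k2*(T_m - T_f) - k3*(T_f - T_s) + bfat*(T_b - T_f) = 0
            row = n + s
            A[row, iTm(s)] = k2
            A[row, iTf(s)] = -(k2 + k3 + bfat)
            A[row, iTb] = bfat
            rhs[row] = -q_fat_fixed[s] - k3 * t_skin[s]
            # muscle balance: q_m + k1*(T_c - T_m) - k2*(T_m - T_f) + bm*(T_b - T_m) = 0
            row = 2 * n + s
            A[row, iqm(s)] = 1.0
            A[row, iTm(s)] = -(k1 + k2 + bm)
            A[row, iTf(s)] = k2
            A[row, iTb] = bm
            rhs[row] = -k1 * t_core[s]
            # core balance: q_c - k1*(T_c - T_m) + bc*(T_b - T_c) - resp = 0
            row = 3 * n + s
            A[row, iqc(s)] = 1.0
            A[row, iTm(s)] = k1
            A[row, iTb] = bc
            rhs[row] = k1 * t_core[s] + bc * t_core[s] + (q_resp if SEGMENTS[s] == "torso" else 0.0)
        # blood balance: sum_nodes b*(T_node - T_b) = 0
        row = 4 * n
        for s in range(n):
            A[row, iTm(s)] += b_flow[s, MUSCLE]
            A[row, iTf(s)] += b_flow[s, FAT]
        A[row, iTb] = -b_flow.sum()
        rhs[row] = -(b_flow[:, CORE] @ t_core + b_flow[:, SKIN] @ t_skin)

        x = np.linalg.solve(A, rhs)
        t_m, t_f = x[:n], x[n:2 * n]
        q_m, q_c = x[2 * n:3 * n], x[3 * n:4 * n]
        t_blood = float(x[-1])
        m_total = float(q_m.sum() + q_c.sum() + q_skin_fixed.sum()
                        + q_fat_fixed.sum() + q_resp)
        if abs(m_total - m_total_guess) < 1e-9:
            break
        m_total_guess = m_total

    problems = []
    for s, name in enumerate(SEGMENTS):
        if q_m[s] < -1e-9:
            problems.append(f"{name} muscle basal heat {q_m[s]:.3f} W < 0")
        if q_c[s] < -1e-9:
            problems.append(f"{name} core basal heat {q_c[s]:.3f} W < 0")
        for label, t in (("muscle", t_m[s]), ("fat", t_f[s])):
            if not 25.0 < t < 40.0:
                problems.append(f"{name} {label} set point {t:.2f} C unphysical")
    if not 34.0 < t_blood < 39.0:
        problems.append(f"blood set point {t_blood:.2f} C unphysical")
    if problems:
        raise CalibrationError(
            "thermoneutral calibration failed: " + "; ".join(problems))

    set_point = np.column_stack([t_core, t_m, t_f, t_skin])
    q_basal = np.column_stack([np.maximum(q_c, 0.0), np.maximum(q_m, 0.0),
                               q_fat_fixed, q_skin_fixed])
    return set_point, q_basal, t_blood, m_total / total_area
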