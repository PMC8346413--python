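"""Six-cylinder thermoregulatory model: passive heat balance plus control.

The body is six segments (head, torso, arm, leg, hand, foot), each with four
concentric compartments (core, muscle, fat, skin), coupled radially by
conduction and globally through a central blood pool.  Active control:

* shivering — driven by the product of cold core and cold skin signals plus
  a small cold-skin term, capped, distributed to muscle;
* vasomotion — per-region skin blood flow dilated by a warm core signal and
  constricted by cold core/skin signals (extremity deep flows constrict
  too);
* sweating — driven by warm core/skin signals, inhibited by cold skin;
  regional skin wettedness follows from sweat rate and the evaporative
  capacity of the boundary resistances.

Skin nodes exchange dry heat with the operative temperature through the
regional total thermal resistance and latent heat through the total
evaporative resistance; the torso core pays the respiratory heat loss.
Integration is fixed-step RK4 (default 10 s), output on a 1-min grid, fully
deterministic.  Three auxiliary energy integrals (metabolic+shivering, dry +
evaporative, respiratory) ride along in the state vector so that the energy
audit ``dH = E_met - E_dry_evap - E_resp`` holds to integrator precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .clothing import H_RADIATIVE, RegionalInsulation, convective_coefficient
from .conditions import Activity, Environment, PersonProfile, saturation_vapor_pressure
from .errors import ConfigurationError, SolverError, ValidationError
from .params import (COMPARTMENTS, CORE, FAT, MUSCLE, SEGMENTS, SKIN,
                     SEGMENT_REGION, ModelParameters)

N_SEG = len(SEGMENTS)
N_NODES = N_SEG * len(COMPARTMENTS)
# State vector: 24 node temps, blood temp, E_met, E_surface, E_resp (J).
STATE_SIZE = N_NODES + 4


@dataclass
class BodyState:
    """Temperatures plus the control-derived regional quantities."""

    temps: np.ndarray              # (6,4) C
    t_blood: float                 # C
    sweat_rate: Mapping[str, float] = field(default_factory=dict)   # g/min
    skbf: Mapping[str, float] = field(default_factory=dict)         # L/h
    wettedness: Mapping[str, float] = field(default_factory=dict)

    def temperature(self, segment: str, compartment: str) -> float:
        return float(self.temps[SEGMENTS.index(segment), COMPARTMENTS.index(compartment)])

    @property
    def t(self) -> dict[tuple[str, str], float]:
        return {(s, c): float(self.temps[i, j])
                for i, s in enumerate(SEGMENTS) for j, c in enumerate(COMPARTMENTS)}


def initial_state(params: ModelParameters) -> BodyState:
    """The calibrated thermoneutral state: an exact fixed point of the model
    at the documented thermoneutral environment with basal activity."""
    temps = params.set_point.copy()
    skbf = {s: float(params.bf_basal[i, SKIN]) for i, s in enumerate(SEGMENTS)}
    return BodyState(temps=temps, t_blood=params.t_blood_set,
                     sweat_rate={s: 0.0 for s in SEGMENTS}, skbf=skbf,
                     wettedness={s: params.w_min for s in SEGMENTS})


def thermal_signals(state: BodyState, params: ModelParameters) -> tuple[float, float]:
    """(core_signal, integrated_skin_signal) in C.

    Core signal is the head-core (hypothalamic) deviation; the skin signal
    is the receptor-weighted sum of regional skin deviations (weights sum
    to 1).
    """
    core_sig = float(state.temps[SEGMENTS.index("head"), CORE]
                     - params.set_point[SEGMENTS.index("head"), CORE])
    skin_dev = state.temps[:, SKIN] - params.set_point[:, SKIN]
    skin_sig = float(params.skin_weights @ skin_dev)
    return core_sig, skin_sig


def control_actions(signals: tuple[float, float], state: BodyState,
                    params: ModelParameters, exercise_wm2: float = 0.0,
                    ) -> tuple[float, dict[str, float], dict[str, float]]:
    """Shivering (W), regional skin blood flow (L/h), regional sweat (g/min).

    ``exercise_wm2`` is the metabolic rate above basal; it releases
    vasoconstriction at exercise onset.
    """
    shiver_w, skbf, sweat, _ = _controls(np.asarray(state.temps), signals, params,
                                         exercise_wm2)
    return (float(shiver_w),
            {s: float(skbf[i]) for i, s in enumerate(SEGMENTS)},
            {s: float(sweat[i]) for i, s in enumerate(SEGMENTS)})


def _controls(temps: np.ndarray, signals: tuple[float, float],
              params: ModelParameters, exercise_wm2: float = 0.0):
    core_sig, skin_sig = signals
    cold_core = max(0.0, -core_sig)
    warm_core = max(0.0, core_sig)
    cold_skin = max(0.0, -skin_sig)
    warm_skin = max(0.0, skin_sig)

    shiver_wm2 = min(params.shiver_max_wm2,
                     params.g_shiv_prod * cold_core * cold_skin
                     + params.g_shiv_skin * cold_skin)
    shiver_w = shiver_wm2 * params.total_area

    dil = params.g_dil * warm_core + params.g_dil_exercise * max(0.0, exercise_wm2)
    stric = max(0.0, params.g_str_core * cold_core
                + params.g_str_skin * cold_skin
                - params.g_str_inhib * warm_core
                - params.g_str_exercise * max(0.0, exercise_wm2))
    skbf = (params.bf_basal[:, SKIN] + params.frac_dil * dil) \
        / (1.0 + params.frac_str * stric)
    skbf = np.clip(skbf, params.skbf_min, params.skbf_max)

    sweat_total = max(0.0, params.g_sw_core * warm_core
                      + params.g_sw_skin * warm_skin
                      - params.g_sw_inhib * cold_skin)
    sweat = sweat_total * params.area_fraction

    return shiver_w, skbf, sweat, stric


@dataclass
class Derivatives:
    """Rate of change of the state plus the instantaneous heat flows."""

    d_temps: np.ndarray        # (6,4) C/s
    d_blood: float             # C/s
    dry_loss: np.ndarray       # (6,) W per region
    evap_loss: np.ndarray      # (6,) W
    resp_loss: float           # W
    shiver: float              # W
    metabolic: float           # W (incl. shivering, minus external work)
    skbf: np.ndarray           # (6,) L/h
    sweat: np.ndarray          # (6,) g/min
    wettedness: np.ndarray     # (6,)


def _insulation_arrays(insulation: RegionalInsulation) -> tuple[np.ndarray, np.ndarray]:
    try:
        r_th = np.array([insulation.r_thermal_total[SEGMENT_REGION[s]] for s in SEGMENTS])
        r_ev = np.array([insulation.r_evap_total[SEGMENT_REGION[s]] for s in SEGMENTS])
    except KeyError as exc:
        raise ConfigurationError(f"insulation missing region {exc}") from exc
    if np.any(r_th <= 0) or np.any(r_ev <= 0):
        raise ConfigurationError("total resistances must be positive")
    return r_th, r_ev


def derivatives(state: BodyState, env: Environment, activity: Activity,
                insulation: RegionalInsulation, params: ModelParameters) -> Derivatives:
    """Evaluate the full right-hand side at one body state."""
    r_th, r_ev = _insulation_arrays(insulation)
    return _rhs(np.asarray(state.temps, dtype=float), float(state.t_blood),
                env, activity, r_th, r_ev, params)


def _rhs(temps: np.ndarray, t_blood: float, env: Environment, activity: Activity,
         r_th: np.ndarray, r_ev: np.ndarray, params: ModelParameters) -> Derivatives:
    core_sig, skin_sig = _signals_from_arrays(temps, params)
    exercise_wm2 = max(0.0, activity.m_rate - params.basal_met_rate)
    shiver_w, skbf, sweat, stric = _controls(temps, (core_sig, skin_sig), params,
                                             exercise_wm2)

    # Per-node heat production ------------------------------------------------
    q = params.q_basal.copy()
    extra = exercise_wm2 * params.total_area * (1.0 - activity.external_work_fraction)
    q[:, MUSCLE] += extra * params.work_dist + shiver_w * params.shiver_dist

    # Blood flows -------------------------------------------------------------
    bf = params.bf_basal.copy()
    deep_factor = 1.0 / (1.0 + params.deep_str_frac * stric)
    bf[:, CORE] = np.maximum(bf[:, CORE] * deep_factor, params.deep_min_flow)
    bf[:, MUSCLE] = np.maximum(bf[:, MUSCLE] * deep_factor, params.deep_min_flow)
    bf[:, FAT] = np.maximum(bf[:, FAT] * deep_factor, params.deep_min_flow)
    bf[:, MUSCLE] += params.work_perfusion * (extra * params.work_dist
                                              + shiver_w * params.shiver_dist)
    bf[:, SKIN] = skbf

    # Surface losses ----------------------------------------------------------
    hc = convective_coefficient(env.v_wind)
    t_op = (H_RADIATIVE * env.t_rad + hc * env.t_air) / (H_RADIATIVE + hc)
    t_skin = temps[:, SKIN]
    dry = (t_skin - t_op) * params.area / r_th

    p_skin = np.array([saturation_vapor_pressure(t) for t in t_skin])
    e_max = np.maximum(0.0, (p_skin - env.vapor_pressure) * params.area / r_ev)
    e_sweat = sweat * params.latent_heat / 60.0  # W if fully evaporated
    with np.errstate(divide="ignore", invalid="ignore"):
        w_extra = np.where(e_max > 0, e_sweat / np.maximum(e_max, 1e-12), 0.0)
    wett = np.clip(params.w_min + (1.0 - params.w_min) * w_extra, params.w_min, 1.0)
    evap = wett * e_max

    # Respiration -------------------------------------------------------------
    m_total = activity.m_rate * params.total_area
    p_air_kpa = env.vapor_pressure / 1000.0
    resp = max(0.0, (params.resp_coef[0] * (34.0 - env.t_air)
                     + params.resp_coef[1] * (5.87 - p_air_kpa)) * m_total)

    # Node balances -----------------------------------------------------------
    flow = q.copy()
    k = params.conductance
    cond_cm = k[:, 0] * (temps[:, CORE] - temps[:, MUSCLE])
    cond_mf = k[:, 1] * (temps[:, MUSCLE] - temps[:, FAT])
    cond_fs = k[:, 2] * (temps[:, FAT] - temps[:, SKIN])
    flow[:, CORE] -= cond_cm
    flow[:, MUSCLE] += cond_cm - cond_mf
    flow[:, FAT] += cond_mf - cond_fs
    flow[:, SKIN] += cond_fs

    beta = bf * params.beta_per_flow
    flow += beta * (t_blood - temps)
    flow[SEGMENTS.index("torso"), CORE] -= resp
    flow[:, SKIN] -= dry + evap

    d_temps = flow / params.capacity
    d_blood = float((beta * (temps - t_blood)).sum() / params.blood_capacity)

    return Derivatives(
        d_temps=d_temps, d_blood=d_blood, dry_loss=dry, evap_loss=evap,
        resp_loss=resp, shiver=shiver_w,
        metabolic=float(q.sum()), skbf=skbf, sweat=sweat, wettedness=wett)


def _signals_from_arrays(temps: np.ndarray, params: ModelParameters) -> tuple[float, float]:
    core_sig = float(temps[SEGMENTS.index("head"), CORE]
                     - params.set_point[SEGMENTS.index("head"), CORE])
    skin_sig = float(params.skin_weights @ (temps[:, SKIN] - params.set_point[:, SKIN]))
    return core_sig, skin_sig


def total_enthalpy(state: BodyState, params: ModelParameters) -> float:
    """Total body heat content, J (relative to 0 C)."""
    return float((params.capacity * state.temps).sum()
                 + params.blood_capacity * state.t_blood)


@dataclass
class SimulationResult:
    """Minute-sampled trajectories of all state variables and heat flows."""

    times: np.ndarray          # min
    temps: np.ndarray          # (T,6,4) C
    t_blood: np.ndarray        # (T,) C
    mean_skin: np.ndarray      # (T,) C, area-weighted
    wettedness: np.ndarray     # (T,6)
    skbf: np.ndarray           # (T,6) L/h
    sweat: np.ndarray          # (T,6) g/min
    dry_loss: np.ndarray       # (T,) W
    evap_loss: np.ndarray      # (T,) W
    resp_loss: np.ndarray      # (T,) W
    shiver: np.ndarray         # (T,) W
    metabolic: np.ndarray      # (T,) W
    energy: np.ndarray         # (T,3) J: cumulative met, surface, resp
    params: ModelParameters

    def state_at(self, index: int) -> BodyState:
        return BodyState(
            temps=self.temps[index].copy(), t_blood=float(self.t_blood[index]),
            sweat_rate={s: float(self.sweat[index, i]) for i, s in enumerate(SEGMENTS)},
            skbf={s: float(self.skbf[index, i]) for i, s in enumerate(SEGMENTS)},
            wettedness={s: float(self.wettedness[index, i]) for i, s in enumerate(SEGMENTS)})

    def series(self, segment: str, compartment: str) -> np.ndarray:
        return self.temps[:, SEGMENTS.index(segment), COMPARTMENTS.index(compartment)]

    @property
    def core(self) -> np.ndarray:
        """Reported core temperature: torso core (rectal surrogate)."""
        return self.series("torso", "core")

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"time_min": self.times}
        for i, s in enumerate(SEGMENTS):
            for j, c in enumerate(COMPARTMENTS):
                data[f"t_{s}_{c}"] = self.temps[:, i, j]
        data["t_blood"] = self.t_blood
        data["mean_skin"] = self.mean_skin
        for i, s in enumerate(SEGMENTS):
            data[f"wettedness_{s}"] = self.wettedness[:, i]
            data[f"skbf_{s}"] = self.skbf[:, i]
            data[f"sweat_{s}"] = self.sweat[:, i]
        data["dry_loss_w"] = self.dry_loss
        data["evap_loss_w"] = self.evap_loss
        data["resp_loss_w"] = self.resp_loss
        data["shiver_w"] = self.shiver
        data["metabolic_w"] = self.metabolic
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       params: ModelParameters) -> "SimulationResult":
        n = len(frame)
        temps = np.empty((n, N_SEG, len(COMPARTMENTS)))
        for i, s in enumerate(SEGMENTS):
            for j, c in enumerate(COMPARTMENTS):
                temps[:, i, j] = frame[f"t_{s}_{c}"].to_numpy()
        get = lambda col: frame[col].to_numpy(dtype=float)
        stack = lambda prefix: np.column_stack(
            [get(f"{prefix}_{s}") for s in SEGMENTS])
        return cls(times=get("time_min"), temps=temps, t_blood=get("t_blood"),
                   mean_skin=get("mean_skin"), wettedness=stack("wettedness"),
                   skbf=stack("skbf"), sweat=stack("sweat"),
                   dry_loss=get("dry_loss_w"), evap_loss=get("evap_loss_w"),
                   resp_loss=get("resp_loss_w"), shiver=get("shiver_w"),
                   metabolic=get("metabolic_w"),
                   energy=np.zeros((n, 3)), params=params)

    @classmethod
    def from_csv(cls, path, params: ModelParameters) -> "SimulationResult":
        return cls.from_dataframe(pd.read_csv(path), params)


def simulate(profile: PersonProfile, env: Environment, activity: Activity,
             insulation: RegionalInsulation, params: ModelParameters | None = None,
             duration: float = 120.0, dt: float | None = None,
             start: BodyState | None = None) -> SimulationResult:
    """Integrate the model forward with fixed-step RK4.

    ``duration`` is in minutes, ``dt`` in seconds (must divide the 60-s
    output interval).  The run starts from the calibrated thermoneutral
    state unless ``start`` is given.  Fully deterministic.
    """
    params = params or ModelParameters.for_person(profile)
    dt = params.dt_default if dt is None else float(dt)
    if duration <= 0:
        raise ValidationError("duration must be positive")
    if not 0.0 < dt <= 60.0:
        raise ValidationError("dt must be in (0, 60] seconds")
    out_dt = params.output_interval
    steps_per_out = max(1, round(out_dt / dt))
    dt = out_dt / steps_per_out  # snap so output samples land exactly

    r_th, r_ev = _insulation_arrays(insulation)
    state0 = start or initial_state(params)

    y = np.empty(STATE_SIZE)
    y[:N_NODES] = np.asarray(state0.temps, dtype=float).ravel()
    y[N_NODES] = state0.t_blood
    y[N_NODES + 1:] = 0.0

    def f(vec: np.ndarray) -> tuple[np.ndarray, Derivatives]:
        temps = vec[:N_NODES].reshape(N_SEG, len(COMPARTMENTS))
        der = _rhs(temps, float(vec[N_NODES]), env, activity, r_th, r_ev, params)
        dy = np.empty(STATE_SIZE)
        dy[:N_NODES] = der.d_temps.ravel()
        dy[N_NODES] = der.d_blood
        dy[N_NODES + 1] = der.metabolic
        dy[N_NODES + 2] = float(der.dry_loss.sum() + der.evap_loss.sum())
        dy[N_NODES + 3] = der.resp_loss
        return dy, der

    n_out = int(round(duration)) + 1
    times = np.arange(n_out, dtype=float)
    temps_out = np.empty((n_out, N_SEG, len(COMPARTMENTS)))
    blood_out = np.empty(n_out)
    wett_out = np.empty((n_out, N_SEG))
    skbf_out = np.empty((n_out, N_SEG))
    sweat_out = np.empty((n_out, N_SEG))
    dry_out = np.empty(n_out)
    evap_out = np.empty(n_out)
    resp_out = np.empty(n_out)
    shiver_out = np.empty(n_out)
    met_out = np.empty(n_out)
    energy_out = np.empty((n_out, 3))

    def record(i: int, vec: np.ndarray) -> None:
        _, der = f(vec)
        temps_out[i] = vec[:N_NODES].reshape(N_SEG, len(COMPARTMENTS))
        blood_out[i] = vec[N_NODES]
        wett_out[i] = der.wettedness
        skbf_out[i] = der.skbf
        sweat_out[i] = der.sweat
        dry_out[i] = float(der.dry_loss.sum())
        evap_out[i] = float(der.evap_loss.sum())
        resp_out[i] = der.resp_loss
        shiver_out[i] = der.shiver
        met_out[i] = der.metabolic
        energy_out[i] = vec[N_NODES + 1:]

    record(0, y)
    minute = 0
    for minute in range(1, n_out):
        for _ in range(steps_per_out):
            k1, _ = f(y)
            k2, _ = f(y + 0.5 * dt * k1)
            k3, _ = f(y + 0.5 * dt * k2)
            k4, _ = f(y + dt * k3)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)):
            bad = int(np.argmax(~np.isfinite(y[:N_NODES]))) if not np.all(
                np.isfinite(y[:N_NODES])) else N_NODES
            seg = SEGMENTS[bad // len(COMPARTMENTS)] if bad < N_NODES else "blood"
            comp = COMPARTMENTS[bad % len(COMPARTMENTS)] if bad < N_NODES else ""
            raise SolverError(
                f"non-finite state at t={minute} min (node {seg} {comp})")
        record(minute, y)

    mean_skin = temps_out[:, :, SKIN] @ params.skin_weights
    return SimulationResult(
        times=times, temps=temps_out, t_blood=blood_out, mean_skin=mean_skin,
        wettedness=wett_out, skbf=skbf_out, sweat=sweat_out, dry_loss=dry_out,
        evap_loss=evap_out, resp_loss=resp_out, shiver=shiver_out,
        metabolic=met_out, energy=energy_out, params=params)
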