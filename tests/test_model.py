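"""Thermoregulatory-model tests: fixed point, controls, balances, integrator."""

import numpy as np
import pytest

from coweda import clothing as cl
from coweda import model
from coweda.conditions import Activity, Environment, PersonProfile
from coweda.errors import ConfigurationError, ValidationError
from coweda.params import SEGMENTS, SKIN, ModelParameters

COLD = Environment(t_air=-30.0, rh=30.0, v_wind=1.34)


def isolated_insulation():
    huge = {r: 1e9 for r in cl.REGIONS}
    return cl.RegionalInsulation.from_totals(
        huge, {r: 1e12 for r in cl.REGIONS}, {r: True for r in cl.REGIONS})


class TestInitialState:
    def test_torso_core_is_37(self, params):
        state = model.initial_state(params)
        assert state.temperature("torso", "core") == 37.0

    def test_skin_defaults_near_33_34_extremities_cooler(self, params):
        state = model.initial_state(params)
        skins = {s: state.temperature(s, "skin") for s in SEGMENTS}
        assert all(32.5 <= t <= 35.0 for t in skins.values())
        assert skins["hand"] < skins["torso"]
        assert skins["foot"] < skins["leg"]

    def test_fixed_point_over_60_minutes(self, profile, params, basal_activity,
                                         bare_thermoneutral):
        res = model.simulate(profile, params.thermoneutral, basal_activity,
                             bare_thermoneutral, params=params, duration=60)
        assert np.abs(res.temps - res.temps[0]).max() < 0.1

    def test_bad_area_fractions_rejected_upstream(self, profile):
        with pytest.raises(ValidationError, match="area fractions"):
            ModelParameters.for_person(profile, overrides={
                "area_fraction": {"head": 0.10, "torso": 0.36, "arm": 0.14,
                                  "leg": 0.32, "hand": 0.05, "foot": 0.06}})


class TestSignals:
    def test_null_at_set_points(self, params):
        state = model.initial_state(params)
        assert model.thermal_signals(state, params) == (0.0, 0.0)

    def test_uniform_skin_offset(self, params):
        state = model.initial_state(params)
        state.temps[:, SKIN] -= 1.0
        core, skin = model.thermal_signals(state, params)
        assert core == 0.0
        assert skin == pytest.approx(-1.0)

    def test_hand_only_offset_scales_with_weight(self, params):
        state = model.initial_state(params)
        i = SEGMENTS.index("hand")
        state.temps[i, SKIN] -= 5.0
        _, skin = model.thermal_signals(state, params)
        assert skin == pytest.approx(-5.0 * params.skin_weights[i])


class TestControls:
    def test_basal_at_set_point(self, params):
        state = model.initial_state(params)
        shiver, skbf, sweat = model.control_actions((0.0, 0.0), state, params)
        assert shiver == 0.0
        assert all(sweat[s] == 0.0 for s in SEGMENTS)
        for i, s in enumerate(SEGMENTS):
            assert skbf[s] == pytest.approx(params.bf_basal[i, SKIN])

    def test_shivering_saturates(self, params):
        state = model.initial_state(params)
        shiver, skbf, _ = model.control_actions((-1.0, -10.0), state, params)
        assert shiver == pytest.approx(params.shiver_max_wm2 * params.total_area)
        for i, s in enumerate(SEGMENTS):
            assert skbf[s] <= params.bf_basal[i, SKIN]

    def test_warm_core_drives_sweat_everywhere(self, params):
        state = model.initial_state(params)
        _, skbf, sweat = model.control_actions((0.5, 0.0), state, params)
        assert all(sweat[s] > 0.0 for s in SEGMENTS)
        for i, s in enumerate(SEGMENTS):
            assert skbf[s] >= params.bf_basal[i, SKIN]


class TestDerivatives:
    def test_equilibrium_has_zero_derivatives(self, profile, params,
                                              basal_activity, bare_thermoneutral):
        der = model.derivatives(model.initial_state(params), params.thermoneutral,
                                basal_activity, bare_thermoneutral, params)
        assert np.abs(der.d_temps).max() * 3600 < 1e-2   # C/h
        assert abs(der.d_blood) * 3600 < 1e-2

    def test_doubling_hand_resistance_halves_hand_dry_loss(
            self, profile, params, basal_activity, heavy_ensemble):
        ins = cl.total_insulation(heavy_ensemble, COLD)
        state = model.initial_state(params)
        der1 = model.derivatives(state, COLD, basal_activity, ins, params)
        doubled = cl.RegionalInsulation(
            {**ins.r_thermal_total,
             "hand": 2.0 * ins.r_thermal_total["hand"]},
            ins.r_evap_total, ins.covered)
        der2 = model.derivatives(state, COLD, basal_activity, doubled, params)
        i = SEGMENTS.index("hand")
        assert der2.dry_loss[i] == pytest.approx(der1.dry_loss[i] / 2.0)

    def test_missing_region_is_configuration_error(self, params, basal_activity):
        partial = {r: 0.2 for r in cl.REGIONS if r != "foot"}
        ins = cl.RegionalInsulation.__new__(cl.RegionalInsulation)
        object.__setattr__(ins, "r_thermal_total", partial)
        object.__setattr__(ins, "r_evap_total", partial)
        object.__setattr__(ins, "covered", {r: True for r in partial})
        with pytest.raises(ConfigurationError):
            model.derivatives(model.initial_state(params), COLD, basal_activity,
                              ins, params)

    def test_isolated_body_enthalpy_tracks_metabolism(self, profile):
        """With exchange paths disabled, dH equals the integrated heat input."""
        p = ModelParameters.for_person(
            profile, overrides={"respiration_coefficients": [0.0, 0.0]})
        res = model.simulate(profile, COLD, Activity(m_rate=120.0),
                             isolated_insulation(), params=p, duration=30)
        d_h = (model.total_enthalpy(res.state_at(30), p)
               - model.total_enthalpy(res.state_at(0), p))
        e_met, e_surf, e_resp = res.energy[30]
        assert e_surf < 1.0 and e_resp == 0.0
        assert d_h == pytest.approx(e_met, rel=1e-3)


class TestSimulate:
    def test_thermoneutral_core_stable_120_min(self, profile, params,
                                               basal_activity, bare_thermoneutral):
        res = model.simulate(profile, params.thermoneutral, basal_activity,
                             bare_thermoneutral, params=params, duration=120)
        assert np.all(np.abs(res.core - 37.0) < 0.2)

    def test_first_state_matches_initial(self, profile, params, basal_activity,
                                         bare_thermoneutral):
        res = model.simulate(profile, params.thermoneutral, basal_activity,
                             bare_thermoneutral, params=params, duration=5)
        assert np.array_equal(res.temps[0], model.initial_state(params).temps)
        assert np.all(np.diff(res.times) > 0)

    def test_hand_skin_monotone_cooling_at_minus_30_rest(
            self, profile, params, heavy_ensemble):
        ins = cl.total_insulation(heavy_ensemble, COLD)
        res = model.simulate(profile, COLD, Activity(m_rate=71.0), ins,
                             params=params, duration=120)
        hand = res.series("hand", "skin")
        assert np.all(np.diff(hand[5:]) <= 1e-9)

    def test_deterministic_bit_identical(self, profile, params, heavy_ensemble):
        ins = cl.total_insulation(heavy_ensemble, COLD)
        runs = [model.simulate(profile, COLD, Activity(m_rate=71.0), ins,
                               params=params, duration=20) for _ in range(2)]
        assert np.array_equal(runs[0].temps, runs[1].temps)
        assert np.array_equal(runs[0].t_blood, runs[1].t_blood)
        assert np.array_equal(runs[0].wettedness, runs[1].wettedness)

    @pytest.mark.parametrize("duration, dt", [(0, 10), (60, 0), (60, 61)])
    def test_invalid_duration_or_step(self, profile, params, bare_thermoneutral,
                                      basal_activity, duration, dt):
        with pytest.raises(ValidationError):
            model.simulate(profile, params.thermoneutral, basal_activity,
                           bare_thermoneutral, params=params,
                           duration=duration, dt=dt)

    def test_raising_regional_resistance_never_cools_that_region(
            self, profile, params, heavy_ensemble):
        ins = cl.total_insulation(heavy_ensemble, COLD)
        raised = cl.RegionalInsulation(
            {**ins.r_thermal_total, "hand": ins.r_thermal_total["hand"] + 0.2},
            ins.r_evap_total, ins.covered)
        base = model.simulate(profile, COLD, Activity(m_rate=71.0), ins,
                              params=params, duration=120)
        more = model.simulate(profile, COLD, Activity(m_rate=71.0), raised,
                              params=params, duration=120)
        assert np.all(more.series("hand", "skin")
                      >= base.series("hand", "skin") - 1e-9)

    def test_ambient_monotonicity(self, profile, heavy_ensemble):
        """Colder air never warms any node (passive+vasomotor; shivering off),
        and never warms any skin node or the reported core with full controls.

        Shivering legitimately warms working muscle in colder air, so the
        all-node form is checked with shivering disabled.
        """
        p_full = ModelParameters.for_person(profile)
        no_shiver = {"shivering": {
            "g_prod": 0.0, "g_skin": 0.0, "max_wm2": 0.0,
            "distribution": {"head": 0.03, "torso": 0.50, "arm": 0.12,
                             "leg": 0.30, "hand": 0.02, "foot": 0.03}}}
        p_ns = ModelParameters.for_person(profile, overrides=no_shiver)

        def run(p, t_air):
            env = Environment(t_air=t_air, rh=30.0, v_wind=1.34)
            return model.simulate(profile, env, Activity(m_rate=71.0),
                                  cl.total_insulation(heavy_ensemble, env),
                                  params=p, duration=60)

        temps = [0.0, -15.0, -30.0]
        runs_ns = [run(p_ns, t) for t in temps]
        for warm, cold in zip(runs_ns, runs_ns[1:]):
            assert np.all(cold.temps <= warm.temps + 1e-9)
        runs_full = [run(p_full, t) for t in temps]
        for warm, cold in zip(runs_full, runs_full[1:]):
            assert np.all(cold.temps[:, :, SKIN] <= warm.temps[:, :, SKIN] + 1e-9)
            assert np.all(cold.core <= warm.core + 1e-9)

    def test_trajectory_csv_round_trip(self, profile, params, heavy_ensemble,
                                       tmp_path):
        ins = cl.total_insulation(heavy_ensemble, COLD)
        res = model.simulate(profile, COLD, Activity(m_rate=71.0), ins,
                             params=params, duration=30)
        path = tmp_path / "traj.csv"
        res.to_csv(path)
        back = model.SimulationResult.from_csv(path, params)
        assert np.allclose(back.temps, res.temps)
        assert np.allclose(back.wettedness, res.wettedness)
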