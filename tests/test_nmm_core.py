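import numpy as np
import pytest

from megdcm.network_models import build_model, input_bump
from megdcm._assemble import POPULATIONS, param_names
from megdcm.nmm_core import (ERPDataset, ModelParameters, PopulationState,
                             dstates, firing_rate, generate_erp, integrate,
                             nmda_gate, observe, pack_states, predict_erp,
                             steady_state, unpack_states)


class TestNonlinearities:
    def test_firing_rate_midpoint_is_half(self, params2):
        vthr = params2.constants["V_thr"]
        assert firing_rate(vthr, params2) == pytest.approx(0.5)

    def test_firing_rate_limits(self, params2):
        assert firing_rate(-1e3, params2) == pytest.approx(0.0, abs=1e-12)
        assert firing_rate(+1e3, params2) == pytest.approx(1.0, abs=1e-12)

    def test_firing_rate_one_slope_above_threshold(self, params2):
        k = params2.constants
        v = k["V_thr"] + k["s"]
        assert firing_rate(v, params2) == pytest.approx(1 / (1 + np.exp(-1)),
                                                        rel=1e-12)

    def test_firing_rate_monotone_on_grid(self, params2):
        v = np.linspace(-120, 40, 400)
        out = firing_rate(v, params2)
        assert np.all(np.diff(out) > 0)

    def test_firing_rate_rejects_nonfinite(self, params2):
        with pytest.raises(ValueError):
            firing_rate(np.nan, params2)

    def test_nmda_gate_at_zero_mv_independent_of_steepness(self):
        for a in (0.01, 0.06, 0.3):
            assert nmda_gate(0.0, a) == pytest.approx(1 / 1.2, rel=1e-12)

    def test_nmda_gate_saturates(self):
        assert nmda_gate(1e4, 0.06) == pytest.approx(1.0)

    def test_nmda_gate_hyperpolarized_value(self):
        # independent arithmetic: 1 / (1 + 0.2 * e^{4.2})
        expect = 1.0 / (1.0 + 0.2 * np.exp(4.2))
        assert nmda_gate(-70.0, 0.06) == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(0.0697, abs=5e-4)

    def test_nmda_gate_monotone_on_grid(self):
        v = np.linspace(-120, 40, 400)
        assert np.all(np.diff(nmda_gate(v, 0.06)) > 0)

    def test_nmda_gate_rejects_bad_steepness(self):
        with pytest.raises(ValueError):
            nmda_gate(0.0, 0.0)


class TestStatePacking:
    def test_round_trip(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=64)
        states = unpack_states(x)
        assert len(states) == 4 and all(len(r) == 4 for r in states)
        assert isinstance(states[0][0], PopulationState)
        np.testing.assert_array_equal(pack_states(states), x)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            unpack_states(np.zeros(30))

    def test_population_order_is_documented(self):
        assert POPULATIONS == ("ss", "sp", "ii", "dp")


def _dstates_oracle(t, x, params, spec, u, condition="angry"):
    """Independent loop-based re-implementation of the derivative field."""
    from megdcm.network_models import condition_edge_gains
    from megdcm._assemble import EXC_CONNS, INH_CONNS
    k = params.constants
    mag = params.magnitudes
    nr = len(spec.regions)
    pop = {(r, p): x[16 * ri + 4 * pi: 16 * ri + 4 * pi + 4]
           for ri, r in enumerate(spec.regions)
           for pi, p in enumerate(POPULATIONS)}
    sig = {rp: 1 / (1 + np.exp(-(s[0] - k["V_thr"]) / k["s"]))
           for rp, s in pop.items()}
    gains = condition_edge_gains(params, spec, condition)
    drive = {rp: {"a": 0.0, "g": 0.0, "n": 0.0} for rp in pop}
    for r in spec.regions:
        for a, b in EXC_CONNS:
            cn = f"self_{a}" if a == b else f"{a}_to_{b}"
            ge = mag.get(f"g_exc_{cn}_{r}", mag[f"g_exc_{cn}"])
            ratio = mag.get(f"nmda_ratio_{cn}_{r}",
                            mag.get(f"nmda_ratio_{cn}", mag["nmda_ratio"]))
            w = ge * np.exp(params.values.get(f"G:{r}:{cn}", 0.0))
            drive[(r, b)]["a"] += w * sig[(r, a)]
            drive[(r, b)]["n"] += w * ratio * sig[(r, a)]
        for a, b in INH_CONNS:
            cn = f"self_{a}" if a == b else f"{a}_to_{b}"
            gi = mag.get(f"g_inh_{cn}_{r}", mag[f"g_inh_{cn}"])
            w = gi * np.exp(params.values.get(f"G:{r}:{cn}", 0.0))
            drive[(r, b)]["g"] += w * sig[(r, a)]
    for (src, dst) in spec.forward_edges:
        ga, gn = gains[(src, dst)]
        drive[(dst, "ss")]["a"] += ga * sig[(src, "sp")]
        drive[(dst, "ss")]["n"] += gn * sig[(src, "sp")]
    for (src, dst) in spec.backward_edges:
        ga, gn = gains[(src, dst)]
        for tgt in ("sp", "ii"):
            drive[(dst, tgt)]["a"] += ga * sig[(src, "dp")]
            drive[(dst, tgt)]["n"] += gn * sig[(src, "dp")]
    kap = {r: {ch: np.exp(params.values.get(f"kappa_{ch}:{r}", 0.0))
               / k[f"tau_{ch}"] for ch in ("ampa", "gaba", "nmda")}
           for r in spec.regions}
    dx = np.zeros_like(x)
    for ri, r in enumerate(spec.regions):
        for pi, p in enumerate(POPULATIONS):
            V, ga_, gg_, gn_ = pop[(r, p)]
            m = 1 / (1 + 0.2 * np.exp(-k["a_mg"] * V))
            cin = u if (r == spec.input_region and p == "ss") else 0.0
            i0 = 16 * ri + 4 * pi
            dx[i0] = (k["g_L"] * (k["V_L"] - V) + ga_ * (k["V_E"] - V)
                      + gg_ * (k["V_I"] - V) + gn_ * m * (k["V_E"] - V)
                      + cin) / k["Cm"]
            dx[i0 + 1] = kap[r]["ampa"] * (drive[(r, p)]["a"] - ga_)
            dx[i0 + 2] = kap[r]["gaba"] * (drive[(r, p)]["g"] - gg_)
            dx[i0 + 3] = kap[r]["nmda"] * (drive[(r, p)]["n"] - gn_)
    return dx


class TestDstates:
    def test_matches_independent_reimplementation(self, spec2):
        rng = np.random.default_rng(11)
        for trial in range(5):
            vals = {n: rng.uniform(-0.4, 0.4) for n in param_names(spec2)}
            p = ModelParameters(values=vals)
            x = np.concatenate([rng.uniform(-80, -40, 1).tolist()
                                + rng.uniform(0, 2, 3).tolist()
                                for _ in range(16)])
            u = rng.uniform(0, 10)
            cond = "happy" if trial % 2 else "angry"
            got = dstates(0.0, x, p, spec2, u, cond)
            want = _dstates_oracle(0.0, x, p, spec2, u, cond)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_zero_at_fixed_point(self, params2, spec2):
        x0 = steady_state(params2, spec2)
        assert np.abs(dstates(0.0, x0, params2, spec2, 0.0)).max() < 1e-8

    def test_conductance_decay_is_exponential(self, params2, spec2):
        # clamp all firing to zero by forcing V very negative: conductances
        # then decay as g0 * exp(-kappa t); check value at t = tau is g0/e
        k = params2.constants
        x = np.zeros(64)
        x[0::4] = -1e3  # V far below threshold -> sigma(V) ~ 0
        x[1::4] = 1.0   # g_ampa = 1
        dx = dstates(0.0, x, params2, spec2, 0.0)
        # dg/dt = -kappa g at zero drive
        assert dx[1] == pytest.approx(-1.0 / k["tau_ampa"], rel=1e-6)

    def test_dimension_mismatch_rejected(self, params2, spec2):
        with pytest.raises(ValueError):
            dstates(0.0, np.zeros(32), params2, spec2, 0.0)


class TestSteadyState:
    def test_residual_below_tolerance(self, params2, spec2):
        x0 = steady_state(params2, spec2)
        assert np.abs(dstates(0.0, x0, params2, spec2, 0.0)).max() < 1e-8

    def test_deterministic(self, params2, spec2):
        a = steady_state(params2, spec2)
        b = steady_state(params2, spec2)
        np.testing.assert_array_equal(a, b)

    def test_fixed_point_under_random_log_perturbations(self, spec2):
        # property: residual < 1e-8 for |log-perturbation| <= 0.5 on the
        # declared free parameters
        from megdcm.synthetic_data import study_free_params
        rng = np.random.default_rng(17)
        free = study_free_params(spec2)
        for _ in range(10):
            vals = {n: rng.uniform(-0.5, 0.5) for n in free}
            p = ModelParameters.default(spec2).copy_with(vals)
            x0 = steady_state(p, spec2)
            assert np.abs(dstates(0.0, x0, p, spec2, 0.0)).max() < 1e-8

    def test_kappa_scaling_leaves_fixed_point_unchanged(self, params2, spec2):
        # at equilibrium dg/dt = 0 regardless of the rate constant
        x0 = steady_state(params2, spec2)
        scaled = params2.copy_with(
            {f"kappa_{ch}:{r}": 0.3 for ch in ("ampa", "gaba", "nmda")
             for r in spec2.regions})
        x1 = steady_state(scaled, spec2)
        np.testing.assert_allclose(x0, x1, atol=1e-7)

    def test_isolated_population_rests_near_leak_potential(self):
        # single region, all couplings scaled to ~zero: V should solve the
        # scalar balance; with vanishing drive that is the leak potential
        spec = build_model(1)
        p = ModelParameters.default(spec)
        p = ModelParameters(values=p.values,
                            magnitudes={**p.magnitudes,
                                        **{k: 1e-12 for k in p.magnitudes
                                           if k.startswith(("g_exc", "g_inh",
                                                            "ext_", "nmda_ratio"))}})
        x0 = steady_state(p, spec)
        V = x0[0::4]
        k = p.constants
        # residual drive comes only from the NMDA-gated leak of sigma(V)~0
        assert np.abs(V - k["V_L"]).max() < 1.0
        # 1-D bisection oracle on the scalar balance for one population
        from scipy.optimize import brentq
        def bal(v):
            return k["g_L"] * (k["V_L"] - v)
        v_oracle = brentq(bal, -120, 0)
        assert abs(v_oracle - k["V_L"]) < 1e-10


class TestIntegrate:
    def test_no_input_stays_at_fixed_point(self, params2, spec2):
        p = params2.copy_with({"input_amp": -30.0})  # amp * e^-30 ~ 0
        t = np.arange(-100.0, 300.5, 1.0)
        traj = integrate(p, spec2, None, t)
        assert np.abs(traj - traj[0]).max() < 1e-6

    def test_custom_input_fn_matches_builtin_bump(self, params2, spec2):
        t = np.arange(-100.0, 200.5, 1.0)
        traj_a = integrate(params2, spec2, None, t)
        traj_b = integrate(params2, spec2,
                           lambda tt: input_bump(tt, 64.0, 16.0, 30.0), t)
        np.testing.assert_allclose(traj_a, traj_b, atol=1e-9)

    def test_step_halving_agreement(self, params2, spec2):
        t1 = np.arange(-100.0, 500.5, 1.0)
        t01 = np.arange(-100.0, 500.05, 0.1)
        x0 = steady_state(params2, spec2)
        y1 = observe(params2, spec2, integrate(params2, spec2, None, t1), x0)
        y01 = observe(params2, spec2, integrate(params2, spec2, None, t01), x0)
        peak = np.abs(y01).max()
        diff = np.abs(y1 - y01[:, ::10]).max()
        assert diff < 1e-3 * peak

    def test_nonuniform_grid_rejected(self, params2, spec2):
        with pytest.raises(ValueError):
            integrate(params2, spec2, None, np.array([0.0, 1.0, 3.0]))

    def test_default_peak_latency_within_evoked_range(self, params2, spec2,
                                                      t_epoch):
        x0 = steady_state(params2, spec2)
        y = observe(params2, spec2,
                    integrate(params2, spec2, None, t_epoch), x0)
        peak_t = t_epoch[np.argmax(np.abs(y).max(axis=0))]
        assert 80 <= peak_t <= 250

    def test_nmda_rate_speeds_conductance_response(self, params2, spec2,
                                                   t_epoch):
        # faster NMDA rate constant -> earlier NMDA conductance peak
        t = np.arange(-100.0, 600.5, 1.0)
        fast = params2.copy_with({f"kappa_nmda:{r}": 0.5
                                  for r in spec2.regions})
        tr0 = integrate(params2, spec2, None, t)
        tr1 = integrate(fast, spec2, None, t)
        # NMDA conductance of EV sp population (region 0, pop 1, field 3)
        g0 = tr0[:, 4 * 1 + 3] - tr0[0, 4 * 1 + 3]
        g1 = tr1[:, 4 * 1 + 3] - tr1[0, 4 * 1 + 3]
        assert t[np.abs(g1).argmax()] < t[np.abs(g0).argmax()]


class TestGenerateErp:
    def test_noiseless_is_deterministic(self, params2, spec2, t_fit):
        a = generate_erp(params2, spec2, ("angry", "happy"), t_fit, 0.0, 1)
        b = generate_erp(params2, spec2, ("angry", "happy"), t_fit, 0.0, 2)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)

    def test_seeded_noise_reproducible(self, params2, spec2, t_fit):
        a = generate_erp(params2, spec2, ("angry",), t_fit, 0.5, 42)
        b = generate_erp(params2, spec2, ("angry",), t_fit, 0.5, 42)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)

    def test_observation_gain_scales_signal_linearly(self, params2, spec2,
                                                     t_fit):
        doubled = params2.copy_with({f"obs_gain:{r}": np.log(2.0)
                                     for r in spec2.regions})
        y1 = predict_erp(params2, spec2, ("angry",), t_fit)
        y2 = predict_erp(doubled, spec2, ("angry",), t_fit)
        np.testing.assert_allclose(y2, 2.0 * y1, rtol=1e-9, atol=1e-12)

    def test_null_emotion_modulation_equates_conditions(self, params2, spec2,
                                                        t_fit):
        y = predict_erp(params2, spec2, ("angry", "happy"), t_fit)
        np.testing.assert_allclose(y[0], y[1], atol=1e-12)

    def test_nonnull_modulation_separates_conditions(self, params2, spec2,
                                                     t_fit):
        p = params2.copy_with({f"B:{a}->{b}": 0.3 for a, b in spec2.edges})
        y = predict_erp(p, spec2, ("angry", "happy"), t_fit)
        assert np.abs(y[0] - y[1]).max() > 0.1

    def test_input_off_gives_identically_zero_observation(self, params2,
                                                          spec2, t_fit):
        p = params2.copy_with({"input_amp": -30.0})
        y = predict_erp(p, spec2, ("angry",), t_fit)
        assert np.abs(y).max() < 1e-6

    def test_unknown_condition_rejected(self, params2, spec2, t_fit):
        with pytest.raises(ValueError):
            generate_erp(params2, spec2, ("neutral",), t_fit, 0.0, 0)

    def test_dataset_long_format_schema(self, params2, spec2, t_fit):
        erp = generate_erp(params2, spec2, ("angry",), t_fit, 0.1, 0,
                           subject_id="s1", group="TRD", session="baseline")
        df = erp.to_long()
        assert list(df.columns) == ["subject_id", "group", "session",
                                    "condition", "region", "time_ms",
                                    "amplitude"]
        assert len(df) == 4 * t_fit.size
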