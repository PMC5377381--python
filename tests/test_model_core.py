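import numpy as np
import pytest
from scipy.optimize import root

import bacfire as bf

from oracles import random_states, rhs_5d_oracle


def test_ohmic_currents_vanish_at_reversal(params):
    """Each ohmic current is zero when its compartment voltage sits at the
    corresponding reversal potential, over a grid of the other variables."""
    s, d = params.soma, params.dend
    for w in (0.0, 0.3, 1.0):
        for vd in (-80.0, -20.0, 30.0):
            cb = bf.membrane_currents([s.E_Na, w, vd, 0.5, 0.5], params)
            assert cb.I_Na == pytest.approx(0.0, abs=1e-12)
            cb = bf.membrane_currents([s.E_K, w, vd, 0.5, 0.5], params)
            assert cb.I_K == pytest.approx(0.0, abs=1e-12)
            cb = bf.membrane_currents([s.E_SL, w, vd, 0.5, 0.5], params)
            assert cb.I_SL == pytest.approx(0.0, abs=1e-12)
        cb = bf.membrane_currents([-60.0, w, d.E_Ca, 0.5, 0.5], params)
        assert cb.I_Ca == pytest.approx(0.0, abs=1e-12)
        cb = bf.membrane_currents([-60.0, w, d.E_DL, 0.5, 0.5], params)
        assert cb.I_DL == pytest.approx(0.0, abs=1e-12)


def test_coupling_current_antisymmetry(params):
    """I_DS vanishes for equipotential chambers and is antisymmetric under
    exchange of the two voltages."""
    for v in (-70.0, -30.0, 10.0):
        assert bf.membrane_currents([v, 0.1, v, 0.2, 0.8], params).I_DS == 0.0
    a = bf.membrane_currents([-60.0, 0.1, -20.0, 0.2, 0.8], params).I_DS
    b = bf.membrane_currents([-20.0, 0.1, -60.0, 0.2, 0.8], params).I_DS
    assert a == pytest.approx(-b)
    assert a == pytest.approx(params.coupling.g_c * 40.0)


def test_blocked_channel_gives_zero_ca_current(params, rng):
    p0 = params.with_g_ca(0.0)
    for y in random_states(rng, 20):
        assert bf.membrane_currents(y, p0).I_Ca == 0.0


def test_rhs_matches_independent_transcription(params, rng):
    """rhs_5d at 1000 random states matches a second, independently coded
    transcription of the current-balance equations to 1e-12 relative."""
    states = random_states(rng, 1000)
    expected = rhs_5d_oracle(states, I_S=7.0, I_D=-3.0, params=params)
    got = np.stack([bf.rhs_5d(0.0, y, 7.0, -3.0, params) for y in states])
    np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)


def test_rhs_vanishes_at_independent_root(params):
    """An equilibrium found by an independent multidimensional root solver
    has |rhs| below 1e-10."""
    sol = root(lambda y: bf.rhs_5d(0.0, y, 10.0, 5.0, params),
               [-65.0, 0.01, -65.0, 0.0, 1.0], method="hybr")
    resid = np.max(np.abs(bf.rhs_5d(0.0, sol.x, 10.0, 5.0, params)))
    assert resid < 1e-10


def test_w_at_target_has_zero_derivative(params):
    v = -48.0
    w_eq = float(bf.w_inf(v, params))
    dy = bf.rhs_5d(0.0, [v, w_eq, -60.0, 0.1, 0.9], 0.0, 0.0, params)
    assert dy[1] == pytest.approx(0.0, abs=1e-15)


def test_voltage_dynamics_decouple_from_ca_gates_when_blocked(params, rng):
    """With g_Ca = 0 the (V_S, w, V_D) derivatives are independent of n and
    h, i.e. the voltage dynamics equal the same model with the Ca gate
    equations removed."""
    p0 = params.with_g_ca(0.0)
    for y in random_states(rng, 10):
        y2 = y.copy()
        y2[3], y2[4] = rng.uniform(0, 1, 2)
        d1 = bf.rhs_5d(0.0, y, 4.0, 9.0, p0)
        d2 = bf.rhs_5d(0.0, y2, 4.0, 9.0, p0)
        np.testing.assert_allclose(d1[[0, 1, 2]], d2[[0, 1, 2]], rtol=0, atol=1e-14)
        # the gates still relax towards their dendritic-voltage targets
        assert d2[3] == pytest.approx(
            (float(bf.n_inf(y[2], p0)) - y2[3]) / p0.dend.tau_n)


def test_gating_stays_in_unit_interval_along_trajectory(params):
    """w, n, h remain in [0, 1] along a strongly driven trajectory."""
    res = bf.run_step("5d", params, 40.0, 80.0, stim_duration=400.0)
    for idx in (1, 3, 4):
        assert res.y[idx].min() >= 0.0
        assert res.y[idx].max() <= 1.0


def test_parameter_registry_round_trip(tmp_path, params):
    """Dump/load preserves every constant; unknown keys are rejected."""
    path = tmp_path / "p.json"
    bf.dump_parameters(params, path)
    again = bf.load_parameters(path)
    assert again == params
    import json
    flat = json.loads(path.read_text())
    flat["soma.g_Kx"] = 1.0
    path.write_text(json.dumps(flat))
    with pytest.raises(KeyError, match="unknown registry key"):
        bf.load_parameters(path)


def test_invariant_violations_raise(params):
    with pytest.raises(ValueError):
        bf.SomaticParameters(C_m=-1.0)
    with pytest.raises(ValueError):
        bf.CouplingParameters(p=1.0)
    with pytest.raises(ValueError):
        bf.DendriticParameters(tau_n=0.0)
    # a blocked channel is a *valid* configuration
    bf.DendriticParameters(g_Ca=0.0)
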