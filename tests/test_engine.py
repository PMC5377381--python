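import numpy as np
import pytest

import bacfire as bf
from bacfire.engine import finite_difference_jacobian


def test_resting_state_is_a_refined_stable_root(params, rest_5d):
    resid = np.max(np.abs(bf.rhs_5d(0.0, rest_5d, 0.0, 0.0, params)))
    assert resid < 1e-10
    J = finite_difference_jacobian(
        lambda y: bf.rhs_5d(0.0, y, 0.0, 0.0, params), rest_5d)
    assert np.max(np.linalg.eigvals(J).real) < 0.0


def test_resting_state_matches_long_relaxation(params, rest_5d):
    """The refined equilibrium agrees with the t→∞ limit of a 2000 ms
    relaxation to better than 1e-6 mV."""
    proto = bf.StimulusProtocol(duration=2000.0)
    res = bf.integrate("5d", params, proto, initial=rest_5d + 1e-3)
    assert abs(res.V_S[-1] - rest_5d[0]) < 1e-6


def test_subthreshold_equilibria_are_stable_below_rheobase(params):
    """Below the somatic onset every constant-input equilibrium has strictly
    negative leading eigenvalue."""
    for i_s in (0.0, 10.0, 25.0, 33.0):
        eq = bf.find_resting_state("5d", params, I_S=i_s)
        J = finite_difference_jacobian(
            lambda y: bf.rhs_5d(0.0, y, i_s, 0.0, params), eq)
        assert np.max(np.linalg.eigvals(J).real) < 0.0


def test_no_stable_rest_above_threshold_is_an_error(params):
    with pytest.raises(bf.NoStableRestingState):
        bf.find_resting_state("5d", params, I_S=50.0)


def test_equilibrium_persists_under_zero_input(params, rest_5d):
    """From rest with no input, V_S stays constant to within 10×abs_tol over
    500 ms."""
    settings = bf.SolverSettings(output_dt=0.05)
    proto = bf.StimulusProtocol(duration=500.0)
    res = bf.integrate("5d", params, proto, rest_5d, settings)
    assert np.max(np.abs(res.V_S - rest_5d[0])) < 10 * settings.abs_tol


def test_determinism_bit_identical(params, rest_5d):
    proto = bf.StimulusProtocol(duration=200.0, dend=bf.step(75.0, 10.0))
    a = bf.integrate("5d", params, proto, rest_5d)
    b = bf.integrate("5d", params, proto, rest_5d)
    np.testing.assert_array_equal(a.y, b.y)


def test_suprathreshold_step_settles_into_periodic_orbit(params, rest_5d):
    """A suprathreshold somatic step produces repetitive APs: the last five
    ISIs have a coefficient of variation below 1e-3."""
    res = bf.run_step("5d", params, 40.0, 0.0, stim_duration=1200.0,
                      initial=rest_5d, settings=bf.SolverSettings())
    train = bf.detect_spikes(res.t, res.V_S)
    isis = train.isis[-5:]
    assert len(train) > 10
    assert np.std(isis) / np.mean(isis) < 1e-3


def test_grid_refinement_only_moves_spikes_by_interpolation(params, rest_5d):
    """Refining output_dt changes detected spike times by less than half the
    coarser grid spacing."""
    coarse = bf.run_step("5d", params, 40.0, 0.0, stim_duration=300.0,
                         initial=rest_5d, settings=bf.SolverSettings(output_dt=0.05))
    fine = bf.run_step("5d", params, 40.0, 0.0, stim_duration=300.0,
                       initial=rest_5d, settings=bf.SolverSettings(output_dt=0.01))
    tc = bf.detect_spikes(coarse.t, coarse.V_S).times
    tf = bf.detect_spikes(fine.t, fine.V_S).times
    assert len(tc) == len(tf)
    assert np.max(np.abs(tc - tf)) < 0.025


def test_stimulus_breakpoints_are_exact(params, rest_5d):
    """The integrator restarts at waveform discontinuities: the sample just
    before a pulse onset is still at rest, and the protocol reports its
    breakpoints."""
    proto = bf.StimulusProtocol(duration=100.0, dend=bf.pulse(80.0, 30.0, 20.0))
    np.testing.assert_allclose(proto.breakpoints(), [30.0, 50.0])
    res = bf.integrate("5d", params, proto, rest_5d,
                       bf.SolverSettings(output_dt=0.01))
    i_on = int(round(30.0 / 0.01))
    assert abs(res.V_D[i_on - 1] - rest_5d[2]) < 1e-6
    assert res.V_D[i_on + 200] > rest_5d[2] + 1.0


def test_derived_traces_recomputed_from_states(params, rest_5d):
    res = bf.run_step("5d", params, 0.0, 75.0, stim_duration=100.0, initial=rest_5d)
    d = params.dend
    np.testing.assert_array_equal(
        res.I_Ca, d.g_Ca * res.y[3] * res.y[4] * (res.y[2] - d.E_Ca))
    assert np.all(np.diff(res.t) > 0)


def test_trace_export_round_trip(tmp_path, params, rest_5d):
    res = bf.run_step("5d", params, 0.0, 75.0, stim_duration=50.0, initial=rest_5d)
    out = tmp_path / "trace.csv"
    res.save(out)
    import pandas as pd
    df = pd.read_csv(out)
    assert list(df.columns) == ["time", "V_S", "w", "V_D", "n", "h", "I_Ca", "I_DS"]
    assert (tmp_path / "trace.manifest.json").exists()


def test_protocol_validation():
    with pytest.raises(ValueError):
        bf.StimulusProtocol(duration=5.0, soma=bf.step(10.0, onset=10.0))
    with pytest.raises(ValueError):
        bf.pulse(10.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        bf.SolverSettings(rel_tol=0.0)
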