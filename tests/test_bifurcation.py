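import numpy as np
import pytest

import bacfire as bf
from bacfire.bifurcation import (EquilibriumBranch, LimitCycleBranch,
                                 classify_onset)


@pytest.fixture(scope="module")
def somatic_branch(params):
    return bf.continue_equilibria("5d", params, "I_S", (0.0, 45.0))


def test_branch_points_are_roots(params, somatic_branch):
    br = somatic_branch
    take = np.linspace(0, len(br.params_values) - 1, 25).astype(int)
    for i in take:
        resid = np.max(np.abs(bf.rhs_5d(0.0, br.states[i],
                                        br.params_values[i], 0.0, params)))
        assert resid < 1e-10


def test_branch_matches_independent_resting_solver(params, somatic_branch):
    """Branch states agree with find_resting_state at 10 interior parameter
    values where a stable equilibrium exists."""
    br = somatic_branch
    stable_mask = br.stable & (br.params_values > 0.5) & (br.params_values < 33.0)
    idx = np.nonzero(stable_mask)[0]
    for i in idx[np.linspace(0, len(idx) - 1, 10).astype(int)]:
        eq = bf.find_resting_state("5d", params, I_S=br.params_values[i])
        np.testing.assert_allclose(br.states[i], eq, atol=1e-6)


def test_stability_flags_match_eigenvalues(somatic_branch):
    br = somatic_branch
    np.testing.assert_array_equal(br.stable, br.leading_eig < 0.0)


def test_fold_has_zero_eigenvalue_and_no_hopf_below(params, somatic_branch):
    """The stable equilibrium disappears at a fold (zero eigenvalue) with no
    Hopf crossing on the branch below it."""
    br = somatic_branch
    assert br.folds, "no fold found on the somatic branch"
    fold = br.folds[0]
    assert fold["min_abs_eig"] < 1e-6
    # lower branch = points before the first parameter reversal
    i_turn = int(np.nonzero(np.diff(br.params_values) < 0)[0][0])
    # stability is lost only at the fold itself, never before it
    assert br.stable[:i_turn].all()


def test_invalid_sweep_parameter_rejected(params):
    with pytest.raises(ValueError, match="sweep_param"):
        bf.continue_equilibria("5d", params, "g_Ca", (0.0, 1.0))


def _synthetic_branches(exponent=0.5, lam_c=10.0):
    """Constructed equilibrium + cycle data with exact power-law onset."""
    lam = np.linspace(9.0, 12.0, 61)
    eq = EquilibriumBranch(
        sweep_param="I_S", params_values=np.linspace(9.0, lam_c, 30),
        states=np.zeros((30, 5)), leading_eig=-np.ones(30),
        stable=np.ones(30, dtype=bool),
        folds=[{"param": lam_c, "state": np.zeros(5), "min_abs_eig": 1e-9}])
    above = lam > lam_c
    f = np.where(above, 40.0 * np.maximum(lam - lam_c, 1e-12) ** exponent, np.nan)
    period = 1000.0 / f
    lc = LimitCycleBranch(sweep_param="I_S", direction="up", params_values=lam,
                          v_max=np.where(above, 20.0, -60.0),
                          v_min=np.full_like(lam, -60.0),
                          period=period, exists=above)
    return eq, lc


def test_constructed_sqrt_branch_classified_snic():
    """Synthetic branch data with exact sqrt scaling yields a SNIC whose
    fitted exponent is 0.5 to 1e-3."""
    eq, lc = _synthetic_branches(exponent=0.5)
    events = classify_onset(eq, lc, lc, step_size=0.05)
    assert [e.kind for e in events] == ["SNIC"]
    assert events[0].evidence["scaling"]["exponent"] == pytest.approx(0.5, abs=1e-3)


def test_constructed_linear_branch_not_snic():
    """An onset with linear (exponent 1) rate growth is not called SNIC."""
    eq, lc = _synthetic_branches(exponent=1.0)
    events = classify_onset(eq, lc, lc, step_size=0.05)
    assert events[0].kind == "unclassified"
    assert "scaling" in events[0].evidence


def test_ambiguous_evidence_never_silently_guessed():
    eq, lc = _synthetic_branches()
    empty = LimitCycleBranch(sweep_param="I_S", direction="up",
                             params_values=lc.params_values,
                             v_max=lc.v_min, v_min=lc.v_min,
                             period=np.full_like(lc.period, np.nan),
                             exists=np.zeros_like(lc.exists))
    events = classify_onset(eq, empty, empty, step_size=0.05)
    assert all(e.kind == "unclassified" for e in events)
    assert all(e.evidence for e in events)


def test_cycle_sweep_records_extrema_and_period(params, rest_5d):
    """At a suprathreshold value the sweep's period matches the mean ISI of
    an independent long simulation to < 0.1 ms."""
    vals = np.array([38.0, 40.0])
    lc = bf.sweep_limit_cycles("5d", params, "I_S", vals, "up",
                               settle=400.0, measure=600.0)
    assert lc.exists.all()
    assert np.all(lc.v_max > lc.v_min)
    res = bf.run_step("5d", params, 40.0, 0.0, stim_duration=2000.0,
                      initial=rest_5d)
    train = bf.detect_spikes(res.t, res.V_S)
    independent = float(np.mean(train.isis[-10:]))
    assert abs(lc.period[list(vals).index(40.0)] - independent) < 0.1
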