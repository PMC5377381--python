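import numpy as np
import pytest

import bacfire as bf


def _sawtooth(n_teeth, period=50.0, dt=0.1, lo=-70.0, hi=20.0):
    t = np.arange(0, n_teeth * period, dt)
    phase = (t % period) / period
    return t, lo + (hi - lo) * phase


def test_constant_subthreshold_trace_has_no_spikes():
    t = np.arange(0, 100, 0.1)
    train = bf.detect_spikes(t, np.full_like(t, -60.0))
    assert len(train) == 0
    assert train.f_S == 0.0


def test_empty_trace_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        bf.detect_spikes(np.array([]), np.array([]))


def test_sawtooth_crossings_counted_once_each():
    t, v = _sawtooth(3)
    train = bf.detect_spikes(t, v, threshold=0.0, refractory=2.0)
    assert len(train) == 3


def test_refractory_suppresses_rapid_recrossings():
    t = np.arange(0, 10, 0.01)
    v = -60 + 70 * np.sin(2 * np.pi * t / 1.0)   # 1 ms period, crosses 0 often
    train = bf.detect_spikes(t, v, threshold=0.0, refractory=2.0)
    assert np.all(np.diff(train.times) >= 2.0)


def test_periodic_train_f_inst_is_reciprocal_isi():
    period = 8.0
    times = np.arange(0.0, 400.0, period)
    t = np.arange(0, 400, 0.01)
    v = np.full_like(t, -65.0)
    for ts in times:
        v[np.abs(t - ts) < 0.3] = 20.0
    train = bf.detect_spikes(t, v)
    np.testing.assert_allclose(train.f_inst, 1000.0 / period, rtol=1e-2)


def test_average_rate_counting():
    train = bf.SpikeTrain(times=np.linspace(50, 950, 10), window=(0.0, 1000.0))
    assert bf.average_rate(train, (0.0, 1000.0)) == pytest.approx(10.0)
    with pytest.raises(ValueError, match="window"):
        bf.average_rate(train, (100.0, 100.0))


def test_average_rate_matches_mean_f_inst_for_periodic_train():
    """For a perfectly periodic train the count rate equals the mean
    instantaneous rate up to edge effects of less than one period."""
    period = 10.0
    times = np.arange(0.0, 1000.0, period)
    train = bf.SpikeTrain(times=times, window=(0.0, 1000.0 - period))
    f_count = train.f_S       # 100 spikes in 990 ms = 101.01 Hz
    f_inst = np.mean(train.f_inst)   # exactly 100 Hz
    # edge effect: the window is short of a whole period at its end
    edge = 1000.0 * period / (1000.0 - period) ** 2 * len(train)
    assert abs(f_count - f_inst) <= edge


def test_burst_summary_constructed_fixture():
    """ISIs [5,5,5,20,20,20,20] ms give peak 200 Hz, plateau 50 Hz, ratio 4."""
    isis = np.array([5.0, 5, 5, 20, 20, 20, 20])
    times = np.concatenate([[0.0], np.cumsum(isis)])
    train = bf.SpikeTrain(times=times, window=(0.0, float(times[-1])))
    s = bf.summarize_burst(train)
    assert s.peak_f_inst == pytest.approx(200.0)
    assert s.plateau_f_inst == pytest.approx(50.0)
    assert s.ratio == pytest.approx(4.0)
    assert s.adapting


def test_periodic_train_is_not_adapting():
    times = np.arange(0.0, 500.0, 10.0)
    train = bf.SpikeTrain(times=times, window=(0.0, 490.0))
    s = bf.summarize_burst(train)
    assert s.ratio == pytest.approx(1.0)
    assert not s.adapting


def test_burst_summary_needs_three_spikes():
    train = bf.SpikeTrain(times=np.array([0.0, 10.0]), window=(0.0, 10.0))
    with pytest.raises(ValueError, match="insufficient spikes"):
        bf.summarize_burst(train)


def test_blocked_channel_yields_no_ca_events(params, rest_5d):
    res = bf.run_step("5d", params.with_g_ca(0.0), 0.0, 80.0,
                      stim_duration=400.0)
    assert bf.detect_ca_spikes(res) == []


def test_dendritic_step_evokes_one_prompt_ca_event(params, rest_5d):
    """A single suprathreshold dendritic step with the active channel evokes
    exactly one episode starting within 50 ms of stimulus onset."""
    res = bf.run_step("5d", params, 0.0, 75.0, stim_duration=500.0,
                      initial=rest_5d)
    events = bf.detect_ca_spikes(res)
    assert len(events) == 1
    onset = res.protocol.dend.onset
    assert 0.0 <= events[0].onset - onset < 50.0
    assert events[0].peak_V_D > params.analysis.ca_spike_vd_threshold


def test_larger_g_ca_gives_longer_ca_event(params, rest_5d):
    """Doubling the Ca conductance from half the registry value strictly
    prolongs the pulse-evoked Ca spike."""
    durations = {}
    for g in (params.dend.g_Ca / 2, params.dend.g_Ca):
        rep = bf.pulse_protocol("5d", params.with_g_ca(g), amplitude=100.0,
                                total=600.0)
        assert len(rep.ca_events) == 1
        durations[g] = rep.ca_events[0].duration
    assert durations[params.dend.g_Ca] > durations[params.dend.g_Ca / 2]


def test_spike_count_robust_to_threshold_band(params, rest_5d):
    """Spike counts for a default-parameter run are unchanged for any
    detection threshold in the plausible -20..0 mV band."""
    res = bf.run_step("5d", params, 40.0, 0.0, stim_duration=500.0,
                      initial=rest_5d)
    counts = {thr: len(bf.detect_spikes(res.t, res.V_S, threshold=thr))
              for thr in (-20.0, -10.0, -5.0, 0.0)}
    assert len(set(counts.values())) == 1
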