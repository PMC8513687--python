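"""Generator behaviour: calibrated fiducials, determinism, refractory
capture, radial gradients, and the time-lapse adhesion model."""

import numpy as np
import pytest
from pydantic import ValidationError as PydanticValidationError

import quadcell as qc
from quadcell.errors import ValidationError


# ------------------------------------------------------------------ optical

@pytest.mark.parametrize("preset", ["PACED_BEAT", "BASELINE_0NM", "ISO_3NM", "ISO_10NM"])
def test_optical_round_trip_recovers_requested_fiducials(preset):
    """Generated beat -> extractor returns the requested fiducials within
    2 sample periods at zero noise, for every preset."""
    beat = qc.beat_params(preset, jitter_sd_ms=0.0)
    trace = qc.synth_optical_beat(beat, sampling_rate_hz=1000.0)
    train = qc.StimTrain(onsets_ms=np.array([0.0]))
    (feat,) = qc.extract_optical_features(trace, train)
    tol = 2 * trace.dt_ms
    assert feat.ct_prime_pks_ms == pytest.approx(beat.ct_prime_pk_ms, abs=tol)
    assert feat.ct_pks_ms == pytest.approx(beat.ct_pk_ms, abs=tol)
    assert feat.rx_prime_pks_ms == pytest.approx(beat.rx_prime_pk_ms, abs=tol)
    assert feat.t_d_ms == pytest.approx(beat.t_d_ms, abs=tol)


def test_realized_waveform_fiducials_match_directly(baseline_beat):
    """Argmax / extreme-derivative locations of the raw sampled waveform
    (no smoothing) sit at the requested times within one sample."""
    fs = 2000.0
    trace = qc.synth_optical_beat(baseline_beat, sampling_rate_hz=fs)
    x = trace.samples
    dt = trace.dt_ms
    pk = np.argmax(x)
    assert pk * dt == pytest.approx(baseline_beat.ct_pk_ms, abs=dt)
    d = np.gradient(x, dt)
    assert np.argmax(d[: pk + 1]) * dt == pytest.approx(
        baseline_beat.ct_prime_pk_ms, abs=dt
    )
    assert (pk + np.argmin(d[pk:])) * dt == pytest.approx(
        baseline_beat.rx_prime_pk_ms, abs=dt
    )
    below = np.flatnonzero(x[pk:] < 0.1 * x[pk])
    assert (pk + below[0]) * dt == pytest.approx(baseline_beat.t_d_ms, abs=dt)
    # baseline is exactly zero before the stimulus
    trace2 = qc.synth_optical_beat(baseline_beat, stim_ms=100.0, sampling_rate_hz=fs)
    assert np.all(trace2.samples[: int(100 / trace2.dt_ms)] == 0.0)


def test_zero_amplitude_beat_is_flat(baseline_beat):
    beat = baseline_beat.model_copy(update={"amplitude_au": 0.0})
    trace = qc.synth_optical_beat(beat)
    assert np.all(trace.samples == 0.0)


def test_fiducial_ordering_enforced():
    with pytest.raises(PydanticValidationError):
        qc.BeatParams(ct_prime_pk_ms=200.0, ct_pk_ms=190.0,
                      rx_prime_pk_ms=300.0, t_d_ms=450.0)


# ---------------------------------------------------------------- potential

def test_twave_apex_at_exact_fpd(baseline_ep, single_pulse_train):
    """Noiseless trace: T-wave apex sits exactly FPD after the spike trough."""
    fs = 10000.0  # fine sampling to read the continuous-time construction
    trace = qc.synth_extracellular_trace(baseline_ep, single_pulse_train, fs)
    x = trace.samples
    dt = trace.dt_ms
    blank = int(10 / dt)
    spike = blank + np.argmin(x[blank:])
    assert spike * dt == pytest.approx(baseline_ep.t_ap_ms, abs=dt)
    gap = spike + int(60 / dt)
    apex = gap + np.argmax(x[gap:])
    assert (apex - spike) * dt == pytest.approx(baseline_ep.fpd_ms, abs=2 * dt)


def test_spike_amplitude_round_trip(baseline_ep, single_pulse_train):
    trace = qc.synth_extracellular_trace(baseline_ep, single_pulse_train, 5000.0)
    (feat,) = qc.extract_potential_features(trace, single_pulse_train)
    assert feat.spike_amplitude_uv == pytest.approx(
        baseline_ep.spike_amp_uv, rel=0.10
    )


def test_empty_train_gives_pure_noise():
    ep = qc.ep_params("BASELINE_0NM", noise_sd_uv=5.0)
    train = qc.StimTrain(onsets_ms=np.array([]))
    trace = qc.synth_extracellular_trace(ep, train, seed=7, duration_ms=500.0)
    assert trace.samples.std() == pytest.approx(5.0, rel=0.2)
    assert abs(trace.samples.mean()) < 1.0


def test_same_seed_identical_traces(single_pulse_train):
    ep = qc.ep_params("BASELINE_0NM", noise_sd_uv=10.0)
    a = qc.synth_extracellular_trace(ep, single_pulse_train, seed=3)
    b = qc.synth_extracellular_trace(ep, single_pulse_train, seed=3)
    c = qc.synth_extracellular_trace(ep, single_pulse_train, seed=4)
    assert np.array_equal(a.samples, b.samples)
    assert not np.array_equal(a.samples, c.samples)


def test_artefact_must_dominate_spike():
    with pytest.raises(PydanticValidationError):
        qc.EPParams(t_ap_ms=10.0, spike_amp_uv=100.0, fpd_ms=200.0,
                    artefact_amp_uv=50.0)


# ---------------------------------------------------------- paced recording

def _one_pixel_recording(params, frequency_hz, n_pulses=10):
    proto = qc.StimProtocol(amplitude_uA=8.0, pulse_width_ms=1.2,
                            frequency_hz=frequency_hz, n_pulses=n_pulses)
    # margin past the last pulse so its beat upstroke is fully recorded
    duration = n_pulses * proto.period_ms + 500.0
    return qc.synth_paced_recording(params, proto, duration, pixels=[0],
                                    geometry=qc.ArrayGeometry(rows=2, cols=2))


def test_alternating_beats_at_5hz(paced_monolayer):
    """ARP 222 ms at 5 Hz pacing: beats on alternating pulses only."""
    params = paced_monolayer.model_copy(update={"arp_ms": 222.0})
    rec = _one_pixel_recording(params, 5.0, n_pulses=10)
    result = qc.detect_captures(rec.optical[0], rec.train)
    assert result.n_captured == 5
    assert result.capture_rate == 0.5


def test_every_pulse_beats_at_4hz(paced_monolayer):
    params = paced_monolayer.model_copy(update={"arp_ms": 222.0})
    rec = _one_pixel_recording(params, 4.0, n_pulses=8)
    result = qc.detect_captures(rec.optical[0], rec.train)
    assert result.capture_rate == 1.0


def test_negative_radial_slope_gives_periphery_first(paced_monolayer, small_geometry):
    params = paced_monolayer.model_copy(update={
        "mech_onset_intercept_ms": 40.0,
        "mech_onset_radial_slope_ms_per_um": -0.05,
    })
    proto = qc.StimProtocol(amplitude_uA=8.0, pulse_width_ms=1.2,
                            frequency_hz=1.0, n_pulses=2)
    rec = qc.synth_paced_recording(params, proto, 2000.0, geometry=small_geometry)
    corner, centre = 0, small_geometry.pixel_id(3, 3)
    onset = {}
    for pid in (corner, centre):
        x = rec.optical[pid].samples
        onset[pid] = np.flatnonzero(x > 0.05 * x.max())[0]
    assert onset[corner] < onset[centre]


def test_duration_must_cover_train(paced_monolayer):
    proto = qc.StimProtocol(amplitude_uA=8.0, pulse_width_ms=1.2,
                            frequency_hz=1.0, n_pulses=5)
    with pytest.raises(ValidationError):
        qc.synth_paced_recording(paced_monolayer, proto, duration_ms=3000.0,
                                 pixels=[0], geometry=qc.ArrayGeometry(rows=2, cols=2))


def test_recording_determinism():
    params = qc.monolayer_params("PACED_BEAT", seed=11)
    proto = qc.stim_protocol("PACED_BEAT", n_pulses=3)
    g = qc.ArrayGeometry(rows=2, cols=2)
    kwargs = dict(duration_ms=6000.0, geometry=g, potential_pixels=[1])
    a = qc.synth_paced_recording(params, proto, **kwargs)
    b = qc.synth_paced_recording(params, proto, **kwargs)
    assert np.array_equal(a.optical[0].samples, b.optical[0].samples)
    assert np.array_equal(a.potential[1].samples, b.potential[1].samples)


def test_capture_pattern_matches_model_on_grid(paced_monolayer):
    """Generated recordings capture exactly as the refractory model predicts
    over a grid of (ARP, frequency) pairs."""
    for arp in (100.0, 222.0, 340.0):
        for freq in (0.5, 2.0, 4.0, 5.0, 9.0):
            params = paced_monolayer.model_copy(update={"arp_ms": arp})
            rec = _one_pixel_recording(params, freq, n_pulses=20)
            result = qc.detect_captures(rec.optical[0], rec.train)
            expected = qc.capture_pattern(arp, rec.train.onsets_ms).sum() / 20
            assert result.capture_rate == pytest.approx(expected)


# -------------------------------------------------------------- time-lapse

def test_timelapse_plateaus_match_cell_type(small_geometry):
    ts = np.arange(0.0, 144.0, 12.0)
    geom = qc.DEFAULT_GEOMETRY
    _, fib = qc.synth_timelapse(qc.timelapse_params("FIBROBLAST_TIMELAPSE"), geom, ts)
    assert 1.0e6 <= fib.frames[-1].max() <= 1.2e6
    _, card = qc.synth_timelapse(
        qc.timelapse_params("CARDIO_SPHEROID_TIMELAPSE"), geom, np.arange(0.0, 96.0, 12.0)
    )
    assert 0.5e6 <= card.frames[-1].max() <= 0.8e6


def test_zero_aggregates_constant_baseline(small_geometry):
    params = qc.TimelapseParams(impedance_base_ohm=2e5, impedance_plateau_ohm=1e6)
    op, im = qc.synth_timelapse(params, small_geometry, np.array([0.0, 1.0, 2.0]))
    assert np.all(op.frames == 0.0)
    assert np.all(im.frames == 2e5)


def test_adhesion_monotone_before_detachment(small_geometry):
    params = qc.TimelapseParams(
        aggregates=(qc.AggregateParams(centre_rc=(3, 3), seed_time_h=0.0,
                                       initial_radius_um=120.0,
                                       growth_rate_um_per_h=5.0),),
        impedance_base_ohm=2e5, impedance_plateau_ohm=1e6,
    )
    _, im = qc.synth_timelapse(params, small_geometry, np.arange(0.0, 48.0, 4.0))
    assert np.all(np.diff(im.frames, axis=0) >= -1e-9)


def test_aggregate_centre_outside_grid_rejected(small_geometry):
    params = qc.TimelapseParams(
        aggregates=(qc.AggregateParams(centre_rc=(99, 0), seed_time_h=0.0,
                                       initial_radius_um=100.0,
                                       growth_rate_um_per_h=1.0),),
        impedance_base_ohm=2e5, impedance_plateau_ohm=1e6,
    )
    with pytest.raises(ValidationError):
        qc.synth_timelapse(params, small_geometry, np.array([0.0, 1.0]))
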