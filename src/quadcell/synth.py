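"""Synthetic multimodal recordings of paced cardiac monolayers.

Generates the four data modalities the analysis pipeline consumes:

* per-pixel optical intensity transients of paced beats, built from a
  smooth rise/decay waveform *calibrated* so that its realized fiducials
  (contraction-slope peak CT', contraction peak CT, relaxation-slope peak
  RX', 10 %-decay cycle duration T_d) land exactly at the requested times;
* extracellular potential traces containing biphasic stimulation artefacts
  (~mV), evoked spikes (~100 uV) at a conduction delay, and T-waves;
* full-array paced recordings with a deterministic refractory capture rule
  and a radial mechanical-onset gradient (periphery-first contraction);
* time-lapse opacity and impedance frame series of aggregate seeding,
  spreading, adhesion and enzymatic detachment.

All randomness derives from the single integer seed carried by the
parameter object; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ValidationError
from .geometry import ArrayGeometry, DEFAULT_GEOMETRY
from .imaging import FrameSeries, IMPEDANCE, OPACITY
from .pacing import capture_pattern
from .stim import StimProtocol, StimTrain, generate_stimulation_train
from .trace import OPTICAL, POTENTIAL, PixelTrace

DECAY_FRACTION = 0.1  # T_d: first decay below this fraction of beat peak


# --------------------------------------------------------------------------
# parameter models
# --------------------------------------------------------------------------

class BeatParams(BaseModel):
    """Fiducials of one opto-mechanical beat transient.

    All times are measured from the stimulus; ``jitter_sd_ms`` is the
    beat-to-beat standard deviation of the whole-transient timing shift.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    amplitude_au: float = 1.0
    ct_prime_pk_ms: float
    ct_pk_ms: float
    rx_prime_pk_ms: float
    t_d_ms: float
    jitter_sd_ms: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "BeatParams":
        if self.amplitude_au < 0:
            raise ValueError("amplitude_au must be non-negative")
        if not (0 < self.ct_prime_pk_ms < self.ct_pk_ms
                < self.rx_prime_pk_ms < self.t_d_ms):
            raise ValueError(
                "fiducials must satisfy 0 < CT' < CT < RX' < T_d"
            )
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter_sd_ms must be non-negative")
        return self


class EPParams(BaseModel):
    """Extracellular-potential complex parameters.

    ``t_ap_ms`` is the stimulus-to-spike delay at the recording electrode,
    ``fpd_ms`` the spike-extremum-to-T-wave-apex field potential duration.
    The stimulation artefact dominates the evoked spike in amplitude.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    t_ap_ms: float
    spike_amp_uv: float
    fpd_ms: float
    artefact_amp_uv: float
    twave_width_ms: float = 80.0
    twave_amp_uv: float = 30.0
    spike_width_ms: float = 1.5
    noise_sd_uv: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "EPParams":
        if self.t_ap_ms <= 0 or self.fpd_ms <= 0:
            raise ValueError("t_ap_ms and fpd_ms must be positive")
        if self.spike_amp_uv <= 0:
            raise ValueError("spike_amp_uv must be positive")
        if self.artefact_amp_uv < self.spike_amp_uv:
            raise ValueError("artefact amplitude must dominate the spike")
        if self.twave_width_ms <= 0 or self.spike_width_ms <= 0:
            raise ValueError("widths must be positive")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be non-negative")
        return self


class MonolayerParams(BaseModel):
    """Electromechanical behaviour of the paced monolayer.

    A negative ``mech_onset_radial_slope_ms_per_um`` makes contraction start
    at the array periphery and propagate toward the centre; the
    extracellular spike delay grows with radial distance at
    ``1 / ep_conduction_um_per_ms``.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    arp_ms: float
    mech_onset_intercept_ms: float = 0.0
    mech_onset_radial_slope_ms_per_um: float = 0.0
    ep_conduction_um_per_ms: float = 50.0
    beat: BeatParams
    ep: EPParams
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "MonolayerParams":
        if self.arp_ms <= 0:
            raise ValueError("arp_ms must be positive")
        if self.ep_conduction_um_per_ms <= 0:
            raise ValueError("ep_conduction_um_per_ms must be positive")
        return self


class AggregateParams(BaseModel):
    """One pipetted cell aggregate in a time-lapse assay."""

    model_config = {"frozen": True, "extra": "forbid"}

    centre_rc: tuple[int, int]
    seed_time_h: float
    initial_radius_um: float
    growth_rate_um_per_h: float
    opacity_decay_per_h: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "AggregateParams":
        if self.initial_radius_um <= 0:
            raise ValueError("initial_radius_um must be positive")
        if self.growth_rate_um_per_h < 0 or self.opacity_decay_per_h < 0:
            raise ValueError("rates must be non-negative")
        return self


class DetachmentParams(BaseModel):
    """Enzymatic (trypsin) detachment: slow at room temperature, faster
    once the chip is moved to 37 C incubation."""

    model_config = {"frozen": True, "extra": "forbid"}

    start_min: float
    rate_rt_per_min: float
    rate_37c_per_min: float
    incubation_start_min: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "DetachmentParams":
        if self.rate_rt_per_min < 0 or self.rate_37c_per_min < 0:
            raise ValueError("rates must be non-negative")
        if self.rate_37c_per_min <= self.rate_rt_per_min:
            raise ValueError("37 C rate must exceed the room-temperature rate")
        return self


class TimelapseParams(BaseModel):
    """Time-lapse opacity/impedance assay parameters."""

    model_config = {"frozen": True, "extra": "forbid"}

    aggregates: tuple[AggregateParams, ...] = ()
    impedance_base_ohm: float
    impedance_plateau_ohm: float
    adhesion_tau_h: float = 6.0
    detachment: DetachmentParams | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TimelapseParams":
        if not 0 < self.impedance_base_ohm < self.impedance_plateau_ohm:
            raise ValueError("need impedance_plateau_ohm > impedance_base_ohm > 0")
        if self.adhesion_tau_h <= 0:
            raise ValueError("adhesion_tau_h must be positive")
        return self


@dataclass(frozen=True)
class Recording:
    """A multimodal paced recording: traces keyed by flat pixel id."""

    geometry: ArrayGeometry
    protocol: StimProtocol
    train: StimTrain
    optical: dict[int, PixelTrace]
    potential: dict[int, PixelTrace] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        traces = list(self.optical.values()) + list(self.potential.values())
        if traces:
            fs = {t.sampling_rate_hz for t in traces}
            ns = {t.n_samples for t in traces}
            if len(fs) != 1 or len(ns) != 1:
                raise ValidationError("all traces must share sampling rate and length")
        for pid in list(self.optical) + list(self.potential):
            if not 0 <= pid < self.geometry.n_pixels:
                raise ValidationError(f"pixel id {pid} outside geometry")

    @property
    def sampling_rate_hz(self) -> float:
        trace = next(iter(self.optical.values()), None) or next(
            iter(self.potential.values())
        )
        return trace.sampling_rate_hz


# --------------------------------------------------------------------------
# optical beat waveform, calibrated to its fiducials
# --------------------------------------------------------------------------

# Each beat phase mixes a broad sigmoid (sets the overall time course) with
# a sharper one (weight _SHARP_WEIGHT, time constants in ms) centred on the
# same fiducial.  Both components peak their slope at the fiducial, so the
# realized derivative extremum is exact while being sharp enough to locate
# under measurement noise.
_SHARP_WEIGHT = 0.25
_SHARP_RISE_TAU_MS = 10.0
_SHARP_DECAY_TAU_MS = 12.0


@lru_cache(maxsize=256)
def _decay_calibration(ct_pk: float, rx_pk: float, t_d: float) -> tuple[float, float]:
    """(broad decay time-constant, sharp-component weight) such that the
    decay passes through the 10 % criterion exactly at T_d.

    Falls back to a pure broad sigmoid when T_d sits too close to RX' for
    the sharp component to fit underneath the criterion.
    """

    def decay_at_td(tau: float, lam: float) -> float:
        num = (1 - lam) * expit((rx_pk - t_d) / tau) / expit(
            (rx_pk - ct_pk) / tau
        ) + lam * expit((rx_pk - t_d) / _SHARP_DECAY_TAU_MS)
        den = (1 - lam) + lam * expit((rx_pk - ct_pk) / _SHARP_DECAY_TAU_MS)
        return num / den

    for lam in (_SHARP_WEIGHT, 0.0):
        lo, hi = decay_at_td(1e-6, lam), decay_at_td(1e7, lam)
        if lo < DECAY_FRACTION < hi:
            tau = brentq(
                lambda tau: decay_at_td(tau, lam) - DECAY_FRACTION,
                1e-6, 1e7, xtol=1e-10,
            )
            return tau, lam
    raise ValidationError(
        f"cannot calibrate decay for CT={ct_pk}, RX'={rx_pk}, T_d={t_d}"
    )


def beat_shape(t_rel_ms: np.ndarray, beat: BeatParams) -> np.ndarray:
    """Unit-amplitude beat transient evaluated at stimulus-relative times.

    Piecewise two-component sigmoid: a rise whose slope peaks exactly at
    CT', normalized to 0 at the stimulus and 1 at CT; then a decay whose
    slope is most negative exactly at RX', calibrated to cross the 10 %
    decay criterion exactly at T_d.  Zero before the stimulus.
    """
    t = np.asarray(t_rel_ms, dtype=float)
    ctp, ct, rx, td = (
        beat.ct_prime_pk_ms,
        beat.ct_pk_ms,
        beat.rx_prime_pk_ms,
        beat.t_d_ms,
    )
    lam = _SHARP_WEIGHT
    tau_r = min(ctp, ct - ctp) / 2.5

    def rise(tt):
        return (1 - lam) * expit((tt - ctp) / tau_r) + lam * expit(
            (tt - ctp) / _SHARP_RISE_TAU_MS
        )

    r0, r1 = rise(0.0), rise(ct)
    tau_d, lam_d = _decay_calibration(ct, rx, td)
    d_den = (1 - lam_d) + lam_d * expit((rx - ct) / _SHARP_DECAY_TAU_MS)

    y = np.zeros_like(t)
    rising = (t >= 0) & (t <= ct)
    y[rising] = (rise(t[rising]) - r0) / (r1 - r0)
    decaying = t > ct
    td_dec = t[decaying]
    y[decaying] = (
        (1 - lam_d) * expit((rx - td_dec) / tau_d) / expit((rx - ct) / tau_d)
        + lam_d * expit((rx - td_dec) / _SHARP_DECAY_TAU_MS)
    ) / d_den
    return y


def synth_optical_beat(
    beat: BeatParams,
    sampling_rate_hz: float = 1000.0,
    stim_ms: float = 0.0,
    duration_ms: float | None = None,
    pixel_id: int = 0,
) -> PixelTrace:
    """One noiseless optical beat transient following a stimulus at ``stim_ms``.

    The realized fiducials of the sampled waveform (maximum rise slope,
    global maximum, most negative decay slope, 10 %-decay time) match the
    requested parameters to within the sampling resolution.
    """
    if sampling_rate_hz < 200:
        raise ValidationError("sampling_rate_hz must be at least 200 Hz")
    dt = 1000.0 / sampling_rate_hz
    if duration_ms is None:
        duration_ms = stim_ms + 1.5 * beat.t_d_ms
    n = int(round(duration_ms / dt))
    t = np.arange(n) * dt
    if beat.amplitude_au == 0:
        samples = np.zeros(n)
    else:
        samples = beat.amplitude_au * beat_shape(t - stim_ms, beat)
    return PixelTrace(pixel_id, OPTICAL, sampling_rate_hz, samples)


# --------------------------------------------------------------------------
# extracellular potential complex
# --------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _spike_calibration() -> tuple[float, float]:
    """(trough offset in units of sigma, peak-to-peak of the unit template).

    The spike template is a dominant negative Gaussian lobe preceded by a
    smaller positive lobe 2.5 sigma earlier; the overlap shifts the realized
    trough slightly, so its location and span are found numerically once.
    """
    u = np.arange(-8.0, 8.0, 1e-3)
    f = 0.55 * np.exp(-((u + 2.5) ** 2) / 2.0) - np.exp(-(u**2) / 2.0)
    return float(u[np.argmin(f)]), float(f.max() - f.min())


def _spike_waveform(t_ms: np.ndarray, trough_ms: float, ep: EPParams) -> np.ndarray:
    """Biphasic evoked spike with its trough exactly at ``trough_ms`` and
    realized peak-to-peak amplitude ``spike_amp_uv``."""
    u_min, span = _spike_calibration()
    u = (t_ms - trough_ms) / ep.spike_width_ms + u_min
    f = 0.55 * np.exp(-((u + 2.5) ** 2) / 2.0) - np.exp(-(u**2) / 2.0)
    return ep.spike_amp_uv / span * f


def _add_ep_complex(
    samples: np.ndarray,
    t_ms: np.ndarray,
    onset_ms: float,
    ep: EPParams,
    artefact_width_ms: float,
    captured: bool,
    t_ap_ms: float | None = None,
) -> None:
    """Add one stimulation artefact (always) and, if captured, the evoked
    spike and T-wave, in place."""
    w = artefact_width_ms
    samples[(t_ms >= onset_ms) & (t_ms < onset_ms + w)] += ep.artefact_amp_uv
    samples[(t_ms >= onset_ms + w) & (t_ms < onset_ms + 2 * w)] -= ep.artefact_amp_uv
    if not captured:
        return
    t_ap = ep.t_ap_ms if t_ap_ms is None else t_ap_ms
    trough = onset_ms + t_ap
    near = np.abs(t_ms - trough) <= 10 * ep.spike_width_ms
    samples[near] += _spike_waveform(t_ms[near], trough, ep)
    apex = trough + ep.fpd_ms
    sd_tw = ep.twave_width_ms / 2.355  # width is FWHM
    near = np.abs(t_ms - apex) <= 6 * sd_tw
    samples[near] += ep.twave_amp_uv * np.exp(
        -((t_ms[near] - apex) ** 2) / (2 * sd_tw**2)
    )


def synth_extracellular_trace(
    ep: EPParams,
    train: StimTrain,
    sampling_rate_hz: float = 1000.0,
    seed: int | None = None,
    duration_ms: float | None = None,
    artefact_width_ms: float = 1.2,
    captured: np.ndarray | None = None,
    pixel_id: int = 0,
) -> PixelTrace:
    """Extracellular potential trace for a pulse train.

    Every pulse contributes a biphasic rectangular artefact; each captured
    pulse (all by default) additionally contributes an evoked spike at
    ``t_ap_ms`` and a T-wave with apex at spike + ``fpd_ms``.  Gaussian
    noise of sd ``noise_sd_uv`` is added from ``seed``.
    """
    dt = 1000.0 / sampling_rate_hz
    if duration_ms is None:
        tail = ep.t_ap_ms + ep.fpd_ms + ep.twave_width_ms + 200.0
        duration_ms = (train.onsets_ms[-1] + tail) if len(train) else 1000.0
    n = int(round(duration_ms / dt))
    t = np.arange(n) * dt
    samples = np.zeros(n)
    if captured is None:
        captured = np.ones(len(train), dtype=bool)
    for onset, cap in zip(train.onsets_ms, captured):
        _add_ep_complex(samples, t, onset, ep, artefact_width_ms, bool(cap))
    if ep.noise_sd_uv > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, ep.noise_sd_uv, n)
    return PixelTrace(pixel_id, POTENTIAL, sampling_rate_hz, samples)


# --------------------------------------------------------------------------
# paced multimodal recording
# --------------------------------------------------------------------------

def synth_paced_recording(
    params: MonolayerParams,
    protocol: StimProtocol,
    duration_ms: float,
    sampling_rate_hz: float = 1000.0,
    geometry: ArrayGeometry = DEFAULT_GEOMETRY,
    pixels: list[int] | None = None,
    potential_pixels: list[int] = (),
    meta: dict | None = None,
) -> Recording:
    """Simulate a paced monolayer recording across the array.

    Pulse capture follows the deterministic refractory rule (first pulse
    captures; later pulses capture iff at least one ARP has elapsed since
    the last captured pulse).  Each captured pulse spawns, per pixel, an
    optical beat whose onset is
    ``stim + mech_onset_intercept + mech_onset_radial_slope * r(pixel)``
    plus Gaussian beat-to-beat jitter, with r the distance from the array
    centre; designated ``potential_pixels`` additionally record the
    extracellular complex with the spike delayed by ``r / conduction``.
    """
    train = generate_stimulation_train(protocol)
    if duration_ms <= train.onsets_ms[-1]:
        raise ValidationError("duration_ms does not cover the stimulation train")
    if pixels is None:
        pixels = list(range(geometry.n_pixels))
    dt = 1000.0 / sampling_rate_hz
    n = int(round(duration_ms / dt))
    t = np.arange(n) * dt

    captured = capture_pattern(params.arp_ms, train.onsets_ms)
    r_um = geometry.radial_distance_um(pixels)
    rng = np.random.default_rng(params.seed)
    jitter = rng.normal(
        0.0, params.beat.jitter_sd_ms, size=(len(train), len(pixels))
    ) if params.beat.jitter_sd_ms > 0 else np.zeros((len(train), len(pixels)))

    beat = params.beat
    window_ms = 1.4 * beat.t_d_ms
    optical: dict[int, PixelTrace] = {}
    for j, pid in enumerate(pixels):
        samples = np.zeros(n)
        base_onset = (
            params.mech_onset_intercept_ms
            + params.mech_onset_radial_slope_ms_per_um * r_um[j]
        )
        for i, (onset, cap) in enumerate(zip(train.onsets_ms, captured)):
            if not cap or beat.amplitude_au == 0:
                continue
            b0 = onset + base_onset + jitter[i, j]
            lo = max(int(np.floor(b0 / dt)), 0)
            hi = min(int(np.ceil((b0 + window_ms) / dt)) + 1, n)
            if lo >= n:
                continue
            samples[lo:hi] += beat.amplitude_au * beat_shape(t[lo:hi] - b0, beat)
        optical[pid] = PixelTrace(pid, OPTICAL, sampling_rate_hz, samples)

    potential: dict[int, PixelTrace] = {}
    if potential_pixels:
        r_pot = geometry.radial_distance_um(list(potential_pixels))
        for j, pid in enumerate(potential_pixels):
            samples = np.zeros(n)
            delay = r_pot[j] / params.ep_conduction_um_per_ms
            for onset, cap in zip(train.onsets_ms, captured):
                _add_ep_complex(
                    samples, t, onset, params.ep, protocol.pulse_width_ms,
                    bool(cap), t_ap_ms=params.ep.t_ap_ms + delay,
                )
            if params.ep.noise_sd_uv > 0:
                samples = samples + rng.normal(0.0, params.ep.noise_sd_uv, n)
            potential[pid] = PixelTrace(pid, POTENTIAL, sampling_rate_hz, samples)

    info = {"seed": params.seed, "arp_ms": params.arp_ms}
    if meta:
        info.update(meta)
    return Recording(geometry, protocol, train, optical, potential, info)


# --------------------------------------------------------------------------
# time-lapse opacity / impedance assay
# --------------------------------------------------------------------------

def synth_timelapse(
    params: TimelapseParams,
    geometry: ArrayGeometry,
    timestamps_h: np.ndarray,
) -> tuple[FrameSeries, FrameSeries]:
    """Time-lapse opacity and impedance frame series of seeded aggregates.

    Opacity: each aggregate is a radial Gaussian blob whose radius grows at
    ``growth_rate_um_per_h`` and whose amplitude decays at
    ``opacity_decay_per_h`` (cells spreading and migrating away).
    Impedance: baseline plus a smooth adhesion disc per aggregate ramping
    toward the plateau with time constant ``adhesion_tau_h``; after
    ``detachment.start_min`` the impedance excess decays exponentially at
    the temperature-appropriate rate.
    """
    ts = np.asarray(timestamps_h, dtype=float)
    if ts.ndim != 1 or (ts.size > 1 and not np.all(np.diff(ts) > 0)):
        raise ValidationError("timestamps_h must be strictly increasing")
    for agg in params.aggregates:
        r, c = agg.centre_rc
        if not (0 <= r < geometry.rows and 0 <= c < geometry.cols):
            raise ValidationError(f"aggregate centre {agg.centre_rc} outside grid")

    centres = geometry.pixel_centres_um().reshape(geometry.rows, geometry.cols, 2)
    det = params.detachment
    opacity = np.zeros((ts.size, geometry.rows, geometry.cols))
    impedance = np.full_like(opacity, params.impedance_base_ohm)
    z_span = params.impedance_plateau_ohm - params.impedance_base_ohm

    for k, t_h in enumerate(ts):
        excess = np.zeros((geometry.rows, geometry.cols))
        for agg in params.aggregates:
            dt_h = t_h - agg.seed_time_h
            if dt_h < 0:
                continue
            cr, cc = agg.centre_rc
            cx, cy = centres[cr, cc]
            d = np.hypot(centres[..., 0] - cx, centres[..., 1] - cy)
            radius = agg.initial_radius_um + agg.growth_rate_um_per_h * dt_h
            amp = np.exp(-agg.opacity_decay_per_h * dt_h)
            opacity[k] += amp * np.exp(-(d**2) / (2 * radius**2))
            ramp = 1.0 - np.exp(-dt_h / params.adhesion_tau_h)
            disc = expit((radius - d) / (geometry.pitch_um / 4.0))
            excess = np.maximum(excess, z_span * ramp * disc)
        if det is not None:
            t_min = t_h * 60.0
            if t_min >= det.start_min:
                inc = det.incubation_start_min
                inc = np.inf if inc is None else inc
                rt_elapsed = min(t_min, inc) - det.start_min
                c37_elapsed = max(0.0, t_min - inc)
                excess *= np.exp(
                    -det.rate_rt_per_min * max(rt_elapsed, 0.0)
                    - det.rate_37c_per_min * c37_elapsed
                )
        impedance[k] += excess

    return (
        FrameSeries(OPACITY, opacity, ts),
        FrameSeries(IMPEDANCE, impedance, ts),
    )
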