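"""Per-beat multi-parametric feature extraction from optical and
extracellular traces.

Optical fiducials (all stimulus-relative):

* ``CT'_PKS`` — contraction slope peak time: maximum of the time derivative
  during the rise;
* ``CT_PKS``  — contraction peak time: the beat maximum;
* ``RX'_PKS`` — relaxation slope peak time: most negative derivative during
  the decay;
* ``T_d``     — optical cycle duration: first decay below 10 % of the beat
  peak above baseline.

Extracellular features: ``T_ap`` (stimulus-to-spike delay), spike
peak-to-peak amplitude, and ``FPD`` (spike extremum to T-wave apex) — the
in vitro analogue of the QT interval.  The stimulation artefact window is
blanked (pulse width plus a guard) before spike detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import median_abs_deviation

from .errors import ModalityError, ValidationError
from .stim import StimTrain
from .trace import OPTICAL, POTENTIAL, PixelTrace

DECAY_FRACTION = 0.1


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction tuning knobs (all durations in ms).

    ``beat_threshold_frac`` is the fraction of the median candidate-beat
    peak below which a stimulus window counts as non-captured;
    ``candidate_frac`` selects candidate windows relative to the largest
    window peak.  Spike detection thresholds at ``spike_mad_factor`` times
    the trace's median absolute deviation.
    """

    smoothing_window_ms: float = 7.0
    polyorder: int = 3
    lowpass_hz: float | None = None
    baseline_window_ms: float = 25.0
    beat_threshold_frac: float = 0.3
    candidate_frac: float = 0.2
    decay_fraction: float = DECAY_FRACTION
    artefact_width_ms: float = 1.2  # per phase; biphasic artefact spans twice this
    artefact_guard_ms: float = 5.0
    spike_search_ms: float = 80.0
    spike_mad_factor: float = 4.0
    spike_pp_window_ms: float = 12.0
    twave_gap_ms: float = 40.0
    twave_smoothing_ms: float = 15.0
    td_smoothing_ms: float = 31.0
    beat_min_separation_ms: float = 50.0


@dataclass(frozen=True)
class OpticalBeatFeatures:
    beat_index: int
    stim_ms: float
    ct_prime_pks_ms: float
    ct_pks_ms: float
    rx_prime_pks_ms: float
    t_d_ms: float
    peak_amplitude_au: float

    def __post_init__(self):
        if not (0 <= self.ct_prime_pks_ms < self.ct_pks_ms
                < self.rx_prime_pks_ms < self.t_d_ms):
            raise ValidationError(
                "optical fiducials must satisfy CT' < CT < RX' < T_d"
            )


@dataclass(frozen=True)
class PotentialFeatures:
    beat_index: int
    stim_ms: float
    t_ap_ms: float
    spike_amplitude_uv: float
    fpd_ms: float

    def __post_init__(self):
        if min(self.t_ap_ms, self.spike_amplitude_uv, self.fpd_ms) <= 0:
            raise ValidationError("potential features must be positive")


def delta_intensity(trace: PixelTrace, reference_index: int = 0) -> PixelTrace:
    """Baseline-referenced intensity: samples minus the reference sample."""
    if not 0 <= reference_index < trace.n_samples:
        raise IndexError(f"reference_index {reference_index} out of range")
    return trace.with_samples(trace.samples - trace.samples[reference_index])


def smooth_and_differentiate(
    trace: PixelTrace, smoothing_window_ms: float = 7.0, polyorder: int = 3
) -> tuple[PixelTrace, PixelTrace]:
    """Local-polynomial (Savitzky-Golay) smoothing and its time derivative.

    Returns ``(smoothed, derivative)`` with the derivative in units per ms;
    lengths are preserved (mirrored edges).
    """
    window = int(round(smoothing_window_ms / trace.dt_ms))
    window = max(window, polyorder + 1)
    if window % 2 == 0:
        window += 1
    if window > trace.n_samples:
        raise ValidationError("smoothing window longer than trace")
    sm = savgol_filter(trace.samples, window, polyorder, mode="mirror")
    deriv = np.gradient(sm, trace.dt_ms)
    return trace.with_samples(sm), trace.with_samples(deriv)


def _stimulus_windows(trace: PixelTrace, train: StimTrain) -> list[tuple[int, int, int]]:
    """(onset_index, window_end_index, beat_index) per stimulus.

    Each window runs to the next onset, or for the last stimulus to the end
    of the trace (capped at the train period if one exists)."""
    t = trace.times_ms()
    period = train.period_ms
    windows = []
    onsets = train.onsets_ms
    for i, onset in enumerate(onsets):
        if onset < t[0] - trace.dt_ms / 2 or onset > t[-1]:
            raise ValidationError(f"stimulus at {onset} ms outside trace span")
        lo = trace.index_at(onset)
        if i + 1 < len(onsets):
            hi = trace.index_at(onsets[i + 1])
        elif np.isfinite(period):
            hi = min(lo + int(round(period / trace.dt_ms)), trace.n_samples)
        else:
            hi = trace.n_samples
        windows.append((lo, hi, i))
    return windows


def _decay_crossing(x_sm, x_raw, pk, thr, run_len=5, fit_half=40):
    """First decay below ``thr`` after the peak, in (fractional) samples.

    Coarse localization requires ``run_len`` consecutive smoothed samples
    below the threshold (robust to noise blips); the crossing is then
    refined by a local quadratic fit of the raw samples, which averages
    noise over the fit window without the bias a straight line would pick
    up from the decay's curvature.  Returns None when the trace ends first.
    """
    below = x_sm[pk:] < thr
    run = 0
    coarse = None
    for i, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run == run_len:
            coarse = pk + i - run_len + 1
            break
    if coarse is None:
        return None
    lo = max(pk, coarse - fit_half)
    hi = min(len(x_raw), coarse + fit_half)
    if hi - lo >= 6:
        t = np.arange(lo, hi, dtype=float) - coarse
        c2, c1, c0 = np.polyfit(t, x_raw[lo:hi], 2)
        roots = np.roots([c2, c1, c0 - thr]) if c2 != 0 else (
            [(thr - c0) / c1] if c1 != 0 else []
        )
        local = [r.real for r in np.atleast_1d(roots)
                 if abs(np.imag(r)) < 1e-9 and -fit_half <= np.real(r) <= fit_half]
        if local:
            refined = coarse + min(local, key=abs)
            return float(min(max(refined, pk), len(x_raw) - 1))
    return float(coarse)


def extract_optical_features(
    trace: PixelTrace,
    stim_train: StimTrain,
    config: FeatureConfig | None = None,
) -> list[OpticalBeatFeatures]:
    """Extract per-beat optical fiducials, one record per captured stimulus.

    Each stimulus window is baseline-referenced at its own onset sample;
    windows whose peak falls below the capture threshold (30 % of the median
    candidate-beat peak) yield no record, as do beats truncated by the end
    of the recording.
    """
    cfg = config or FeatureConfig()
    if trace.modality != OPTICAL:
        raise ModalityError("optical features require an optical trace")
    dt = trace.dt_ms
    if cfg.lowpass_hz is not None:
        from scipy.signal import butter, filtfilt

        b, a = butter(3, cfg.lowpass_hz / (trace.sampling_rate_hz / 2))
        sm = filtfilt(b, a, trace.samples)
        dv = np.gradient(sm, dt)
    else:
        sm_trace, dv_trace = smooth_and_differentiate(
            trace, cfg.smoothing_window_ms, cfg.polyorder
        )
        sm, dv = sm_trace.samples, dv_trace.samples
    windows = _stimulus_windows(trace, stim_train)

    # Per-window baseline reference: mean raw intensity just before the
    # stimulus where available (the previous beat has decayed there), which
    # keeps the reference noise-robust; when the recording starts at the
    # stimulus the smoothed onset sample is the only unbiased choice.
    n_base = max(int(round(cfg.baseline_window_ms / dt)), 1)
    refs = []
    for lo, hi, _ in windows:
        if lo >= n_base:
            refs.append(float(trace.samples[lo - n_base : lo].mean()))
        else:
            refs.append(float(sm[lo]))

    peaks = np.array([np.max(sm[lo:hi]) - ref if hi > lo else 0.0
                      for (lo, hi, _), ref in zip(windows, refs)])
    pmax = peaks.max(initial=0.0)
    if pmax <= 0:
        return []
    candidates = peaks[peaks >= cfg.candidate_frac * pmax]
    threshold = cfg.beat_threshold_frac * float(np.median(candidates))

    out: list[OpticalBeatFeatures] = []
    for (lo, hi, beat_index), ref, peak in zip(windows, refs, peaks):
        if peak <= threshold or hi - lo < 3:
            continue
        x = sm[lo:hi] - ref
        d = dv[lo:hi]
        pk = int(np.argmax(x))
        if pk == 0:
            continue
        ctp = int(np.argmax(d[: pk + 1]))  # earliest on ties
        rxp = pk + int(np.argmin(d[pk:]))
        td = _decay_crossing(x, trace.samples[lo:hi] - ref, pk,
                             cfg.decay_fraction * x[pk])
        if td is None:
            continue  # beat truncated by recording end
        try:
            out.append(
                OpticalBeatFeatures(
                    beat_index=beat_index,
                    stim_ms=float(stim_train.onsets_ms[beat_index]),
                    ct_prime_pks_ms=ctp * dt,
                    ct_pks_ms=pk * dt,
                    rx_prime_pks_ms=rxp * dt,
                    t_d_ms=td * dt,
                    peak_amplitude_au=float(x[pk]),
                )
            )
        except ValidationError:
            continue  # degenerate window (ordering violated)
    return out


def extract_potential_features(
    trace: PixelTrace,
    stim_train: StimTrain,
    config: FeatureConfig | None = None,
) -> list[PotentialFeatures]:
    """Extract T_ap, spike amplitude and FPD per captured stimulus.

    The artefact window (biphasic pulse width plus guard) is excluded; the
    spike is the largest absolute excursion in the search window, its
    amplitude the local peak-to-peak; the T-wave apex is the largest smooth
    extremum after a refractory gap.  Stimuli with no supra-threshold spike
    (or with the T-wave cut off by the next stimulus) yield no record.
    """
    cfg = config or FeatureConfig()
    if trace.modality != POTENTIAL:
        raise ModalityError("potential features require a potential trace")
    x = trace.samples
    dt = trace.dt_ms
    sm_tw = savgol_filter(
        x,
        max(2 * (int(round(cfg.twave_smoothing_ms / dt)) // 2) + 1, 5),
        3,
        mode="mirror",
    )
    windows = _stimulus_windows(trace, stim_train)

    blank_ms = 2 * cfg.artefact_width_ms + cfg.artefact_guard_ms
    # noise scale excluding artefact windows
    mask = np.ones(trace.n_samples, dtype=bool)
    for lo, _, _ in windows:
        mask[lo : min(lo + int(np.ceil(blank_ms / dt)) + 1, trace.n_samples)] = False
    mad = median_abs_deviation(x[mask]) if mask.any() else 0.0
    threshold = max(cfg.spike_mad_factor * mad, 1e-6)

    out: list[PotentialFeatures] = []
    for lo, hi, beat_index in windows:
        s_lo = lo + int(np.ceil(blank_ms / dt))
        s_hi = min(lo + int(round(cfg.spike_search_ms / dt)), hi)
        if s_hi <= s_lo:
            continue
        seg = x[s_lo:s_hi]
        spike = s_lo + int(np.argmax(np.abs(seg)))
        if abs(x[spike]) <= threshold:
            continue
        half_pp = int(round(cfg.spike_pp_window_ms / 2 / dt))
        ppseg = x[max(spike - half_pp, 0) : spike + half_pp + 1]
        amplitude = float(ppseg.max() - ppseg.min())

        t_lo = spike + int(round(cfg.twave_gap_ms / dt))
        # stop short of the window end so the next pulse's artefact cannot
        # leak into the search through the smoothing kernel
        t_hi = hi - int(np.ceil(cfg.twave_smoothing_ms / dt)) if hi < trace.n_samples else hi
        if t_lo >= t_hi:
            continue
        tw = sm_tw[t_lo:t_hi]
        apex = t_lo + int(np.argmax(np.abs(tw)))
        if abs(sm_tw[apex]) <= threshold:
            continue
        out.append(
            PotentialFeatures(
                beat_index=beat_index,
                stim_ms=float(stim_train.onsets_ms[beat_index]),
                t_ap_ms=(spike - lo) * dt,
                spike_amplitude_uv=amplitude,
                fpd_ms=(apex - spike) * dt,
            )
        )
    return out
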