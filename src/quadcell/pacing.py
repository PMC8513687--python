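"""Stimulation capture rates and absolute-refractory-period estimation.

Pacing a cardiomyocyte monolayer at increasing frequency probes its
absolute refractory period (ARP): a pulse arriving sooner than one ARP
after the last captured pulse cannot elicit a beat.  The deterministic
capture model here reproduces the characteristic capture-rate staircase
(100 % while the period exceeds the ARP, then 1/2, 1/3, ...), and the ARP
is read back either from the half-capture frequency or by inverting the
model against a measured capture curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, ValidationError
from .stim import StimTrain

_EPS_MS = 1e-9


@dataclass(frozen=True)
class CaptureResult:
    frequency_hz: float
    n_pulses: int
    n_captured: int

    def __post_init__(self):
        if self.n_captured > self.n_pulses:
            raise ValidationError("n_captured cannot exceed n_pulses")

    @property
    def capture_rate(self) -> float:
        return self.n_captured / self.n_pulses


@dataclass(frozen=True)
class ArpEstimate:
    arp_ms: float
    method: str
    supporting_frequencies_hz: tuple[float, ...]


def capture_pattern(arp_ms: float, onsets_ms: np.ndarray) -> np.ndarray:
    """Boolean capture decision per pulse under the refractory rule.

    The first pulse always captures; a later pulse captures iff the time
    elapsed since the last *captured* pulse is at least ``arp_ms`` (closed
    interval: elapsed time exactly equal to the ARP captures).
    """
    if arp_ms <= 0:
        raise ValidationError("arp_ms must be positive")
    onsets = np.asarray(onsets_ms, dtype=float)
    captured = np.zeros(onsets.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(onsets):
        if t - last >= arp_ms - _EPS_MS:
            captured[i] = True
            last = t
    return captured


def refractory_capture_model(
    arp_ms: float, period_ms: float, n_pulses: int = 20
) -> float:
    """Capture fraction of a periodic train under the refractory rule.

    Simulates the deterministic pulse-by-pulse capture decision.  For
    ``n_pulses >= 20`` the asymptotic fraction is reported (the pattern is
    periodic, capturing every m-th pulse); for shorter trains the finite
    ratio captured/n is returned.
    """
    if period_ms <= 0 or n_pulses < 1:
        raise ValidationError("period_ms and n_pulses must be positive")
    onsets = np.arange(n_pulses) * period_ms
    captured = capture_pattern(arp_ms, onsets)
    idx = np.flatnonzero(captured)
    if n_pulses >= 20 and idx.size >= 2:
        gaps = np.diff(idx)
        return 1.0 / float(gaps[0])
    return float(captured.sum() / n_pulses)


def _beat_upstroke_times(trace, config=None) -> np.ndarray:
    """Times (ms) of contraction upstrokes: local maxima of the smoothed
    derivative above a fraction of the largest upstroke slope."""
    from scipy.signal import find_peaks

    from .features import FeatureConfig, smooth_and_differentiate

    cfg = config or FeatureConfig()
    _, dv = smooth_and_differentiate(trace, cfg.smoothing_window_ms, cfg.polyorder)
    d = dv.samples
    dmax = d.max(initial=0.0)
    if dmax <= 0:
        return np.array([])
    height = max(0.4 * dmax, 1e-12)
    distance = max(int(round(cfg.beat_min_separation_ms / trace.dt_ms)), 1)
    peaks, _ = find_peaks(d, height=height, distance=distance)
    return trace.t0_ms + peaks * trace.dt_ms


def peak_to_next_stimulus_ms(ct_pk_ms: float, frequency_hz: float) -> float:
    """Interval from the contraction peak to the next stimulation pulse.

    At pacing period ``1000 / frequency_hz``, a beat peaking ``ct_pk_ms``
    after its stimulus leaves ``period - ct_pk_ms`` of relaxation before the
    next pulse arrives; negative values mean the next pulse lands before
    the peak.
    """
    if frequency_hz <= 0:
        raise ValidationError("frequency_hz must be positive")
    return 1000.0 / frequency_hz - ct_pk_ms


def detect_captures(source, stim_train: StimTrain, config=None) -> CaptureResult:
    """Count stimulation pulses that elicited a beat.

    ``source`` is either a list of per-beat feature records (anything with a
    ``stim_ms`` attribute, as produced by the feature extractors) or an
    optical :class:`~quadcell.trace.PixelTrace`.  For a trace, beats are
    detected as supra-threshold local maxima of the smoothed time
    derivative (one per contraction upstroke) — this stays reliable when
    pacing is fast enough for successive beats to overlap, where full
    fiducial extraction would drop truncated beats.  Because the mechanical
    latency can exceed the pacing period, upstrokes are counted rather than
    attributed to individual pulses: each detected beat marks one captured
    pulse, capped at the pulse count.
    """
    if len(stim_train) == 0:
        raise ValidationError("stim train is empty")
    from .trace import PixelTrace

    onsets = stim_train.onsets_ms
    if isinstance(source, PixelTrace):
        upstrokes = _beat_upstroke_times(source, config)
        n_hit = int(np.sum(upstrokes >= onsets[0] - 1e-9))
        n_hit = min(n_hit, len(stim_train))
        hit = set(range(n_hit))
    else:
        hit = {int(np.argmin(np.abs(onsets - rec.stim_ms))) for rec in source}
    period = stim_train.period_ms
    freq = 1000.0 / period if np.isfinite(period) else float("nan")
    return CaptureResult(frequency_hz=freq, n_pulses=len(stim_train), n_captured=len(hit))


def estimate_arp(
    capture_curve: list[CaptureResult],
    method: str = "sweep_bisection",
    half_tol: float = 0.05,
    arp_grid_ms: np.ndarray | None = None,
) -> ArpEstimate:
    """Estimate the absolute refractory period from a capture-rate curve.

    ``half_capture_doubling``: ARP = twice the period at the highest
    frequency showing ~50 % capture (the classical readout: at that
    frequency every second pulse captures, so the inter-beat interval —
    twice the period — equals the ARP).

    ``sweep_bisection``: smallest ARP on a 1 ms grid whose model-predicted
    capture fraction matches every observed (frequency, rate) pair within
    ``half_tol``.
    """
    if not capture_curve:
        raise EstimationError("empty capture curve")
    rates = {c.frequency_hz: c.capture_rate for c in capture_curve}
    if all(r > 1.0 - half_tol for r in rates.values()):
        raise EstimationError(
            "no capture-rate transition observed: pace at higher frequencies "
            "until the rate drops to ~50 %"
        )

    if method == "half_capture_doubling":
        half = [f for f, r in rates.items() if abs(r - 0.5) <= half_tol]
        if not half:
            raise EstimationError(
                "no frequency with ~50 % capture; use sweep_bisection or "
                "refine the frequency sweep"
            )
        f_star = max(half)
        return ArpEstimate(2 * 1000.0 / f_star, "half_capture_doubling", (f_star,))

    if method == "sweep_bisection":
        grid = np.arange(1.0, 2000.0 + 0.5, 1.0) if arp_grid_ms is None else np.asarray(arp_grid_ms)
        consistent = []
        for arp in grid:
            if all(
                abs(refractory_capture_model(arp, 1000.0 / f, max(c.n_pulses, 20)) - rates[f])
                <= half_tol
                for f, c in ((c.frequency_hz, c) for c in capture_curve)
            ):
                consistent.append(arp)
        if not consistent:
            raise EstimationError("no ARP on the grid is consistent with the curve")
        return ArpEstimate(
            float(min(consistent)),
            "sweep_bisection",
            tuple(sorted(rates)),
        )

    raise ValidationError(f"unknown method {method!r}")
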