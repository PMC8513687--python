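"""Spatiotemporal contraction-wave reconstruction from scanned pixel traces.

The array records optical transients pixel by pixel under periodic pacing;
because the beat is stimulus-locked, each pixel's trace can be folded to
stimulus-relative time and the 1024 folded traces reassembled into a
delta-light-intensity movie (intensity at time t minus intensity at the
stimulus).  An activation map (time to mechanical onset per pixel) and a
radial slope index then quantify whether contraction starts at the
periphery (negative slope) or the centre (positive slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, EstimationError, ValidationError
from .geometry import ArrayGeometry
from .synth import Recording


@dataclass(frozen=True)
class SpatiotemporalMovie:
    """Stimulus-relative delta-intensity movie on the pixel grid."""

    geometry: ArrayGeometry
    times_ms: np.ndarray
    delta_intensity: np.ndarray  # (T, rows, cols)

    def __post_init__(self):
        times = np.asarray(self.times_ms, dtype=float)
        delta = np.asarray(self.delta_intensity, dtype=float)
        object.__setattr__(self, "times_ms", times)
        object.__setattr__(self, "delta_intensity", delta)
        if delta.shape != (times.size, self.geometry.rows, self.geometry.cols):
            raise ValidationError("movie dimensions inconsistent with geometry")


@dataclass(frozen=True)
class ActivationMap:
    """Per-pixel time to mechanical onset (ms); NaN marks non-responding pixels."""

    onset_ms: np.ndarray

    def __post_init__(self):
        onset = np.asarray(self.onset_ms, dtype=float)
        object.__setattr__(self, "onset_ms", onset)
        finite = onset[np.isfinite(onset)]
        if finite.size and np.any(finite < 0):
            raise ValidationError("onsets must be non-negative")

    @property
    def n_responding(self) -> int:
        return int(np.isfinite(self.onset_ms).sum())


def align_sequential_traces(recording: Recording) -> SpatiotemporalMovie:
    """Fold per-pixel traces to stimulus-relative time and grid them.

    Each pixel's trace is cut at every stimulus onset, averaged over its
    available full cycles, and referenced to the stimulus-onset sample so
    the movie is identically zero at relative time 0.  Exactly
    ``rows x cols`` traces must be present.
    """
    geom = recording.geometry
    train = recording.train
    if len(train) < 1:
        raise AlignmentError("recording has no stimulation train")
    trace0 = next(iter(recording.optical.values()), None)
    if trace0 is None:
        raise AlignmentError("recording has no optical traces")
    dt = trace0.dt_ms
    if len(train) > 1 and not train.is_periodic(tol_ms=dt):
        raise AlignmentError("stimulation train is not periodic")
    if set(recording.optical) != set(range(geom.n_pixels)):
        raise AlignmentError(
            f"need exactly {geom.n_pixels} pixel traces covering the grid, "
            f"got {len(recording.optical)}"
        )

    period_ms = train.period_ms if len(train) > 1 else (
        trace0.duration_ms - train.onsets_ms[0]
    )
    n_rel = int(round(period_ms / dt))
    times = np.arange(n_rel) * dt
    movie = np.empty((n_rel, geom.rows, geom.cols))
    for pid, trace in recording.optical.items():
        cycles = []
        for onset in train.onsets_ms:
            lo = trace.index_at(onset)
            if lo + n_rel <= trace.n_samples:
                cycles.append(trace.samples[lo : lo + n_rel])
        if not cycles:
            raise AlignmentError(f"pixel {pid} has no complete stimulation cycle")
        folded = np.mean(cycles, axis=0)
        folded = folded - folded[0]  # delta intensity relative to the stimulus
        r, c = geom.pixel_rc(pid)
        movie[:, r, c] = folded
    return SpatiotemporalMovie(geom, times, movie)


def activation_map(
    movie: SpatiotemporalMovie,
    onset_criterion: float = 0.2,
    noise_floor: float = 0.0,
) -> ActivationMap:
    """Per-pixel mechanical onset time from the delta-intensity movie.

    Onset is the first time the pixel's delta intensity reaches
    ``onset_criterion`` of its own peak (linearly interpolated between
    samples); pixels whose peak does not exceed ``noise_floor`` are NaN.
    """
    if not 0 < onset_criterion < 1:
        raise ValidationError("onset_criterion must be in (0, 1)")
    delta = movie.delta_intensity
    times = movie.times_ms
    rows, cols = delta.shape[1:]
    onset = np.full((rows, cols), np.nan)
    for r in range(rows):
        for c in range(cols):
            x = delta[:, r, c]
            peak = x.max()
            if peak <= noise_floor:
                continue
            thr = onset_criterion * peak
            above = np.flatnonzero(x >= thr)
            i = above[0]
            if i == 0:
                onset[r, c] = times[0]
            else:
                frac = (thr - x[i - 1]) / (x[i] - x[i - 1])
                onset[r, c] = times[i - 1] + frac * (times[i] - times[i - 1])
    return ActivationMap(onset)


def periphery_centre_index(
    amap: ActivationMap, geometry: ArrayGeometry, min_pixels: int = 10
) -> float:
    """Least-squares slope of onset time versus radial distance (ms per um).

    Negative: contraction starts at the periphery and propagates to the
    centre; positive: centre leads (classical outward electrical spread).
    """
    onset = amap.onset_ms.ravel()
    finite = np.isfinite(onset)
    if finite.sum() < min_pixels:
        raise EstimationError(
            f"need at least {min_pixels} responding pixels, got {int(finite.sum())}"
        )
    r = geometry.radial_distance_um()[finite]
    return float(np.polyfit(r, onset[finite], 1)[0])
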