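"""Array-scan image assembly and time-lapse adhesion/detachment metrics.

The array measures two static imaging modalities: *opacity* (transmitted
light intensity at 4096 photodiode sites, 4 per pixel) and *impedance*
(100 kHz magnitude between adjacent electrode pairs).  Opacity reports local
cell density; impedance reports cell-to-surface adhesion.  This module
assembles raw scan measurements into frames and computes growth, adhesion
and enzymatic-detachment metrics from frame series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, ModalityError, ValidationError
from .geometry import ArrayGeometry

OPACITY = "opacity"
IMPEDANCE = "impedance"


@dataclass(frozen=True)
class Frame:
    """One 2-D array-scan image with a timestamp."""

    modality: str
    values: np.ndarray
    timestamp_h: float = 0.0

    def __post_init__(self):
        if self.modality not in (OPACITY, IMPEDANCE):
            raise ValidationError(f"unknown modality {self.modality!r}")
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError("frame values must be 2-D")
        if not np.all(np.isfinite(values)):
            raise ValidationError("frame values must be finite")
        if self.modality == IMPEDANCE and np.any(values <= 0):
            raise ValidationError("impedance values must be positive")
        if self.modality == OPACITY and np.any(values < 0):
            raise ValidationError("opacity values must be non-negative")


@dataclass(frozen=True)
class FrameSeries:
    """Time-ordered stack of frames of one modality."""

    modality: str
    frames: np.ndarray  # (T, rows, cols)
    timestamps_h: np.ndarray

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        ts = np.asarray(self.timestamps_h, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps_h", ts)
        if self.modality not in (OPACITY, IMPEDANCE):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if frames.ndim != 3:
            raise ValidationError("frames must be (T, rows, cols)")
        if ts.ndim != 1 or ts.size != frames.shape[0]:
            raise ValidationError("timestamps must match frame count")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(self.modality, self.frames[i], float(self.timestamps_h[i]))


@dataclass(frozen=True)
class PairScan:
    """One adjacent-electrode-pair impedance measurement.

    ``pair_index`` holds flat (row-major) ids of the excitation pixel and its
    neighbour; they must be grid-adjacent (Manhattan distance 1).
    """

    orientation: str
    pair_index: tuple[int, int]
    impedance_ohm: float

    def __post_init__(self):
        if self.orientation not in ("horizontal", "vertical"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        if self.impedance_ohm <= 0:
            raise ValidationError("impedance_ohm must be positive")


@dataclass(frozen=True)
class AdhesionMetrics:
    attached_fraction: float
    front_radius_um: tuple[float, ...]
    mean_attached_impedance_ohm: float


@dataclass(frozen=True)
class DetachmentKinetics:
    """Per-phase exponential-decay fits of region impedance excess."""

    half_times_min: tuple[float, ...]
    rates_per_min: tuple[float, ...]
    final_fraction: float


def full_pair_scan_count(geometry: ArrayGeometry) -> int:
    """Number of adjacent pairs in a full scan (both orientations)."""
    return geometry.rows * (geometry.cols - 1) + (geometry.rows - 1) * geometry.cols


def assemble_opacity_frame(
    site_values: np.ndarray,
    geometry: ArrayGeometry,
    timestamp_h: float = 0.0,
) -> tuple[Frame, Frame]:
    """Assemble a full optical scan into site- and pixel-resolution frames.

    ``site_values`` holds one measurement per photodiode site in pixel-major
    order, the 4 sites of each pixel in row-major order on its 2 x 2 subgrid.
    Returns ``(site_frame, pixel_frame)`` where the site frame is
    ``(2*rows, 2*cols)`` and the pixel frame is each pixel's 4-site mean.
    """
    values = np.asarray(site_values, dtype=float).ravel()
    if values.size != geometry.n_optical_sites:
        raise ValidationError(
            f"expected {geometry.n_optical_sites} site values, got {values.size}"
        )
    per_pixel = values.reshape(geometry.rows, geometry.cols, 2, 2)
    site_img = per_pixel.transpose(0, 2, 1, 3).reshape(
        2 * geometry.rows, 2 * geometry.cols
    )
    pixel_img = per_pixel.mean(axis=(2, 3))
    return (
        Frame(OPACITY, site_img, timestamp_h),
        Frame(OPACITY, pixel_img, timestamp_h),
    )


def assemble_impedance_frame(
    scans: list[PairScan],
    geometry: ArrayGeometry,
    timestamp_h: float = 0.0,
) -> Frame:
    """Map adjacent-pair impedance scans onto the pixel grid.

    Each pixel's value is the mean impedance over all pair measurements
    incident to it.  Every pixel must be covered by at least one scan.
    """
    sums = np.zeros(geometry.n_pixels)
    counts = np.zeros(geometry.n_pixels, dtype=int)
    for scan in scans:
        a, b = scan.pair_index
        ra, ca = geometry.pixel_rc(a)
        rb, cb = geometry.pixel_rc(b)
        if abs(ra - rb) + abs(ca - cb) != 1:
            raise ValidationError(f"pair {scan.pair_index} is not grid-adjacent")
        sums[a] += scan.impedance_ohm
        sums[b] += scan.impedance_ohm
        counts[a] += 1
        counts[b] += 1
    if np.any(counts == 0):
        missing = int(np.sum(counts == 0))
        raise CoverageError(f"{missing} pixels not covered by any pair scan")
    img = (sums / counts).reshape(geometry.rows, geometry.cols)
    return Frame(IMPEDANCE, img, timestamp_h)


def adhesion_metrics(
    frame: Frame,
    baseline_ohm: float,
    threshold_fraction: float = 0.5,
    aggregate_centres_um: list[tuple[float, float]] | None = None,
    geometry: ArrayGeometry | None = None,
    coverage: float = 0.95,
) -> AdhesionMetrics:
    """Attached fraction, per-aggregate front radius and attached-mean impedance.

    A pixel counts as attached when its impedance exceeds
    ``baseline_ohm * (1 + threshold_fraction)``.  For each supplied aggregate
    centre (x, y in um), the front radius is the radius of the smallest
    centred disc containing ``coverage`` of the attached pixels assigned to
    that centre (nearest-centre assignment).
    """
    if frame.modality != IMPEDANCE:
        raise ModalityError("adhesion metrics require an impedance frame")
    if geometry is None:
        geometry = ArrayGeometry(
            rows=frame.values.shape[0], cols=frame.values.shape[1]
        )
    threshold = baseline_ohm * (1.0 + threshold_fraction)
    attached = frame.values.ravel() > threshold
    fraction = float(attached.mean())
    mean_z = float(frame.values.ravel()[attached].mean()) if attached.any() else float("nan")

    radii: list[float] = []
    if aggregate_centres_um:
        centres = np.asarray(aggregate_centres_um, dtype=float)
        pix = geometry.pixel_centres_um()[attached]
        if pix.size == 0:
            radii = [float("nan")] * len(centres)
        else:
            d = np.linalg.norm(pix[:, None, :] - centres[None, :, :], axis=2)
            owner = np.argmin(d, axis=1)
            for k in range(len(centres)):
                dk = d[owner == k, k]
                radii.append(float(np.quantile(dk, coverage)) if dk.size else float("nan"))
    return AdhesionMetrics(fraction, tuple(radii), mean_z)


def detachment_kinetics(
    series: FrameSeries,
    region: np.ndarray | None = None,
    baseline_ohm: float | None = None,
    phase_boundaries_min: list[float] | None = None,
) -> DetachmentKinetics:
    """Fit single-exponential decay of region-mean impedance excess per phase.

    ``region`` is a boolean pixel mask (default: all pixels); ``baseline_ohm``
    defaults to the series-wide minimum pixel value.  ``phase_boundaries_min``
    splits the series into temperature phases (e.g. room temperature, then
    37 C incubation); each phase is fitted separately by log-linear least
    squares and reported as a half-time ``ln 2 / k``.  A non-decaying phase
    is flagged with an infinite half-time.
    """
    if series.modality != IMPEDANCE:
        raise ModalityError("detachment kinetics require an impedance series")
    if len(series) < 3:
        raise ValidationError("need at least 3 frames")
    mask = np.ones(series.frames.shape[1:], dtype=bool) if region is None else region
    t_min = series.timestamps_h * 60.0
    mean_z = series.frames[:, mask].mean(axis=1)
    base = float(series.frames.min()) if baseline_ohm is None else float(baseline_ohm)
    excess = mean_z - base
    if np.all(np.diff(mean_z) >= 0):
        warnings.warn("impedance series is non-decreasing; no detachment detected")

    bounds = [t_min[0]] + list(phase_boundaries_min or []) + [t_min[-1] + 1e-9]
    half_times: list[float] = []
    rates: list[float] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sel = (t_min >= lo - 1e-9) & (t_min <= hi + 1e-9)
        t_ph, e_ph = t_min[sel], excess[sel]
        ok = e_ph > 0
        if ok.sum() < 2:
            half_times.append(float("inf"))
            rates.append(0.0)
            continue
        slope = np.polyfit(t_ph[ok], np.log(e_ph[ok]), 1)[0]
        k = max(-float(slope), 0.0)
        if k < 1e-8:  # numerically flat: no detachment in this phase
            k = 0.0
        rates.append(k)
        half_times.append(float(np.log(2) / k) if k > 0 else float("inf"))
    final_fraction = float(excess[-1] / excess[0]) if excess[0] > 0 else float("nan")
    return DetachmentKinetics(tuple(half_times), tuple(rates), final_fraction)
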