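"""Uniformly sampled per-pixel time series (optical or extracellular)."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

OPTICAL = "optical"
POTENTIAL = "potential"


@dataclass(frozen=True)
class PixelTrace:
    """One uniformly sampled time series from one pixel.

    ``samples`` are in arbitrary intensity units for the optical modality
    and microvolts for the extracellular-potential modality.
    """

    pixel_id: int
    modality: str
    sampling_rate_hz: float
    samples: np.ndarray
    t0_ms: float = 0.0

    def __post_init__(self):
        if self.modality not in (OPTICAL, POTENTIAL):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValidationError("samples must be 1-D with length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples must be finite")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * self.dt_ms

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms`` (must lie in the trace)."""
        idx = int(round((t_ms - self.t0_ms) / self.dt_ms))
        if not 0 <= idx < self.n_samples:
            raise IndexError(f"time {t_ms} ms outside trace")
        return idx

    def with_samples(self, samples: np.ndarray) -> "PixelTrace":
        """Copy of the trace with new samples, metadata preserved."""
        return replace(self, samples=samples)
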