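"""Biphasic current stimulation protocols and realized pulse trains.

A protocol describes a train of charge-balanced biphasic current pulses:
each pulse delivers a positive phase of ``amplitude_uA`` for
``pulse_width_ms`` immediately followed by an equal and opposite negative
phase, so the net injected charge is zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, model_validator

from .errors import ValidationError


class StimProtocol(BaseModel):
    """Charge-balanced biphasic pulse-train description.

    ``pulse_width_ms`` is the duration of one phase; the full biphasic pulse
    occupies twice that.  The inter-pulse period ``1000 / frequency_hz`` must
    exceed the phase width.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    amplitude_uA: float
    pulse_width_ms: float
    frequency_hz: float
    n_pulses: int = 10
    start_ms: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "StimProtocol":
        if self.amplitude_uA <= 0:
            raise ValueError("amplitude_uA must be positive")
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be positive")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be at least 1")
        if 1000.0 / self.frequency_hz <= self.pulse_width_ms:
            raise ValueError(
                "inter-pulse period must exceed the pulse phase width"
            )
        return self

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    @property
    def phase_charge_nC(self) -> float:
        """Charge per phase (uA * ms = nC); equal for both phases."""
        return self.amplitude_uA * self.pulse_width_ms


@dataclass(frozen=True)
class StimTrain:
    """Realized pulse-onset schedule in milliseconds."""

    onsets_ms: np.ndarray
    protocol: StimProtocol | None = field(default=None, compare=False)

    def __post_init__(self):
        onsets = np.asarray(self.onsets_ms, dtype=float)
        object.__setattr__(self, "onsets_ms", onsets)
        if onsets.ndim != 1:
            raise ValidationError("onsets_ms must be one-dimensional")
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValidationError("onsets_ms must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets_ms.size

    @property
    def period_ms(self) -> float:
        """Median inter-pulse interval; NaN for fewer than two pulses."""
        if len(self) < 2:
            return float("nan")
        return float(np.median(np.diff(self.onsets_ms)))

    def is_periodic(self, tol_ms: float) -> bool:
        if len(self) < 2:
            return True
        d = np.diff(self.onsets_ms)
        return bool(np.ptp(d) <= tol_ms)


def generate_stimulation_train(protocol: StimProtocol) -> StimTrain:
    """Realize the onset schedule of a stimulation protocol.

    Onsets start at ``start_ms`` and are spaced exactly
    ``1000 / frequency_hz`` apart.
    """
    if not isinstance(protocol, StimProtocol):
        raise ValidationError("protocol must be a StimProtocol")
    onsets = protocol.start_ms + np.arange(protocol.n_pulses) * protocol.period_ms
    return StimTrain(onsets_ms=onsets, protocol=protocol)
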