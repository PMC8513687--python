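"""Named parameter presets for the synthetic generators.

Presets bundle the printed study conditions (contraction/relaxation
fiducials per isoproterenol dose, the 222 ms refractory period, stimulation
protocols, impedance plateaus) so that downstream stages can be exercised
under realistic settings with one name.  Fields that are design choices
rather than measured values are flagged in each preset's ``authoritative``
list and notes.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .errors import ValidationError
from .stim import StimProtocol
from .synth import (
    BeatParams,
    DetachmentParams,
    EPParams,
    MonolayerParams,
    TimelapseParams,
)


@lru_cache(maxsize=1)
def _load() -> dict:
    text = resources.files("quadcell.data").joinpath("presets.json").read_text()
    return json.loads(text)["presets"]


def list_presets() -> list[str]:
    return sorted(_load())


def get_preset(name: str) -> dict:
    presets = _load()
    if name not in presets:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    return presets[name]


def beat_params(name: str, **overrides) -> BeatParams:
    preset = get_preset(name)
    if "beat" not in preset:
        raise ValidationError(f"preset {name!r} has no beat parameters")
    return BeatParams(**{**preset["beat"], **overrides})


def ep_params(name: str, **overrides) -> EPParams:
    preset = get_preset(name)
    if "ep" not in preset:
        raise ValidationError(f"preset {name!r} has no extracellular parameters")
    return EPParams(**{**preset["ep"], **overrides})


def stim_protocol(name: str, **overrides) -> StimProtocol:
    preset = get_preset(name)
    if "protocol" not in preset:
        raise ValidationError(f"preset {name!r} has no stimulation protocol")
    return StimProtocol(**{**preset["protocol"], **overrides})


def monolayer_params(
    name: str,
    seed: int = 0,
    arp_ms: float | None = None,
    **overrides,
) -> MonolayerParams:
    """Monolayer parameters built from a beat/EP preset.

    ``arp_ms`` defaults to the ARP_222 preset value.  Presets without their
    own extracellular section fall back to the baseline one.
    """
    preset = get_preset(name)
    if arp_ms is None:
        arp_ms = get_preset("ARP_222")["arp_ms"]
    ep_src = name if "ep" in preset else "BASELINE_0NM"
    return MonolayerParams(
        arp_ms=arp_ms,
        beat=beat_params(name),
        ep=ep_params(ep_src),
        seed=seed,
        **overrides,
    )


def timelapse_params(
    name: str, with_detachment: bool = False, seed: int = 0, **overrides
) -> TimelapseParams:
    preset = get_preset(name)
    if "timelapse" not in preset:
        raise ValidationError(f"preset {name!r} has no time-lapse parameters")
    kwargs = dict(preset["timelapse"])
    kwargs["aggregates"] = tuple(
        a if isinstance(a, dict) else a for a in kwargs["aggregates"]
    )
    if with_detachment:
        if "detachment" not in preset:
            raise ValidationError(f"preset {name!r} has no detachment phase")
        kwargs["detachment"] = DetachmentParams(**preset["detachment"])
    kwargs["seed"] = seed
    kwargs.update(overrides)
    return TimelapseParams(**kwargs)
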