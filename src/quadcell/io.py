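"""Readers/writers for recordings, frame series, feature tables and configs.

On-disk layout (HDF5, schema ``quadcell-1``):

* recording: ``/optical/traces`` (pixels x samples) with ``/optical/pixel_ids``,
  ``/potential/traces`` likewise, ``/stim/onsets_ms``; root attributes
  ``schema_version``, ``sampling_rate_hz``, ``rows``, ``cols``, ``pitch_um``,
  ``seed``, ``preset`` and the stimulation protocol as JSON.
* frame series: ``/frames`` (T x rows x cols), ``/timestamps_h``, attribute
  ``modality`` in {opacity, impedance}.
* movies: ``/movie`` (T x rows x cols), ``/times_ms``.

Feature tables and dose summaries are plain CSV with a fixed column order;
times are milliseconds (float64), impedances Ohm, doses nM.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from .errors import SchemaError, ValidationError
from .features import OpticalBeatFeatures, PotentialFeatures
from .geometry import ArrayGeometry
from .imaging import FrameSeries
from .stim import StimProtocol, StimTrain
from .synth import Recording
from .trace import OPTICAL, POTENTIAL, PixelTrace
from .wave import SpatiotemporalMovie

SCHEMA_VERSION = "quadcell-1"

FEATURE_COLUMNS = ["pixel_id", "modality", "beat_index", "stim_ms",
                   "feature", "value", "units"]

_UNITS = {
    "ct_prime_pks_ms": "ms",
    "ct_pks_ms": "ms",
    "rx_prime_pks_ms": "ms",
    "t_d_ms": "ms",
    "peak_amplitude_au": "au",
    "t_ap_ms": "ms",
    "spike_amplitude_uv": "uV",
    "fpd_ms": "ms",
}

_OPTICAL_FEATURES = ["ct_prime_pks_ms", "ct_pks_ms", "rx_prime_pks_ms",
                     "t_d_ms", "peak_amplitude_au"]
_POTENTIAL_FEATURES = ["t_ap_ms", "spike_amplitude_uv", "fpd_ms"]


def _check_schema(f: h5py.File, path) -> None:
    version = f.attrs.get("schema_version")
    if version is None:
        raise SchemaError(f"{path}: missing schema_version attribute")
    major = str(version).rsplit("-", 1)[-1]
    if str(version).split("-")[0] != "quadcell" or major.split(".")[0] != "1":
        raise SchemaError(f"{path}: unsupported schema version {version!r}")


def write_recording(rec: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
        f.attrs["rows"] = rec.geometry.rows
        f.attrs["cols"] = rec.geometry.cols
        f.attrs["pitch_um"] = rec.geometry.pitch_um
        f.attrs["photodiode_sites_per_pixel"] = rec.geometry.photodiode_sites_per_pixel
        f.attrs["fov_mm"] = rec.geometry.fov_mm
        f.attrs["protocol_json"] = rec.protocol.model_dump_json()
        f.attrs["meta_json"] = json.dumps(rec.meta)
        stim = f.create_group("stim")
        stim.create_dataset("onsets_ms", data=rec.train.onsets_ms)
        for name, traces in (("optical", rec.optical), ("potential", rec.potential)):
            grp = f.create_group(name)
            pids = sorted(traces)
            grp.create_dataset("pixel_ids", data=np.asarray(pids, dtype=np.int64))
            data = np.stack([traces[p].samples for p in pids]) if pids else np.empty((0, 0))
            grp.create_dataset("traces", data=data)


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        for group in ("stim", "optical"):
            if group not in f:
                raise SchemaError(f"{path}: missing /{group} group")
        geometry = ArrayGeometry(
            rows=int(f.attrs["rows"]),
            cols=int(f.attrs["cols"]),
            pitch_um=float(f.attrs["pitch_um"]),
            photodiode_sites_per_pixel=int(f.attrs["photodiode_sites_per_pixel"]),
            fov_mm=float(f.attrs["fov_mm"]),
        )
        protocol = StimProtocol(**json.loads(f.attrs["protocol_json"]))
        meta = json.loads(f.attrs.get("meta_json", "{}"))
        fs = float(f.attrs["sampling_rate_hz"])
        train = StimTrain(onsets_ms=f["stim/onsets_ms"][:], protocol=protocol)
        out: dict[str, dict[int, PixelTrace]] = {}
        for name, modality in (("optical", OPTICAL), ("potential", POTENTIAL)):
            traces: dict[int, PixelTrace] = {}
            if name in f and f[name]["pixel_ids"].size:
                pids = f[name]["pixel_ids"][:]
                data = f[name]["traces"][:]
                for pid, samples in zip(pids, data):
                    traces[int(pid)] = PixelTrace(int(pid), modality, fs, samples)
            out[name] = traces
    return Recording(geometry, protocol, train, out["optical"], out["potential"], meta)


def write_frameseries(series: FrameSeries, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["modality"] = series.modality
        f.create_dataset("frames", data=series.frames)
        f.create_dataset("timestamps_h", data=series.timestamps_h)


def read_frameseries(path) -> FrameSeries:
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        if "frames" not in f or "timestamps_h" not in f:
            raise SchemaError(f"{path}: missing /frames or /timestamps_h")
        return FrameSeries(
            str(f.attrs["modality"]), f["frames"][:], f["timestamps_h"][:]
        )


def write_movie(movie: SpatiotemporalMovie, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["rows"] = movie.geometry.rows
        f.attrs["cols"] = movie.geometry.cols
        f.attrs["pitch_um"] = movie.geometry.pitch_um
        f.create_dataset("movie", data=movie.delta_intensity)
        f.create_dataset("times_ms", data=movie.times_ms)


def read_movie(path) -> SpatiotemporalMovie:
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        geometry = ArrayGeometry(
            rows=int(f.attrs["rows"]),
            cols=int(f.attrs["cols"]),
            pitch_um=float(f.attrs["pitch_um"]),
        )
        return SpatiotemporalMovie(geometry, f["times_ms"][:], f["movie"][:])


def features_to_frame(
    records: list[tuple[int, OpticalBeatFeatures | PotentialFeatures]]
) -> pd.DataFrame:
    """Tidy (long) DataFrame from ``(pixel_id, feature-record)`` pairs."""
    rows = []
    for pixel_id, rec in records:
        if isinstance(rec, OpticalBeatFeatures):
            modality, names = OPTICAL, _OPTICAL_FEATURES
        elif isinstance(rec, PotentialFeatures):
            modality, names = POTENTIAL, _POTENTIAL_FEATURES
        else:
            raise ValidationError(f"unsupported record type {type(rec).__name__}")
        for name in names:
            rows.append(
                dict(
                    pixel_id=pixel_id,
                    modality=modality,
                    beat_index=rec.beat_index,
                    stim_ms=rec.stim_ms,
                    feature=name,
                    value=getattr(rec, name),
                    units=_UNITS[name],
                )
            )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return df.sort_values(["pixel_id", "beat_index", "modality", "feature"]).reset_index(
        drop=True
    )


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a tidy feature table as CSV with fixed column order and at
    least 9 significant digits on numeric values."""
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"feature table missing columns: {sorted(missing)}")
    table[FEATURE_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"feature": str, "modality": str, "units": str})
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = []
    for col in ("pixel_id", "beat_index", "stim_ms", "value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad.extend((df.index[numeric.isna()] + 2).tolist())  # +2: header + 1-based
        df[col] = numeric
    if bad:
        raise ValidationError(f"{path}: malformed rows at lines {sorted(set(bad))}")
    return df


class RunConfig(BaseModel):
    """Validated pipeline run configuration (YAML/JSON); unknown keys rejected."""

    model_config = {"extra": "forbid"}

    preset: str | None = None
    protocol: StimProtocol | None = None
    geometry: ArrayGeometry | None = None
    extraction: dict = {}
    seed: int = 0
    out: str | None = None


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return RunConfig(**payload)
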