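"""Readers, writers and timeline alignment.

On-disk conventions
-------------------
Waveforms travel as a delimited text file (CSV with header) holding the
uniform-clock channels, an optional ``<stem>.edi.csv`` companion with the
native-rate Edi channel, and a ``<stem>.meta.json`` sidecar carrying the
sample rate plus protocol metadata (animal id, PEEP, phase, FiO2, blood-gas
annotations) that the analysis passes through untouched.

EIT frame stacks are stored as HDF5 (datasets ``frames[T,32,32]`` and
``time[T]``, attribute ``frame_rate``); pre-reduced four-ROI traces use a
CSV fallback with columns ``time, anterior, mid_anterior, mid_posterior,
posterior``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import h5py
import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import AlignmentError, FormatError, SchemaError
from .records import EIT_GRID, ROI_NAMES, AlignedAcquisition, EITSequence, WaveformRecord

WAVEFORM_CHANNELS = ("time", "p_ao", "p_eso", "p_ga", "flow")

#: unit conversion factors to the canonical units (cmH2O, L/s)
_PRESSURE_FACTORS = {"cmH2O": 1.0, "kPa": 10.197162129779283, "mbar": 1.0197162129779282}
_FLOW_FACTORS = {"L/s": 1.0, "L/min": 1.0 / 60.0, "ml/s": 1e-3}

DEFAULT_SCHEMA: dict = {
    "columns": {name: name for name in WAVEFORM_CHANNELS},
    "pressure_units": "cmH2O",
    "flow_units": "L/s",
    "flow_sign": 1,  # +1 if the file already has inspiration positive
}


def _merge_schema(schema: Optional[Mapping]) -> dict:
    merged = {**DEFAULT_SCHEMA, **(schema or {})}
    merged["columns"] = {**DEFAULT_SCHEMA["columns"], **(schema or {}).get("columns", {})}
    if merged["pressure_units"] not in _PRESSURE_FACTORS:
        raise SchemaError(f"unknown pressure units {merged['pressure_units']!r}")
    if merged["flow_units"] not in _FLOW_FACTORS:
        raise SchemaError(f"unknown flow units {merged['flow_units']!r}")
    if merged["flow_sign"] not in (1, -1):
        raise SchemaError("flow_sign must be +1 or -1")
    return merged


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    return path.with_suffix(".meta.json"), path.with_suffix(".edi.csv")


def read_waveforms(path, schema: Optional[Mapping] = None) -> WaveformRecord:
    """Read a waveform CSV (plus sidecars, if present) into a record.

    ``schema`` may remap column names and declare source units / flow sign;
    channels are converted to cmH2O and inspiration-positive L/s on load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sch = _merge_schema(schema)
    df = pd.read_csv(path)
    data = {}
    for channel in WAVEFORM_CHANNELS:
        col = sch["columns"][channel]
        if col not in df.columns:
            raise SchemaError(f"waveform file {path.name} is missing column {col!r}")
        data[channel] = df[col].to_numpy(dtype=float)
    if data["time"].size < 2:
        raise SchemaError("waveform file must contain at least 2 samples")
    pf = _PRESSURE_FACTORS[sch["pressure_units"]]
    ff = _FLOW_FACTORS[sch["flow_units"]] * sch["flow_sign"]
    for channel in ("p_ao", "p_eso", "p_ga"):
        data[channel] = data[channel] * pf
    data["flow"] = data["flow"] * ff

    meta_path, edi_path = _sidecar_paths(path)
    meta: dict = {}
    sample_rate = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        sample_rate = meta.pop("sample_rate", None)
    if sample_rate is None:
        dt = np.median(np.diff(data["time"]))
        sample_rate = 1.0 / dt
    edi = edi_time = None
    if edi_path.exists():
        edi_df = pd.read_csv(edi_path)
        edi_time = edi_df["time"].to_numpy(dtype=float)
        edi = edi_df["edi"].to_numpy(dtype=float)
    return WaveformRecord(
        time=data["time"], p_ao=data["p_ao"], p_eso=data["p_eso"],
        p_ga=data["p_ga"], flow=data["flow"], sample_rate=float(sample_rate),
        edi=edi, edi_time=edi_time, meta=meta,
    )


def write_waveforms(record: WaveformRecord, path) -> Path:
    """Write a record to CSV with JSON metadata and Edi sidecars."""
    path = Path(path)
    df = pd.DataFrame({name: getattr(record, name) for name in WAVEFORM_CHANNELS})
    df.to_csv(path, index=False, float_format="%.10g")
    meta_path, edi_path = _sidecar_paths(path)
    meta = {"sample_rate": record.sample_rate, **record.meta}
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    if record.edi is not None:
        pd.DataFrame({"time": record.edi_time, "edi": record.edi}).to_csv(
            edi_path, index=False, float_format="%.10g"
        )
    return path


def read_eit(path, frame_rate: Optional[float] = None) -> EITSequence:
    """Read an EIT sequence: HDF5 frame stack or CSV four-ROI trace table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            frames = f["frames"][...]
            time = f["time"][...]
            rate = float(f.attrs.get("frame_rate", frame_rate or 50.0))
            mask = f["lung_mask"][...].astype(bool) if "lung_mask" in f else None
        if frames.ndim != 3 or frames.shape[1:] != (EIT_GRID, EIT_GRID):
            raise FormatError(
                f"expected {EIT_GRID}x{EIT_GRID} frames, got shape {frames.shape}"
            )
        return EITSequence(time=time, frames=frames, frame_rate=rate, lung_mask=mask)
    df = pd.read_csv(path)
    missing = [c for c in ("time", *ROI_NAMES) if c not in df.columns]
    if missing:
        raise FormatError(f"EIT trace table missing columns {missing}")
    time = df["time"].to_numpy(dtype=float)
    traces = np.vstack([df[name].to_numpy(dtype=float) for name in ROI_NAMES])
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(time))) if time.size > 1 else 50.0
    return EITSequence(time=time, roi_traces=traces, frame_rate=float(frame_rate))


def write_eit(eit: EITSequence, path) -> Path:
    """Write a sequence: HDF5 when frames are present, CSV for traces."""
    path = Path(path)
    if eit.frames is not None:
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=eit.frames)
            f.create_dataset("time", data=eit.time)
            f.attrs["frame_rate"] = eit.frame_rate
            if eit.lung_mask is not None:
                f.create_dataset("lung_mask", data=eit.lung_mask.astype(np.uint8))
        return path
    df = pd.DataFrame({"time": eit.time})
    for i, name in enumerate(ROI_NAMES):
        df[name] = eit.roi_traces[i]
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def _global_z(eit: EITSequence) -> np.ndarray:
    if eit.roi_traces is not None:
        return eit.roi_traces.sum(axis=0)
    return eit.frames.reshape(eit.n_frames, -1).mean(axis=1)


def align(
    waveforms: WaveformRecord,
    eit: EITSequence,
    method: str = "declared-offset",
    offset: float = 0.0,
    max_lag: float = 2.0,
) -> AlignedAcquisition:
    """Place both modalities on the waveform clock.

    ``declared-offset`` applies ``offset`` as given (default 0: simultaneous
    acquisition).  ``cross-correlation`` scans lags in frame-period steps over
    ``[-max_lag, +max_lag]`` and picks the offset maximizing the Pearson
    correlation between the global impedance trace and the tidal volume
    obtained by integrating flow.
    """
    if method == "declared-offset":
        return AlignedAcquisition(waveforms=waveforms, eit=eit, offset=float(offset))
    if method != "cross-correlation":
        raise ValueError(f"unknown alignment method {method!r}")
    if waveforms.duration < 5.0 or eit.duration < 5.0:
        raise AlignmentError("cross-correlation alignment needs >= 5 s of each signal")

    volume = cumulative_trapezoid(waveforms.flow, waveforms.time, initial=0.0)
    z = _global_z(eit)
    z = z - z.mean()
    period = 1.0 / eit.frame_rate
    lags = np.arange(-max_lag, max_lag + 0.5 * period, period)
    best_lag, best_r = 0.0, -np.inf
    for lag in lags:
        t_eit = eit.time + lag
        inside = (t_eit >= waveforms.time[0]) & (t_eit <= waveforms.time[-1])
        if inside.sum() < 3:
            continue
        v = np.interp(t_eit[inside], waveforms.time, volume)
        zi = z[inside]
        v = v - v.mean()
        zi = zi - zi.mean()
        denom = np.sqrt((v * v).sum() * (zi * zi).sum())
        if denom == 0:
            continue
        r = float((v * zi).sum() / denom)
        if r > best_r:
            best_r, best_lag = r, float(lag)
    if not np.isfinite(best_r):
        raise AlignmentError("no lag in the scan range yields timeline overlap")
    return AlignedAcquisition(waveforms=waveforms, eit=eit, offset=best_lag)
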