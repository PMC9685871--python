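"""Breath segmentation and per-breath volumes from the flow signal.

Spontaneous breathing is segmented directly from airway flow: an
inspiration starts at a positive-going crossing of a small flow threshold
that is sustained for a minimum duration (hysteresis against sensor noise),
expiration starts at the subsequent return of flow through zero, and the
breath ends at the next inspiration onset.  Tidal volumes come from
trapezoidal integration of the flow lobes, reported in ml.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import SamplingError
from .records import WaveformRecord

#: rejects pneumotachograph noise without missing rapid shallow breaths
DEFAULT_FLOW_THRESHOLD = 0.02   # L/s
DEFAULT_MIN_INSP_DURATION = 0.08  # s


@dataclass(frozen=True)
class BreathSegment:
    """Sample indices delimiting one breath on the waveform clock."""

    insp_start: int
    insp_end: int   # first expiratory sample
    exp_end: int    # exclusive end of the breath = next inspiration onset
    sample_rate: float

    def __post_init__(self) -> None:
        if not (0 <= self.insp_start < self.insp_end < self.exp_end):
            raise ValueError(
                f"invalid segment indices {self.insp_start}, {self.insp_end}, {self.exp_end}"
            )

    @property
    def duration(self) -> float:
        """Full-cycle duration in seconds."""
        return (self.exp_end - self.insp_start) / self.sample_rate

    @property
    def slice(self) -> slice:
        return slice(self.insp_start, self.exp_end)


@dataclass(frozen=True)
class BreathMetrics:
    """Simple per-breath summaries."""

    vt_insp: float    # ml
    vt_exp: float     # ml
    peak_flow: float  # L/s, inspiratory phase
    peak_p_ao: float  # cmH2O, inspiratory phase
    rr_inst: float    # breaths/min, 60/duration


def detect_breaths(
    flow: np.ndarray,
    sample_rate: float,
    min_insp_duration: float = DEFAULT_MIN_INSP_DURATION,
    flow_threshold: float = DEFAULT_FLOW_THRESHOLD,
) -> list[BreathSegment]:
    """Segment a flow series into complete, non-overlapping breaths.

    Incomplete leading/trailing breaths are discarded; an empty list (no
    qualifying crossings) is a valid result, not an error.
    """
    if sample_rate <= 0:
        raise SamplingError("sample_rate must be positive")
    flow = np.asarray(flow, dtype=float)
    if flow.size < 2 * sample_rate:
        raise ValueError("flow series must cover at least 2 s")

    min_samples = max(1, int(round(min_insp_duration * sample_rate)))
    above = flow > flow_threshold
    # positive-going threshold crossings (ignore an onset already in progress
    # at sample 0: that breath is incomplete)
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1

    onsets = []
    for idx in rising:
        if np.all(above[idx:idx + min_samples]) and idx + min_samples <= flow.size:
            onsets.append(int(idx))

    segments: list[BreathSegment] = []
    for start, nxt in zip(onsets, onsets[1:]):
        # expiration: first return of flow through zero after the sustained onset
        window = flow[start + min_samples:nxt]
        below = np.flatnonzero(window <= 0.0)
        if below.size == 0:
            continue  # no expiratory phase before the next onset: malformed
        insp_end = start + min_samples + int(below[0])
        if insp_end >= nxt:
            continue
        segments.append(
            BreathSegment(insp_start=start, insp_end=insp_end, exp_end=nxt,
                          sample_rate=float(sample_rate))
        )
    return segments


def integrate_volume(
    flow: np.ndarray, segment: BreathSegment, sample_rate: float | None = None
) -> tuple[float, float, np.ndarray]:
    """Trapezoidal volumes over one breath.

    Returns ``(vt_insp, vt_exp, volume_series)`` with volumes in ml; the
    volume series is zeroed at the inspiration onset.
    """
    flow = np.asarray(flow, dtype=float)
    rate = float(sample_rate if sample_rate is not None else segment.sample_rate)
    if segment.exp_end > flow.size:
        raise IndexError(
            f"segment end {segment.exp_end} outside series of length {flow.size}"
        )
    seg = flow[segment.slice]
    dt = 1.0 / rate
    vt_insp = 1000.0 * float(np.trapezoid(np.clip(seg, 0.0, None), dx=dt))
    vt_exp = 1000.0 * float(np.trapezoid(np.clip(-seg, 0.0, None), dx=dt))
    volume_series = 1000.0 * cumulative_trapezoid(seg, dx=dt, initial=0.0)
    return vt_insp, vt_exp, volume_series


def breath_metrics(record: WaveformRecord, segment: BreathSegment) -> BreathMetrics:
    """Peak flow/pressure over inspiration and instantaneous rate."""
    vt_insp, vt_exp, _ = integrate_volume(record.flow, segment, record.sample_rate)
    insp = slice(segment.insp_start, segment.insp_end)
    return BreathMetrics(
        vt_insp=vt_insp,
        vt_exp=vt_exp,
        peak_flow=float(np.max(record.flow[insp])),
        peak_p_ao=float(np.max(record.p_ao[insp])),
        rr_inst=60.0 / segment.duration,
    )


def select_breaths(segments: list[BreathSegment], n: int = 3) -> list[BreathSegment]:
    """First ``n`` complete breaths of an acquisition (fewer with a warning)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(segments) < n:
        warnings.warn(
            f"only {len(segments)} complete breaths available, requested {n}",
            stacklevel=2,
        )
    return segments[:n]
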