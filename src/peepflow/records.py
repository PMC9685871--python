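"""Core in-memory containers: synchronized waveforms and EIT sequences.

A :class:`WaveformRecord` holds one acquisition of airway-opening pressure
(``p_ao``), esophageal pressure (``p_eso``), gastric pressure (``p_ga``) and
airway flow sampled on a single uniform clock (200 Hz by convention), plus an
optional diaphragm electrical-activity channel (Edi) on its own, typically
slower, clock (100 Hz).  Pressures are in cmH2O, flow in L/s with inspiration
positive, Edi in uV.

An :class:`EITSequence` holds either a stack of 32x32 relative-impedance
frames or the pre-reduced four-ROI mean-impedance traces (anterior,
mid-anterior, mid-posterior, posterior), at 50 Hz by convention.  Impedance
is in arbitrary units relative to a device-set zero; only differences and
ratios of it are ever interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import AlignmentError, FormatError, SamplingError

#: canonical ROI names, anterior (ventral) to posterior (dorsal)
ROI_NAMES = ("anterior", "mid_anterior", "mid_posterior", "posterior")

EIT_GRID = 32

#: relative tolerance on sample-interval uniformity (1 part in 1e6)
TIME_UNIFORMITY_RTOL = 1e-6


def check_uniform_time(time: np.ndarray, rtol: float = TIME_UNIFORMITY_RTOL) -> float:
    """Validate a strictly increasing, uniform time vector; return the step.

    Raises :class:`SamplingError` naming the maximum relative deviation.
    """
    time = np.asarray(time, dtype=float)
    if time.ndim != 1 or time.size < 2:
        raise SamplingError("time vector must be 1-D with at least 2 samples")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise SamplingError("time must be strictly increasing")
    step = float(np.median(dt))
    max_dev = float(np.max(np.abs(dt - step)) / step)
    if max_dev > rtol:
        raise SamplingError(
            f"non-uniform sampling: max relative step deviation {max_dev:.3g} "
            f"exceeds tolerance {rtol:.1g}"
        )
    return step


@dataclass
class WaveformRecord:
    """One acquisition of pressure/flow waveforms on a uniform clock."""

    time: np.ndarray            # s
    p_ao: np.ndarray            # cmH2O
    p_eso: np.ndarray           # cmH2O
    p_ga: np.ndarray            # cmH2O (carried, unused by the analysis)
    flow: np.ndarray            # L/s, inspiration positive
    sample_rate: float = 200.0  # Hz
    edi: Optional[np.ndarray] = None       # uV, native clock
    edi_time: Optional[np.ndarray] = None  # s, same timeline as `time`
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("time", "p_ao", "p_eso", "p_ga", "flow"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.sample_rate <= 0:
            raise SamplingError("sample_rate must be positive")
        n = self.time.size
        for name in ("p_ao", "p_eso", "p_ga", "flow"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise SamplingError(
                    f"channel {name!r} has length {arr.size}, expected {n}"
                )
        check_uniform_time(self.time)
        if (self.edi is None) != (self.edi_time is None):
            raise SamplingError("edi and edi_time must be given together")
        if self.edi is not None:
            self.edi = np.asarray(self.edi, dtype=float)
            self.edi_time = np.asarray(self.edi_time, dtype=float)
            if self.edi.shape != self.edi_time.shape:
                raise SamplingError("edi and edi_time lengths differ")

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Record span in seconds (first to last sample)."""
        return float(self.time[-1] - self.time[0])


@dataclass
class EITSequence:
    """A thoracic EIT acquisition: frame stack or four-ROI mean traces.

    Exactly one of ``frames`` (shape ``(T, 32, 32)``) and ``roi_traces``
    (shape ``(4, T)``, anterior to posterior) is present at load time.
    """

    time: np.ndarray                       # s, one stamp per frame
    frames: Optional[np.ndarray] = None    # (T, 32, 32) relative impedance, AU
    roi_traces: Optional[np.ndarray] = None  # (4, T) mean Z per ROI, AU
    frame_rate: float = 50.0               # Hz
    lung_mask: Optional[np.ndarray] = None  # (32, 32) bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.frame_rate <= 0:
            raise FormatError("frame_rate must be positive")
        if (self.frames is None) == (self.roi_traces is None):
            raise FormatError(
                "exactly one of frames and roi_traces must be provided"
            )
        t = self.time.size
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=float)
            if (
                self.frames.ndim != 3
                or self.frames.shape[1:] != (EIT_GRID, EIT_GRID)
            ):
                raise FormatError(
                    f"expected frame stack (T, {EIT_GRID}, {EIT_GRID}), "
                    f"got {self.frames.shape}"
                )
            if self.frames.shape[0] != t:
                raise FormatError("frame count does not match time stamps")
        else:
            self.roi_traces = np.asarray(self.roi_traces, dtype=float)
            if self.roi_traces.shape != (4, t):
                raise FormatError(
                    f"expected roi_traces shape (4, {t}), got {self.roi_traces.shape}"
                )
        if self.lung_mask is not None:
            self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
            if self.lung_mask.shape != (EIT_GRID, EIT_GRID):
                raise FormatError("lung_mask must be 32x32")

    @property
    def n_frames(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class AlignedAcquisition:
    """A waveform record and EIT sequence placed on one timeline.

    ``offset`` is the number of seconds added to the EIT clock so that both
    modalities share the waveform clock.
    """

    waveforms: WaveformRecord
    eit: EITSequence
    offset: float = 0.0

    def eit_time(self) -> np.ndarray:
        """EIT frame stamps expressed on the waveform timeline."""
        return self.eit.time + self.offset

    def overlap(self) -> float:
        """Overlapping span (s) between waveforms and shifted EIT."""
        et = self.eit_time()
        lo = max(self.waveforms.time[0], et[0])
        hi = min(self.waveforms.time[-1], et[-1])
        return float(hi - lo)

    def __post_init__(self) -> None:
        if self.overlap() <= 0:
            raise AlignmentError(
                f"no timeline overlap at offset {self.offset:+.3f} s"
            )
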