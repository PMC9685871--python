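"""Regional tidal impedance analysis and DFV-guided PEEP selection.

The 32x32 impedance image is divided into four equal horizontal bands from
anterior (ventral) to posterior (dorsal).  For each analyzed breath the
end-expiratory and end-inspiratory frames are identified on the global
impedance trace; the per-ROI difference dZ between them is the regional
tidal impedance change, and its share of the total over all four ROIs is
taken as the regional share of tidal volume.  The dependent fraction of
ventilation is

    DFV (%) = 100 * dZ(dependent) / dZ(whole lung)

with the dependent region the two most posterior bands.  DFV = 50% marks an
antero-posteriorly homogeneous distribution, which is the titration target:
the selected PEEP is the level whose DFV is nearest 50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import CoverageError, DegenerateBreathError, PartitionError
from .records import EIT_GRID, ROI_NAMES, EITSequence

#: half-width (s) of the end-expiration search window around the flow onset
DEFAULT_SEARCH_WINDOW = 0.2

DEFAULT_BANDS = ((0, 8), (8, 16), (16, 24), (24, 32))


def round_pct(value: float) -> int:
    """Nearest whole percent, halves away from zero (display convention)."""
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)


@dataclass(frozen=True)
class RoiPartition:
    """Four ordered, disjoint row bands covering the 32-row grid."""

    bands: tuple = DEFAULT_BANDS
    lung_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.bands) != 4:
            raise PartitionError("exactly four ROI bands are required")
        prev_stop = 0
        for lo, hi in self.bands:
            if lo != prev_stop or hi <= lo:
                raise PartitionError(
                    f"bands must be disjoint, ordered and contiguous; got {self.bands}"
                )
            prev_stop = hi
        if prev_stop != EIT_GRID:
            raise PartitionError(f"bands must cover all {EIT_GRID} rows")


@dataclass(frozen=True)
class RegionalTidal:
    """Per-ROI tidal impedance change and derived distribution for one breath."""

    dz: np.ndarray               # (4,) AU, anterior..posterior
    dz_total: float              # AU
    proportions: np.ndarray      # (4,) % of total
    nondependent_pct: float      # % (anterior + mid-anterior)
    dependent_pct: float         # % (mid-posterior + posterior)
    dfv: float                   # %, == dependent_pct
    end_exp_frame: int
    end_insp_frame: int
    paradoxical: bool = False    # any negative regional dZ
    meta: dict = field(default_factory=dict)


def roi_mean_series(eit: EITSequence, partition: RoiPartition | None = None) -> np.ndarray:
    """Mean impedance per ROI and frame, shape (4, T).

    Pass-through when the sequence already carries reduced traces.
    """
    if eit.roi_traces is not None:
        return eit.roi_traces
    partition = partition or RoiPartition()
    mask = partition.lung_mask
    if mask is None and eit.lung_mask is not None:
        mask = eit.lung_mask
    out = np.empty((4, eit.n_frames))
    for i, (lo, hi) in enumerate(partition.bands):
        band = eit.frames[:, lo:hi, :]
        if mask is not None:
            band_mask = mask[lo:hi, :]
            if not band_mask.any():
                raise PartitionError(
                    f"ROI band {ROI_NAMES[i]!r} is empty after lung masking"
                )
            out[i] = band[:, band_mask].mean(axis=1)
        else:
            out[i] = band.reshape(eit.n_frames, -1).mean(axis=1)
    return out


def tidal_frames(
    global_z: np.ndarray,
    frame_rate: float,
    insp_start_frame: int,
    exp_end_frame: int,
    search_window: float = DEFAULT_SEARCH_WINDOW,
) -> tuple[int, int]:
    """End-expiratory and end-inspiratory frame of one breath.

    ``insp_start_frame``/``exp_end_frame`` delimit the breath on the frame
    clock.  End-inspiration is the global-impedance maximum within the
    breath; end-expiration is the minimum in a +-``search_window`` band
    around the inspiration onset (restricted to precede end-inspiration),
    absorbing the residual timing slack between the 50 Hz frames and the
    200 Hz flow onset.
    """
    global_z = np.asarray(global_z, dtype=float)
    n = global_z.size
    if not (0 <= insp_start_frame < exp_end_frame <= n):
        raise CoverageError(
            f"breath frames [{insp_start_frame}, {exp_end_frame}) outside coverage 0..{n}"
        )
    if exp_end_frame - insp_start_frame < 3:
        raise CoverageError("breath window spans fewer than 3 EIT frames")
    end_insp = insp_start_frame + int(
        np.argmax(global_z[insp_start_frame:exp_end_frame])
    )
    half = max(1, int(round(search_window * frame_rate)))
    lo = max(0, insp_start_frame - half)
    hi = min(end_insp, insp_start_frame + half + 1)
    if hi <= lo:
        hi = lo + 1
    end_exp = lo + int(np.argmin(global_z[lo:hi]))
    return end_exp, end_insp


def regional_tidal(
    roi_series: np.ndarray, end_exp_frame: int, end_insp_frame: int
) -> RegionalTidal:
    """Regional dZ, proportional distribution and DFV for one breath."""
    roi_series = np.asarray(roi_series, dtype=float)
    if end_exp_frame >= end_insp_frame:
        raise ValueError("end-expiratory frame must precede end-inspiratory frame")
    dz = roi_series[:, end_insp_frame] - roi_series[:, end_exp_frame]
    dz_total = float(dz.sum())
    if dz_total <= 0:
        raise DegenerateBreathError(
            f"non-positive total tidal impedance change ({dz_total:.3g} AU)"
        )
    proportions = 100.0 * dz / dz_total
    nondep = float(proportions[0] + proportions[1])
    dep = float(proportions[2] + proportions[3])
    return RegionalTidal(
        dz=dz, dz_total=dz_total, proportions=proportions,
        nondependent_pct=nondep, dependent_pct=dep, dfv=dep,
        end_exp_frame=int(end_exp_frame), end_insp_frame=int(end_insp_frame),
        paradoxical=bool(np.any(dz < 0)),
    )


def dependent_fraction(dz: Sequence[float]) -> float:
    """DFV (%) from four regional dZ values, anterior to posterior."""
    dz = np.asarray(dz, dtype=float)
    if dz.shape != (4,):
        raise ValueError("dz must hold exactly four ROI values")
    total = float(dz.sum())
    if total <= 0:
        raise DegenerateBreathError("non-positive total tidal impedance change")
    return 100.0 * float(dz[2] + dz[3]) / total


def titrate_peep(dfv_by_peep: Mapping[float, float]) -> float:
    """PEEP level whose DFV is nearest 50% (ties go to the lower PEEP)."""
    if not dfv_by_peep:
        raise ValueError("dfv_by_peep must contain at least one level")
    return min(dfv_by_peep, key=lambda p: (abs(dfv_by_peep[p] - 50.0), p))


def distribution_difference(
    dependent_pct: Sequence[float], nondependent_pct: Sequence[float]
) -> np.ndarray:
    """Dependent minus non-dependent distribution, percentage points.

    Negative values mean a predominantly non-dependent distribution; the
    zero crossing marks antero-posterior homogeneity.
    """
    dep = np.asarray(dependent_pct, dtype=float)
    nondep = np.asarray(nondependent_pct, dtype=float)
    if dep.shape != nondep.shape:
        raise ValueError("aggregate arrays must have matching shapes")
    return dep - nondep
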