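"""Per-breath lung mechanics from transpulmonary pressure.

Transpulmonary pressure is the airway-opening minus esophageal pressure,
P_TP = P_AO - P_ESO.  Each breath is fitted with the linear equation of
motion

    P_TP(t) = V(t)/C + R * V'(t) + P0

by ordinary least squares over the whole breath (volume zeroed at the
inspiration onset), yielding compliance C (ml/cmH2O), resistance R
(cmH2O*s/L) and the end-expiratory offset P0.  Because breathing is
continuous and un-paused, the maximum transpulmonary pressure is corrected
for the resistive pressure drop at that instant:

    P_TP,true max = P_TP,max - R * V'(at max)

where P_TP,max = P_AO - dP_ESO at the tracing maximum, and dP_ESO is the
esophageal swing from end-expiration to the moment of maximum P_TP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breaths import BreathSegment, integrate_volume
from .errors import ConditioningError
from .records import WaveformRecord

#: condition-number ceiling beyond which the fit is refused
MAX_CONDITION = 1e12


@dataclass(frozen=True)
class EquationOfMotionFit:
    compliance_c: float    # ml/cmH2O (from the 1/C coefficient)
    resistance_rrs: float  # cmH2O*s/L
    p0: float              # cmH2O, fit intercept
    fit_r2: float
    rejected: bool         # True when the compliance coefficient was <= 0


@dataclass(frozen=True)
class BreathMechanics:
    """All fitted and derived mechanics for one breath."""

    compliance_c: float
    resistance_rrs: float
    p0: float
    fit_r2: float
    rejected: bool
    delta_peso: float       # cmH2O, esophageal swing at P_TP max
    p_tp_max: float         # cmH2O
    p_tp_true_max: float    # cmH2O, resistive-corrected
    idx_tp_max: int         # sample index of the P_TP maximum
    flow_at_tp_max: float   # L/s


def transpulmonary_series(p_ao: np.ndarray, p_eso: np.ndarray) -> np.ndarray:
    """Elementwise P_AO - P_ESO."""
    p_ao = np.asarray(p_ao, dtype=float)
    p_eso = np.asarray(p_eso, dtype=float)
    if p_ao.shape != p_eso.shape:
        raise ValueError(f"length mismatch: {p_ao.shape} vs {p_eso.shape}")
    return p_ao - p_eso


def fit_equation_of_motion(
    p_tp: np.ndarray,
    flow: np.ndarray,
    volume_ml: np.ndarray,
    segment: BreathSegment,
    window: str = "breath",
) -> EquationOfMotionFit:
    """OLS fit of P_TP = V/C + R*V' + P0 over one breath.

    ``volume_ml`` is the breath-local volume series in ml, zeroed at the
    inspiration onset, with one sample per segment sample.  ``window``
    selects the fitted span: the full breath (default) or inspiration only.
    Volume is converted to liters inside the regression so the resistance
    coefficient is in cmH2O*s/L; the reported compliance is in ml/cmH2O.
    """
    p_tp = np.asarray(p_tp, dtype=float)
    flow = np.asarray(flow, dtype=float)
    volume_ml = np.asarray(volume_ml, dtype=float)
    if window == "breath":
        lo, hi = segment.insp_start, segment.exp_end
    elif window == "inspiration":
        lo, hi = segment.insp_start, segment.insp_end
    else:
        raise ValueError("window must be 'breath' or 'inspiration'")
    if hi - lo < 10:
        raise ValueError("fit window must span at least 10 samples")
    if volume_ml.size == segment.exp_end - segment.insp_start:
        vol = volume_ml[: hi - lo]
    else:
        vol = volume_ml[lo:hi]
    y = p_tp[lo:hi]
    v_l = vol / 1000.0
    x = np.column_stack([v_l, flow[lo:hi], np.ones(hi - lo)])

    cond = np.linalg.cond(x)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise ConditioningError(
            f"design matrix condition number {cond:.3g} (flow collinear with volume?)"
        )
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < 3:
        raise ConditioningError("rank-deficient design matrix")
    elastance, resistance, p0 = (float(c) for c in coef)
    resid = y - x @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    fit_r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    rejected = elastance <= 0
    compliance = 1000.0 / elastance if elastance != 0 else np.inf
    return EquationOfMotionFit(
        compliance_c=compliance, resistance_rrs=resistance, p0=p0,
        fit_r2=fit_r2, rejected=rejected,
    )


def ptp_max_summary(
    p_ao: np.ndarray,
    p_eso: np.ndarray,
    p_tp: np.ndarray,
    flow: np.ndarray,
    segment: BreathSegment,
    end_exp_idx: int | None = None,
    resistance_rrs: float = 0.0,
) -> tuple[float, float, float, int, float]:
    """Esophageal swing and (resistive-corrected) maximum transpulmonary pressure.

    Returns ``(delta_peso, p_tp_max, p_tp_true_max, idx_tp_max, flow_at_tp_max)``.
    ``end_exp_idx`` defaults to the last sample before the inspiration onset;
    it must lie within one breath-length of the onset.
    """
    p_tp = np.asarray(p_tp, dtype=float)
    if end_exp_idx is None:
        end_exp_idx = max(segment.insp_start - 1, 0)
    n_breath = segment.exp_end - segment.insp_start
    if not (0 <= end_exp_idx <= segment.insp_start) or (
        segment.insp_start - end_exp_idx > n_breath
    ):
        raise ValueError(
            f"end_exp_idx {end_exp_idx} outside the neighborhood of the breath onset"
        )
    rel = int(np.argmax(p_tp[segment.slice]))
    idx_tp_max = segment.insp_start + rel
    delta_peso = float(p_eso[idx_tp_max] - p_eso[end_exp_idx])
    p_tp_max = float(p_ao[idx_tp_max] - delta_peso)
    flow_at = float(flow[idx_tp_max])
    p_tp_true_max = p_tp_max - resistance_rrs * flow_at
    return delta_peso, p_tp_max, p_tp_true_max, idx_tp_max, flow_at


def analyze_breath(
    record: WaveformRecord,
    segment: BreathSegment,
    window: str = "breath",
) -> BreathMechanics:
    """Full mechanics for one breath of a record (fit + maxima summary)."""
    p_tp = transpulmonary_series(record.p_ao, record.p_eso)
    _, _, volume = integrate_volume(record.flow, segment, record.sample_rate)
    fit = fit_equation_of_motion(p_tp, record.flow, volume, segment, window=window)
    delta_peso, p_tp_max, p_tp_true_max, idx_tp_max, flow_at = ptp_max_summary(
        record.p_ao, record.p_eso, p_tp, record.flow, segment,
        resistance_rrs=fit.resistance_rrs,
    )
    return BreathMechanics(
        compliance_c=fit.compliance_c, resistance_rrs=fit.resistance_rrs,
        p0=fit.p0, fit_r2=fit.fit_r2, rejected=fit.rejected,
        delta_peso=delta_peso, p_tp_max=p_tp_max, p_tp_true_max=p_tp_true_max,
        idx_tp_max=idx_tp_max, flow_at_tp_max=flow_at,
    )
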