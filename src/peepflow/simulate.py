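"""Protocol-shaped synthetic data: NAVA breathing waveforms plus EIT.

The generator emulates a lavage-injured, spontaneously breathing animal on
neurally adjusted ventilatory assist over an incremental/decremental PEEP
ladder.  Its moving parts:

* **Edi** — repeating half-sine diaphragm bursts; rate and amplitude vary
  with PEEP by linear interpolation between the cohort endpoints (rapid and
  shallow at ZEEP, slow and deep at high PEEP).
* **Breath dynamics** — a single-compartment equation of motion driven by
  ventilator assist (NAVA level x Edi while Edi exceeds the trigger) plus
  muscle pressure (k_edi x Edi), integrated with a fixed-step 4th-order
  Runge-Kutta scheme at the waveform rate.  Esophageal pressure is the
  chest-wall elastic recoil minus muscle pressure, so inspiratory efforts
  produce negative esophageal swings.
* **Recruitment** — the dependent share of each breath's volume follows a
  logistic in PEEP calibrated to the cohort's dependent-fraction profile
  (30% at PEEP 0, ~48% at PEEP 9, 59% at PEEP 15).
* **EIT** — per-ROI impedance is an affine, optionally noisy map of the
  regional volume, painted into 32x32 band frames or emitted as reduced
  traces at 50 Hz.

Muscle gain ``k_edi`` is calibrated per animal and PEEP so that the steady
tidal volume hits the (PEEP-interpolated, animal-scaled) target; the linear
dynamics make that calibration exact from two probe breaths.  Animal
heterogeneity is multiplicative log-normal on volumes, rates and mechanics
and additive on the recruitment parameters.  Everything is driven by one
seeded generator: identical config and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import SimulationError
from .records import EIT_GRID, EITSequence, WaveformRecord


def _lerp(endpoints: tuple[float, float], peep: float, span: float = 15.0) -> float:
    lo, hi = endpoints
    return lo + (hi - lo) * float(peep) / span


@dataclass(frozen=True)
class Recruitment:
    """Logistic dependent-volume-fraction model f_dep(PEEP)."""

    f_min: float = 0.210679
    f_max: float = 0.678150
    p50: float = 7.457929    # cmH2O
    width: float = 5.168145  # cmH2O

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_min <= self.f_max <= 1.0):
            raise ValueError("need 0 <= f_min <= f_max <= 1")

    def __call__(self, peep: float) -> float:
        s = 1.0 / (1.0 + math.exp(-(peep - self.p50) / self.width))
        return self.f_min + (self.f_max - self.f_min) * s


def regional_partition_model(peep: float, recruitment: Recruitment) -> float:
    """Dependent volume fraction in [0, 1] at a given PEEP."""
    return recruitment(peep)


@dataclass(frozen=True)
class NoiseConfig:
    """Per-channel additive Gaussian noise levels."""

    p_ao: float = 0.10   # cmH2O
    p_eso: float = 0.10  # cmH2O
    p_ga: float = 0.05   # cmH2O
    flow: float = 0.005  # L/s
    edi: float = 0.02    # uV
    eit: float = 0.05    # AU


@dataclass(frozen=True)
class AnimalSpread:
    """Cohort heterogeneity: log-normal sigmas and additive jitters."""

    vt: float = 0.20
    rr: float = 0.15
    c_lung: float = 0.14
    r_aw: float = 0.20
    peak_paw: float = 0.15
    p50_jitter: float = 1.5   # cmH2O, additive on the recruitment midpoint
    f_jitter: float = 0.07    # additive on f_min/f_max, clipped


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated protocol run."""

    seed: int = 0
    n_animals: int = 10
    peep_ladder: tuple = (0, 3, 6, 9, 12, 15, 12, 9, 6, 3, 0)
    duration: float = 60.0       # s per acquisition
    sample_rate: float = 200.0   # Hz, waveforms
    edi_rate: float = 100.0      # Hz, Edi channel
    eit_rate: float = 50.0       # Hz, EIT frames
    nava_level: float = 2.3      # cmH2O/uV
    edi_trigger: float = 0.5     # uV, assist gating
    ti_fraction: float = 0.35    # neural inspiratory duty cycle
    rr_endpoints: tuple = (75.0, 38.0)        # breaths/min at PEEP 0 and 15
    vt_endpoints: tuple = (153.0, 297.0)      # ml
    peak_paw_endpoints: tuple = (6.6, 23.5)   # cmH2O
    c_lung_endpoints: tuple = (14.5, 26.9)    # ml/cmH2O
    r_aw: float = 8.0            # cmH2O*s/L
    c_cw: float = 100.0          # ml/cmH2O, chest wall
    eso_offset: float = -2.5     # cmH2O, end-expiratory esophageal baseline
    recruitment: Recruitment = field(default_factory=Recruitment)
    #: fraction of non-dependent volume in the extreme anterior band,
    #: interpolated between PEEP 0 and PEEP 15
    anterior_subsplit: tuple = (0.1286, 0.0244)
    #: fraction of dependent volume in the extreme posterior band
    posterior_subsplit: tuple = (0.011, 0.034)
    eit_gain_per_roi: tuple = (1.0, 1.0, 1.0, 1.0)      # AU/ml
    eit_baseline_per_roi: tuple = (120.0, 180.0, 160.0, 110.0)  # AU
    eit_lag: float = 0.0         # s: EIT clock runs behind by this much
    emit_frames: bool = False    # paint 32x32 frames instead of traces
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    spread: AnimalSpread = field(default_factory=AnimalSpread)

    def incremental_steps(self) -> int:
        """Index of the ladder maximum; steps up to it are incremental."""
        return int(np.argmax(self.peep_ladder))


@dataclass(frozen=True)
class AnimalParams:
    """Realized per-animal parameters after random effects."""

    animal_id: int
    vt_scale: float
    rr_scale: float
    c_lung_scale: float
    r_aw_scale: float
    peak_paw_scale: float
    recruitment: Recruitment


@dataclass
class SimulatedAcquisition:
    """One animal x PEEP-step acquisition with generator ground truth."""

    waveforms: WaveformRecord
    eit: EITSequence
    truth: dict


def simulate_edi(
    rr: float,
    amplitude: float,
    ti_fraction: float,
    duration: float,
    rate: float,
) -> np.ndarray:
    """Half-sine Edi burst train sampled at ``rate`` Hz."""
    if rr <= 0 or amplitude < 0 or duration <= 0 or not 0 < ti_fraction < 1:
        raise ValueError("invalid Edi parameters")
    t = np.arange(int(round(duration * rate))) / rate
    return edi_waveform(t, rr, amplitude, ti_fraction)


def edi_waveform(
    t: np.ndarray, rr: float, amplitude: float, ti_fraction: float
) -> np.ndarray:
    """Evaluate the burst train at arbitrary times (vectorized)."""
    cycle = 60.0 / rr
    ti = ti_fraction * cycle
    phase = np.asarray(t, dtype=float) % cycle
    burst = phase < ti
    out = np.zeros_like(phase)
    out[burst] = amplitude * np.sin(np.pi * phase[burst] / ti)
    return out


def _integrate_compartment(
    drive_half: np.ndarray, n: int, h: float, c_rs: float, r_aw: float
) -> np.ndarray:
    """RK4 integration of R*V' = D(t) - V/C_rs; V in ml, returns V[0..n-1].

    ``drive_half`` holds the driving pressure at half-step resolution
    (``drive_half[2k]`` at t_k, ``drive_half[2k+1]`` at t_k + h/2).
    """
    k = 1000.0 / r_aw  # ml/s per cmH2O
    inv_c = 1.0 / c_rs
    v = 0.0
    out = np.empty(n)
    out[0] = 0.0
    for i in range(n - 1):
        d0 = drive_half[2 * i]
        dh = drive_half[2 * i + 1]
        d1 = drive_half[2 * i + 2]
        k1 = k * (d0 - v * inv_c)
        k2 = k * (dh - (v + 0.5 * h * k1) * inv_c)
        k3 = k * (dh - (v + 0.5 * h * k2) * inv_c)
        k4 = k * (d1 - (v + h * k3) * inv_c)
        v = v + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = v
    if not np.all(np.isfinite(out)):
        bad = int(np.flatnonzero(~np.isfinite(out))[0])
        raise SimulationError(f"non-finite volume at integration step {bad}")
    return out


def simulate_breath_dynamics(
    config: SimConfig,
    peep: float,
    rr: float,
    edi_amplitude: float,
    k_edi: float,
    c_lung: float,
    r_aw: float,
    duration: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[WaveformRecord, dict]:
    """Integrate the NAVA-driven single-compartment model at one PEEP.

    Returns the (optionally noisy) waveform record and a truth dict holding
    the noise-free volume trajectory and the generating parameters.
    """
    duration = config.duration if duration is None else duration
    fs = config.sample_rate
    n = int(round(duration * fs))
    h = 1.0 / fs
    c_rs = 1.0 / (1.0 / c_lung + 1.0 / config.c_cw)

    t_half = np.arange(2 * n - 1) * (h / 2.0)
    edi_half = edi_waveform(t_half, rr, edi_amplitude, config.ti_fraction)
    assist_half = np.where(
        edi_half > config.edi_trigger, config.nava_level * edi_half, 0.0
    )
    drive_half = assist_half + k_edi * edi_half

    volume = _integrate_compartment(drive_half, n, h, c_rs, r_aw)

    t = np.arange(n) / fs
    edi = edi_half[::2]
    assist = assist_half[::2]
    drive = drive_half[::2]
    flow = (drive - volume / c_rs) / r_aw  # L/s
    p_ao = peep + assist
    p_eso = config.eso_offset + volume / config.c_cw - k_edi * edi
    p_ga = 5.0 + 0.3 * volume / config.c_cw  # carried only; not analyzed

    n_edi = int(round(duration * config.edi_rate))
    edi_time = np.arange(n_edi) / config.edi_rate
    edi_native = edi_waveform(edi_time, rr, edi_amplitude, config.ti_fraction)

    if rng is not None:
        nz = config.noise
        p_ao = p_ao + rng.normal(0.0, nz.p_ao, n)
        p_eso = p_eso + rng.normal(0.0, nz.p_eso, n)
        p_ga = p_ga + rng.normal(0.0, nz.p_ga, n)
        flow = flow + rng.normal(0.0, nz.flow, n)
        edi_native = edi_native + rng.normal(0.0, nz.edi, n_edi)

    record = WaveformRecord(
        time=t, p_ao=p_ao, p_eso=p_eso, p_ga=p_ga, flow=flow,
        sample_rate=fs, edi=edi_native, edi_time=edi_time,
    )
    truth = {
        "volume_ml": volume,
        "c_lung": c_lung,
        "c_rs": c_rs,
        "r_aw": r_aw,
        "k_edi": k_edi,
        "rr": rr,
        "edi_amplitude": edi_amplitude,
        "peep": peep,
    }
    return record, truth


def calibrate_k_edi(
    config: SimConfig,
    peep: float,
    rr: float,
    edi_amplitude: float,
    c_lung: float,
    r_aw: float,
    vt_target: float,
) -> float:
    """Muscle gain giving the target steady tidal volume (exact by linearity).

    Two noise-free probe runs (two breathing cycles each) bracket the linear
    map k_edi -> Vt; negative solutions (assist alone overshoots the target)
    are clamped to zero.
    """
    probe_T = 2.0 * 60.0 / rr

    def probe_vt(k: float) -> float:
        _, truth = simulate_breath_dynamics(
            config, peep, rr, edi_amplitude, k, c_lung, r_aw, duration=probe_T
        )
        v = truth["volume_ml"]
        second = v[v.size // 2:]
        return float(second.max() - second.min())

    vt0 = probe_vt(0.0)
    vt1 = probe_vt(1.0)
    if vt1 <= vt0:
        raise SimulationError("muscle drive has no effect; check Edi amplitude")
    k = (vt_target - vt0) / (vt1 - vt0)
    return max(k, 0.0)


def synthesize_eit(
    volume_ml: np.ndarray,
    sample_rate: float,
    f_dep: float,
    config: SimConfig,
    peep: float,
    rng: Optional[np.random.Generator] = None,
) -> tuple[EITSequence, dict]:
    """Map a volume trajectory to a four-ROI (or frame-stack) EIT sequence.

    The dependent/non-dependent split follows ``f_dep``; the extreme bands
    receive a PEEP-interpolated sub-fraction of their half's volume.  Each
    ROI trace is ``gain * V_roi + baseline + noise``.
    """
    n_frames = int(math.floor((volume_ml.size - 1) / sample_rate * config.eit_rate)) + 1
    frame_t = np.arange(n_frames) / config.eit_rate
    wave_t = np.arange(volume_ml.size) / sample_rate
    v = np.interp(frame_t, wave_t, volume_ml)

    ant_frac = _lerp(config.anterior_subsplit, peep)
    post_frac = _lerp(config.posterior_subsplit, peep)
    shares = np.array([
        (1.0 - f_dep) * ant_frac,
        (1.0 - f_dep) * (1.0 - ant_frac),
        f_dep * (1.0 - post_frac),
        f_dep * post_frac,
    ])
    gains = np.asarray(config.eit_gain_per_roi, dtype=float)
    baselines = np.asarray(config.eit_baseline_per_roi, dtype=float)
    traces = gains[:, None] * shares[:, None] * v[None, :] + baselines[:, None]
    if rng is not None and config.noise.eit > 0:
        traces = traces + rng.normal(0.0, config.noise.eit, traces.shape)

    time = frame_t - config.eit_lag
    if config.emit_frames:
        frames = np.empty((n_frames, EIT_GRID, EIT_GRID))
        for i, (lo, hi) in enumerate(((0, 8), (8, 16), (16, 24), (24, 32))):
            frames[:, lo:hi, :] = traces[i][:, None, None]
        eit = EITSequence(time=time, frames=frames, frame_rate=config.eit_rate)
    else:
        eit = EITSequence(time=time, roi_traces=traces, frame_rate=config.eit_rate)
    truth = {"f_dep": f_dep, "roi_shares": shares, "source_traces": traces}
    return eit, truth


def draw_animals(config: SimConfig, rng: np.random.Generator) -> list[AnimalParams]:
    """Sample the cohort's per-animal random effects."""
    sp = config.spread
    animals = []
    for i in range(config.n_animals):
        f_min = float(np.clip(
            config.recruitment.f_min + rng.normal(0.0, sp.f_jitter), 0.02, 0.90))
        f_max = float(np.clip(
            config.recruitment.f_max + rng.normal(0.0, sp.f_jitter), f_min + 0.01, 0.98))
        rec = Recruitment(
            f_min=f_min, f_max=f_max,
            p50=config.recruitment.p50 + float(rng.normal(0.0, sp.p50_jitter)),
            width=config.recruitment.width,
        )
        animals.append(AnimalParams(
            animal_id=i + 1,
            vt_scale=float(rng.lognormal(0.0, sp.vt)),
            rr_scale=float(rng.lognormal(0.0, sp.rr)),
            c_lung_scale=float(rng.lognormal(0.0, sp.c_lung)),
            r_aw_scale=float(rng.lognormal(0.0, sp.r_aw)),
            peak_paw_scale=float(rng.lognormal(0.0, sp.peak_paw)),
            recruitment=rec,
        ))
    return animals


def generate_acquisition(
    config: SimConfig,
    animal: AnimalParams,
    peep: float,
    phase: str,
    rng: np.random.Generator,
) -> SimulatedAcquisition:
    """One 1-minute acquisition for one animal at one PEEP step."""
    rr = _lerp(config.rr_endpoints, peep) * animal.rr_scale
    vt_target = _lerp(config.vt_endpoints, peep) * animal.vt_scale
    c_lung = _lerp(config.c_lung_endpoints, peep) * animal.c_lung_scale
    r_aw = config.r_aw * animal.r_aw_scale
    paw_excess = (_lerp(config.peak_paw_endpoints, peep) - peep) * animal.peak_paw_scale
    edi_amplitude = paw_excess / config.nava_level

    k_edi = calibrate_k_edi(config, peep, rr, edi_amplitude, c_lung, r_aw, vt_target)
    record, truth = simulate_breath_dynamics(
        config, peep, rr, edi_amplitude, k_edi, c_lung, r_aw, rng=rng
    )
    f_dep = regional_partition_model(peep, animal.recruitment)
    eit, eit_truth = synthesize_eit(
        truth["volume_ml"], config.sample_rate, f_dep, config, peep, rng=rng
    )
    record.meta.update({
        "animal": animal.animal_id, "peep": peep, "phase": phase, "fio2": 1.0,
    })
    truth.update(eit_truth)
    truth["vt_target"] = vt_target
    return SimulatedAcquisition(waveforms=record, eit=eit, truth=truth)


def generate_protocol_dataset(config: SimConfig) -> list[SimulatedAcquisition]:
    """Full cohort: every animal through the PEEP ladder, seeded."""
    rng = np.random.default_rng(config.seed)
    animals = draw_animals(config, rng)
    peak = config.incremental_steps()
    acquisitions = []
    for animal in animals:
        for step, peep in enumerate(config.peep_ladder):
            phase = "incremental" if step <= peak else "decremental"
            acq = generate_acquisition(config, animal, float(peep), phase, rng)
            acq.waveforms.meta["step"] = step
            acquisitions.append(acq)
    return acquisitions


def write_dataset(acquisitions, out_dir, eit_format: str = "csv") -> list:
    """Write simulated acquisitions in the formats the readers consume.

    Each acquisition becomes ``aNN_sMM.csv`` (+ ``.meta.json``/``.edi.csv``
    sidecars) and ``aNN_sMM.eit.csv`` or ``aNN_sMM.h5``.
    """
    from pathlib import Path

    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for acq in acquisitions:
        meta = acq.waveforms.meta
        stem = f"a{int(meta.get('animal', 0)):02d}_s{int(meta.get('step', 0)):02d}"
        written.append(_io.write_waveforms(acq.waveforms, out / f"{stem}.csv"))
        if eit_format == "h5" or acq.eit.frames is not None:
            written.append(_io.write_eit(acq.eit, out / f"{stem}.h5"))
        else:
            written.append(_io.write_eit(acq.eit, out / f"{stem}.eit.csv"))
    return written


def make_mechanics_breath(
    compliance: float,
    resistance: float,
    p0: float,
    vt_ml: float = 200.0,
    ti: float = 0.5,
    duration: float = 1.6,
    sample_rate: float = 200.0,
    noise_sigma: float = 0.0,
    rng: Optional[np.random.Generator] = None,
):
    """Single breath obeying the equation of motion exactly (plus noise).

    Flow is a half-sine inspiration followed by an exponential expiration;
    volume is its trapezoidal integral, and transpulmonary pressure is
    built as V/C + R*V' + P0, optionally with Gaussian noise of standard
    deviation ``noise_sigma`` (cmH2O) on the pressure.  Returns
    ``(p_tp, flow, volume_ml, segment)`` ready for the multilinear fit.
    """
    from .breaths import BreathSegment  # local import: avoid cycle at import time

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    amp = np.pi * vt_ml / (2.0 * ti) / 1000.0  # L/s so the lobe integrates to vt
    flow = np.where(t < ti, amp * np.sin(np.pi * t / ti), 0.0)
    tau = resistance * compliance / 1000.0  # s
    exp_mask = t >= ti
    flow[exp_mask] = -(vt_ml / 1000.0 / tau) * np.exp(-(t[exp_mask] - ti) / tau)
    volume_ml = 1000.0 * cumulative_trapezoid(flow, t, initial=0.0)
    p_tp = volume_ml / compliance + resistance * flow + p0
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        p_tp = p_tp + rng.normal(0.0, noise_sigma, n)
    segment = BreathSegment(
        insp_start=0, insp_end=int(round(ti * sample_rate)), exp_end=n,
        sample_rate=sample_rate,
    )
    return p_tp, flow, volume_ml, segment


def realized_tidal_volume(truth: dict) -> float:
    """Generator-state tidal volume (ml) of a steady breath."""
    v = truth["volume_ml"]
    half = v[v.size // 4:]
    return float(half.max() - half.min())
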