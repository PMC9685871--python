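# Methods

This note documents the models, numerical choices and limitations behind
peepflow: what each stage computes, what the synthetic-data generator does
and does not emulate, and where genuinely open design choices were decided.

## Signals and alignment

Waveforms (airway pressure P_AO, esophageal pressure P_ESO, gastric
pressure P_GA, flow V̇) live on one uniform clock, 200 Hz by convention;
uniformity is enforced to 1 part in 10⁶ of the sample interval. Diaphragm
electrical activity (Edi) is carried on its own clock (100 Hz) and is never
resampled — the analysis does not use it numerically; it exists so NAVA
recordings round-trip losslessly. Flow is normalized to inspiration-positive
L/s at load; pressures to cmH₂O.

EIT sequences arrive either as 32×32 relative-impedance frame stacks
(HDF5) or pre-reduced four-ROI mean traces (CSV), at 50 Hz. Both paths
yield identical downstream results for the same underlying data (tested);
the reduction is a plain mean over each band's pixels, with an optional
lung mask (off by default — the four equal bands over the full grid are
the common vendor convention, and they keep the extreme-band shares small,
a percent or two of the total).

The two modalities are assumed simultaneous (declared offset 0). An
opt-in cross-correlation aligner scans lags in frame-period steps over
±2 s and maximizes the correlation between global impedance and integrated
flow; on noise-free simulator output it recovers embedded lags to within
one frame period. How the original acquisition chains were time-locked is
not knowable from the outside, so neither method is claimed as "the" one.

## Breath detection

Inspiration starts at a positive-going crossing of a flow threshold
(default 0.02 L/s) sustained for at least 0.08 s; expiration starts at the
subsequent return of flow through zero; the breath ends at the next onset.
The hysteresis pair rejects pneumotachograph noise without missing the
short inspirations of rapid shallow breathing (~0.25 s inspiratory time at
75 breaths/min). Incomplete leading/trailing breaths are discarded because
both ΔZ and the mechanics fit need full cycles. Volumes are trapezoidal
integrals of the flow lobes, in ml. The analysis uses the first three
complete breaths of each acquisition.

Edi-based (neural) cycle detection is deliberately not implemented: flow
detection is self-contained and the downstream quantities are insensitive
to the exact onset sample (the EIT extrema search has its own window).

## Mechanics

The per-breath fit is ordinary least squares of P_TP = V/C + R·V̇ + P0 over
the full breath (inspiration-only fitting is available as a flag). The
intercept P0 is included because breaths ride on a PEEP-dependent
end-expiratory transpulmonary offset. Volume enters the regression in
liters so the resistance coefficient lands in cmH₂O·s/L; compliance is
reported in ml/cmH₂O. The design matrix is refused above condition number
1e12 (a flow channel proportional to volume is the canonical failure); a
non-positive compliance coefficient flags the fit as rejected — values are
still reported, but the pipeline excludes such breaths from aggregates.

End-expiration for the esophageal swing is the last sample before the
inspiration onset — the natural reading of "P_ESO at end-expiration" for
the breath that contains the P_TP maximum. The corrected maximum
subtracts the resistive term at the instant of the tracing maximum:
P_TP,true max = P_TP,max − R·V̇. By construction this never exceeds
P_TP,max while flow at the maximum is non-negative.

No static (occlusion/plateau) methods are implemented anywhere: the target
recordings are continuous un-paused spontaneous breathing.

## Regional distribution and titration

End-inspiration is the global-impedance maximum within the breath;
end-expiration is the minimum in a ±0.2 s window around the flow-defined
onset (restricted to precede end-inspiration). The window absorbs the
timing slack between 50 Hz frames and the 200 Hz flow clock.

Regional ΔZ may legitimately be negative (pendelluft-like paradox); it is
flagged, never clamped, and proportions are still computed against the
four-ROI total. Proportions are computed per breath and then averaged
(mean of ratios). Display rounding is to the nearest whole percent, halves
away from zero; internal values keep full precision. A breath whose total
ΔZ is non-positive is excluded with a logged reason rather than patched.

Titration minimizes |DFV − 50| over the available PEEP levels with ties
broken toward the lower PEEP (the clinically conservative choice). The
dependent-minus-non-dependent difference curve is also emitted; its zero
crossing marks the homogeneity point.

## Statistics

The Shapiro–Wilk screen is applied to paired differences (paired case) or
to each sample (unpaired); any rejection at α = 0.05 routes to the
nonparametric branch. Constant samples make Shapiro–Wilk undefined; the
default policy routes them nonparametrically (configurable to raise).

The signed-rank test drops zero differences before ranking (Wilcoxon's
original treatment) and uses the exact null distribution up to n = 25,
the tie-corrected normal approximation beyond. scipy.stats provides the
test engines; exactness is verified in the test suite against an
independent brute-force enumeration of all 2ⁿ sign assignments.

The Bonferroni family defaults to m = 15, the unordered pairs among six
PEEP levels (0.05/15 ≈ 0.0033); the family behind any published threshold
is rarely enumerated explicitly, so m is configurable. Incremental and
decremental phases are compared paired by animal and PEEP level, with
their own family size. A null simulation (paired N(0,1), n = 10, 2,000
replicates) keeps the routed pipeline's type-I error within [0.03, 0.07]
at nominal 0.05 (tested).

## The synthetic-data generator

The generator emulates one acquisition per animal per PEEP step of the
0→3→…→15→…→0 cmH₂O ladder: 60 s of NAVA-assisted spontaneous breathing
plus matched EIT.

**Breathing model.** Edi is a half-sine burst train (duty cycle 0.35).
The ventilator applies PEEP plus NAVA-level × Edi while Edi exceeds a
0.5 µV trigger; muscle pressure is k_edi × Edi. A single compartment
R·V̇ = P_appl + P_mus − V/C_rs − PEEP, with 1/C_rs = 1/C_lung + 1/C_cw,
is integrated by fixed-step 4th-order Runge–Kutta at 200 Hz. Esophageal
pressure is the baseline plus chest-wall recoil minus muscle pressure, so
inspiratory efforts produce negative esophageal swings and the fitted
P_TP model recovers exactly C_lung, the airway resistance and
PEEP − baseline as the intercept.

**Calibration.** Respiratory rate (75→38 /min), tidal volume target
(153→297 ml), lung compliance (14.5→26.9 ml/cmH₂O) and peak airway
pressure (6.6→23.5 cmH₂O) interpolate linearly in PEEP between the cohort
endpoints. The Edi amplitude is pinned by the peak-pressure target and the
NAVA level (2.3 cmH₂O/µV); the muscle gain k_edi is then solved per animal
and PEEP from two noise-free probe breaths so the steady tidal volume hits
its target — exact because the dynamics are linear in the drive. Airway
resistance defaults to 8 cmH₂O·s/L and chest-wall compliance to
100 ml/cmH₂O, typical for ~30 kg supine swine.

**Recruitment.** The dependent share of each breath's volume follows a
logistic in PEEP, f_dep(P) = f_min + (f_max − f_min)/(1 + e^−(P−p50)/w),
with defaults (0.2107, 0.6782, 7.458, 5.168) fitted once so the curve
passes through 30% at PEEP 0 and 59% at PEEP 15 exactly and tracks the
intermediate cohort means (47.9% at PEEP 9, 54.1% at PEEP 12); a single
logistic cannot hit every printed step mean simultaneously, and this
compromise keeps the DFV-nearest-50 rule selecting PEEP 9 on the
population curve. The extreme anterior/posterior bands receive a
PEEP-interpolated sub-fraction of their half's volume, reproducing the
cohort's small extreme-band shares (anterior 9→1%, posterior 0→2%).

**EIT synthesis.** Each ROI trace is gain × regional volume + baseline +
Gaussian noise at 50 Hz; frames, when requested, paint each band
uniformly. Default gains are equal across ROIs so impedance shares equal
volume shares; unequal per-ROI gains are available to emulate arbitrary
device scaling (DFV is invariant to a global rescale but not to
differential gains — that is a physical property of the measurement, not
a bug).

**Heterogeneity and noise.** Animals draw multiplicative log-normal
effects on tidal volume (σ=0.20), rate (0.15), compliance (0.14),
resistance (0.20) and peak pressure (0.15), and additive jitter on the
recruitment parameters (±0.07 on the fraction asymptotes, ±1.5 cmH₂O on
the midpoint), sized to approximate the cohort's printed spreads; channel
noise is modest (0.1 cmH₂O pressures, 0.005 L/s flow, 0.05 AU impedance).
Everything derives from one seeded generator; identical config and seed
give bit-identical datasets.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: gas exchange (blood-gas values are
pass-through metadata), two-compartment/pendelluft dynamics, cardiogenic
oscillations and electrode artifacts on EIT, within-animal breath-to-breath
variability beyond channel noise, EIT image reconstruction itself, and any
time-dependence of recruitment (steady state is assumed at every step).
One known tension inherited from the calibration targets: at ZEEP the
printed peak airway pressure can supply only ~6.6 cmH₂O of drive while the
printed tidal volume and compliance require ~15, so the balance comes from
muscle pressure and the simulated esophageal swings run near −8 cmH₂O,
larger than the cohort's −2.5 ± 1.5. The corrected maximum transpulmonary
pressure is unaffected (≈8.6 cmH₂O at PEEP 0, ≈23.4 at PEEP 15, matching
the cohort within its spread).

## Problem sizes used in the test suite

The acceptance-grade end-to-end checks run the full default conditions:
10 animals × 11 ladder steps × 60 s acquisitions (330 analyzed breaths,
660 EIT scans), with the cohort analysis completing in well under a
minute. Unit and property tests use shorter acquisitions (6–20 s) and
small cohorts, which fully exercise the same code paths since every
acquisition is processed independently.

## Known limitations

* Breath delimitation is flow-based only; heavily distorted flow signals
  (secretions, leaks) would need artifact handling upstream.
* The fitted "respiratory-system" resistance from a transpulmonary-pressure
  fit is physically the lung/airway resistance; the conventional symbol is
  kept for continuity with the field's reporting.
* Proportion aggregation uses mean-of-ratios; computing proportions from
  mean ΔZ instead coincides at whole-percent rounding for the documented
  values but is not implemented as an option.
* The titration rule on a finite ladder is sensitive to cohort spread when
  two levels straddle 50% closely; with realistic animal heterogeneity the
  selected level can move between adjacent steps across seeds, which is a
  faithful property of the rule, not noise in the pipeline.
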