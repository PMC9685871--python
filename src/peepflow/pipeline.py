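"""End-to-end protocol analysis: acquisitions -> breaths -> mechanics -> EIT -> stats.

``run_protocol`` consumes a directory of matched waveform/EIT pairs (one
per animal and PEEP step, as written by the simulator or converted from
recordings), analyzes the first breaths of every acquisition, aggregates
per PEEP step and phase, runs the comparison battery with a Bonferroni
family, and applies the DFV-nearest-50% titration rule.  Breaths failing
any stage (rejected mechanics fit, degenerate tidal impedance, missing EIT
coverage) are excluded from every aggregate and logged with a reason;
incremental and decremental phases are never pooled.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import breaths as _breaths
from . import eit as _eit
from . import io as _io
from . import mechanics as _mechanics
from . import stats as _stats
from .errors import (
    ConditioningError,
    CoverageError,
    DegenerateBreathError,
    ManifestError,
    PeepflowError,
)
from .records import ROI_NAMES, EITSequence, WaveformRecord

AGGREGATE_COLUMNS = (
    "vt_insp", "rr_inst", "peak_flow", "peak_p_ao",
    "compliance_c", "resistance_rrs", "delta_peso", "p_tp_max", "p_tp_true_max",
    *(f"prop_{name}" for name in ROI_NAMES),
    "nondependent_pct", "dependent_pct", "dfv",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable threshold of the protocol analysis."""

    n_breaths: int = 3
    flow_threshold: float = _breaths.DEFAULT_FLOW_THRESHOLD
    min_insp_duration: float = _breaths.DEFAULT_MIN_INSP_DURATION
    fit_window: str = "breath"
    search_window: float = _eit.DEFAULT_SEARCH_WINDOW
    alignment: str = "declared-offset"
    alignment_offset: float = 0.0
    alpha: float = 0.05
    family_size: int = _stats.DEFAULT_FAMILY_SIZE
    alpha_normality: float = 0.05
    partition: _eit.RoiPartition = field(default_factory=_eit.RoiPartition)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        if "partition" in raw:
            raw["partition"] = _eit.RoiPartition(
                bands=tuple(tuple(b) for b in raw["partition"])
            )
        return cls(**raw)


@dataclass
class ProtocolResult:
    """All tables produced by one protocol run."""

    per_breath: pd.DataFrame
    per_step: pd.DataFrame
    comparisons: pd.DataFrame
    titration: dict
    regressions: pd.DataFrame
    exclusions: pd.DataFrame
    counts: dict


def analyze_acquisition(
    record: WaveformRecord,
    eit_seq: EITSequence,
    config: AnalysisConfig | None = None,
) -> tuple[list[dict], list[dict]]:
    """Analyze one acquisition; returns (breath rows, exclusion records)."""
    config = config or AnalysisConfig()
    aligned = _io.align(
        record, eit_seq, method=config.alignment, offset=config.alignment_offset
    )
    eit_time = aligned.eit_time()
    roi_series = _eit.roi_mean_series(eit_seq, config.partition)
    global_z = roi_series.sum(axis=0)

    segments = _breaths.detect_breaths(
        record.flow, record.sample_rate,
        min_insp_duration=config.min_insp_duration,
        flow_threshold=config.flow_threshold,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        selected = _breaths.select_breaths(segments, config.n_breaths)

    base = {k: record.meta.get(k) for k in ("animal", "peep", "phase", "step")}
    rows, exclusions = [], []
    for b_idx, seg in enumerate(selected):
        label = {**base, "breath": b_idx}
        try:
            metrics = _breaths.breath_metrics(record, seg)
            mech = _mechanics.analyze_breath(record, seg, window=config.fit_window)
            if mech.rejected:
                raise ConditioningError(
                    "compliance coefficient non-positive; fit rejected"
                )
            t0 = record.time[seg.insp_start]
            t1 = record.time[seg.exp_end - 1]
            f0 = int(np.searchsorted(eit_time, t0, side="left"))
            f1 = int(np.searchsorted(eit_time, t1, side="right"))
            end_exp, end_insp = _eit.tidal_frames(
                global_z, eit_seq.frame_rate, f0, f1,
                search_window=config.search_window,
            )
            regional = _eit.regional_tidal(roi_series, end_exp, end_insp)
        except (ConditioningError, CoverageError, DegenerateBreathError,
                ValueError) as err:
            exclusions.append({**label, "reason": f"{type(err).__name__}: {err}"})
            continue
        rows.append({
            **label,
            "duration": seg.duration,
            "vt_insp": metrics.vt_insp, "vt_exp": metrics.vt_exp,
            "peak_flow": metrics.peak_flow, "peak_p_ao": metrics.peak_p_ao,
            "rr_inst": metrics.rr_inst,
            "compliance_c": mech.compliance_c,
            "resistance_rrs": mech.resistance_rrs,
            "p0": mech.p0, "fit_r2": mech.fit_r2,
            "delta_peso": mech.delta_peso,
            "p_tp_max": mech.p_tp_max, "p_tp_true_max": mech.p_tp_true_max,
            **{f"dz_{n}": regional.dz[i] for i, n in enumerate(ROI_NAMES)},
            **{f"prop_{n}": regional.proportions[i] for i, n in enumerate(ROI_NAMES)},
            "nondependent_pct": regional.nondependent_pct,
            "dependent_pct": regional.dependent_pct,
            "dfv": regional.dfv,
            "end_exp_frame": regional.end_exp_frame,
            "end_insp_frame": regional.end_insp_frame,
            "paradoxical": regional.paradoxical,
        })
    return rows, exclusions


def _per_step(per_breath: pd.DataFrame) -> pd.DataFrame:
    grouped = per_breath.groupby(["phase", "peep"], sort=True)
    pieces = {"n_breaths": grouped.size()}
    for col in AGGREGATE_COLUMNS:
        pieces[f"{col}_mean"] = grouped[col].mean()
        pieces[f"{col}_sd"] = grouped[col].std(ddof=1)
    return pd.DataFrame(pieces).reset_index()


def _animal_step_means(per_breath: pd.DataFrame, column: str = "dfv") -> pd.DataFrame:
    """Per-animal mean of a column by phase and PEEP (wide: animals x PEEP)."""
    return per_breath.pivot_table(
        index="animal", columns=["phase", "peep"], values=column, aggfunc="mean"
    )


def _comparisons(per_breath: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Wilcoxon/t battery: DFV over all PEEP pairs (incremental, paired by
    animal) and incremental vs decremental at each shared level."""
    table = _animal_step_means(per_breath)
    rows = []

    def one(label_a, label_b, a, b, family, m):
        mask = ~(np.isnan(a) | np.isnan(b))
        if mask.sum() < 3:
            return
        try:
            res = _stats.compare(
                a[mask], b[mask], paired=True, alpha=config.alpha, family_size=m,
                alpha_normality=config.alpha_normality,
            )
        except PeepflowError:
            return
        rows.append({
            "family": family, "a": label_a, "b": label_b,
            "test": res.test_name, "statistic": res.statistic,
            "p_value": res.p_value, "n_pairs": res.n,
            "alpha_adjusted": res.alpha_adjusted, "significant": res.significant,
        })

    if "incremental" in table.columns.get_level_values(0):
        inc = table["incremental"]
        peeps = sorted(inc.columns)
        m = config.family_size
        for pa, pb in itertools.combinations(peeps, 2):
            one(f"PEEP {pa:g}", f"PEEP {pb:g}",
                inc[pa].to_numpy(), inc[pb].to_numpy(), "dfv-peep-pairs", m)
    phases = set(table.columns.get_level_values(0))
    if {"incremental", "decremental"} <= phases:
        shared = sorted(
            set(table["incremental"].columns) & set(table["decremental"].columns)
        )
        for p in shared:
            one(f"inc PEEP {p:g}", f"dec PEEP {p:g}",
                table["incremental"][p].to_numpy(),
                table["decremental"][p].to_numpy(),
                "dfv-inc-vs-dec", len(shared))
    return pd.DataFrame(
        rows, columns=["family", "a", "b", "test", "statistic", "p_value",
                       "n_pairs", "alpha_adjusted", "significant"],
    )


def _regressions(per_breath: pd.DataFrame) -> pd.DataFrame:
    """OLS of regional distribution on PEEP within each phase."""
    rows = []
    for phase, sub in per_breath.groupby("phase"):
        for col in ("dependent_pct", "nondependent_pct", "dfv"):
            means = sub.groupby("peep")[col].mean()
            if means.index.nunique() < 2:
                continue
            slope, intercept, r2 = _stats.regress_on_peep(
                means.index.to_numpy(), means.to_numpy()
            )
            rows.append({"phase": phase, "response": col, "slope": slope,
                         "intercept": intercept, "r_squared": r2})
    return pd.DataFrame(
        rows, columns=["phase", "response", "slope", "intercept", "r_squared"]
    )


def analyze_dataset(
    acquisitions, config: AnalysisConfig | None = None
) -> ProtocolResult:
    """Analyze in-memory (record, eit) pairs or SimulatedAcquisition objects."""
    config = config or AnalysisConfig()
    all_rows, all_excl = [], []
    for acq in acquisitions:
        if hasattr(acq, "waveforms"):
            record, eit_seq = acq.waveforms, acq.eit
        else:
            record, eit_seq = acq
        rows, excl = analyze_acquisition(record, eit_seq, config)
        all_rows.extend(rows)
        all_excl.extend(excl)
    if not all_rows:
        raise ManifestError("no analyzable breaths in the dataset")
    per_breath = pd.DataFrame(all_rows)
    per_step = _per_step(per_breath)
    comparisons = _comparisons(per_breath, config)
    regressions = _regressions(per_breath)

    inc = per_breath[per_breath["phase"] == "incremental"]
    source = inc if len(inc) else per_breath
    dfv_by_peep = (
        _animal_step_means(source).T.groupby(level="peep").mean().mean(axis=1)
    )
    titration = {
        "selected_peep": float(_eit.titrate_peep(dfv_by_peep.to_dict())),
        "dfv_by_peep": {float(k): float(v) for k, v in dfv_by_peep.items()},
        "rule": "PEEP with DFV nearest 50%, ties toward the lower PEEP",
    }
    counts = {
        "n_acquisitions": int(len(acquisitions)),
        "n_breaths_selected": int(len(per_breath) + len(all_excl)),
        "n_breaths_analyzed": int(len(per_breath)),
        "n_breaths_excluded": int(len(all_excl)),
        "n_eit_scans": int(2 * len(per_breath)),
    }
    exclusions = pd.DataFrame(
        all_excl, columns=["animal", "peep", "phase", "step", "breath", "reason"]
    )
    return ProtocolResult(
        per_breath=per_breath, per_step=per_step, comparisons=comparisons,
        titration=titration, regressions=regressions, exclusions=exclusions,
        counts=counts,
    )


def discover_pairs(data_dir) -> list[tuple[Path, Path]]:
    """Match waveform CSVs with their EIT partner files; report orphans."""
    data_dir = Path(data_dir)
    waveforms = {
        p.name[: -len(".csv")]: p
        for p in sorted(data_dir.glob("*.csv"))
        if not p.name.endswith((".eit.csv", ".edi.csv"))
    }
    eits: dict[str, Path] = {}
    for p in sorted(data_dir.glob("*.eit.csv")):
        eits[p.name[: -len(".eit.csv")]] = p
    for p in sorted(data_dir.glob("*.h5")):
        eits.setdefault(p.stem, p)
    orphans = sorted(set(waveforms) ^ set(eits))
    if not waveforms or orphans:
        raise ManifestError(
            f"unmatched waveform/EIT pairs in {data_dir}: {orphans or 'no data found'}"
        )
    return [(waveforms[k], eits[k]) for k in sorted(waveforms)]


def run_protocol(data_dir, config: AnalysisConfig | None = None) -> ProtocolResult:
    """Load a data directory and run the full protocol analysis."""
    pairs = discover_pairs(data_dir)
    loaded = [(_io.read_waveforms(w), _io.read_eit(e)) for w, e in pairs]
    return analyze_dataset(loaded, config)


def write_report(result: ProtocolResult, out_dir) -> list[Path]:
    """Emit the result tables and plot-ready CSVs; deterministic bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.8g")
        written.append(path)

    save(result.per_breath, "per_breath.csv")
    save(result.per_step, "per_step.csv")
    save(result.comparisons, "comparisons.csv")
    save(result.regressions, "regressions.csv")
    save(result.exclusions, "exclusions.csv")

    # plot-ready analogues of the result figures
    step = result.per_step
    dist_cols = ["phase", "peep"] + [
        c for c in step.columns if c.startswith("prop_")
    ]
    save(step[dist_cols], "fig_distribution_by_roi.csv")
    save(step[["phase", "peep", "nondependent_pct_mean", "nondependent_pct_sd",
               "dependent_pct_mean", "dependent_pct_sd"]],
         "fig_dependent_vs_nondependent.csv")
    save(step[["phase", "peep", "dfv_mean", "dfv_sd"]], "fig_dfv_by_peep.csv")
    diff = step[["phase", "peep"]].copy()
    diff["difference_pp"] = _eit.distribution_difference(
        step["dependent_pct_mean"].to_numpy(),
        step["nondependent_pct_mean"].to_numpy(),
    )
    save(diff, "fig_distribution_difference.csv")

    titration_path = out / "titration.json"
    titration_path.write_text(json.dumps(result.titration, indent=1, sort_keys=True))
    written.append(titration_path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(result.counts, indent=1, sort_keys=True))
    written.append(manifest_path)
    return written
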