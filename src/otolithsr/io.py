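"""File formats, configuration, and the cohort pipeline driver.

All tabular data travel as CSV, reports as JSON, configuration as YAML.
Every writer has a matching reader and round-trips losslessly; run CSVs
carry a small ``.meta.json`` sidecar holding acquisition metadata (cadence,
core geometry, the FEBs-1 mean ⁸⁸Sr voltage, seeds) that the CSV itself
cannot express.

The pipeline composes the stages in their fixed order — reduction →
cropping → GMV alignment → smoothing → classification → summaries — and
quarantines otoliths that fail (flagged cracked, or undetermined calls)
without aborting the cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .reduction import (RawAblationRun, StandardAcquisition, ReductionConfig,
                        ValidationError, reduce_run, reduction_report,
                        RUN_COLUMNS, PHASES)
from .profiles import OtolithProfile, crop_profile, gmv_align
from .smoothing import SmoothingConfig, SmoothedProfile, smooth_profile
from .classify import ClassifierConfig, LifeHistoryCall, classify_otolith
from .summaries import CohortSummary, summarize_cohort

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# runs and standards
# ---------------------------------------------------------------------------

def write_run_csv(run: RawAblationRun, path: str | Path) -> None:
    path = Path(path)
    run.data.to_csv(path, index=False)
    sidecar = {"cadence_s": run.cadence_s, "scan_speed": run.scan_speed,
               "spot_um": run.spot_um, "meta": _jsonable(run.meta)}
    path.with_suffix(".meta.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))


def read_run_table(path: str | Path) -> RawAblationRun:
    """Read and validate a run CSV (plus its metadata sidecar, if present).

    Diagnostics name the offending column or row: missing voltage columns,
    non-monotone time stamps, and unknown phase labels are all rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in RUN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")
    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        row = int(np.argmax(bad_phase.to_numpy()))
        raise ValidationError(
            f"{path.name}: unknown phase {df['phase'].iloc[row]!r} at row {row}")
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValidationError(f"{path.name}: time_s not increasing at row {row}")
    kwargs = {}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        extra = json.loads(sidecar.read_text())
        kwargs = {"cadence_s": extra.get("cadence_s", 0.5),
                  "scan_speed": extra.get("scan_speed", C.SCAN_SPEED_UM_S),
                  "spot_um": extra.get("spot_um", C.SPOT_UM),
                  "meta": extra.get("meta", {})}
    return RawAblationRun(data=df, **kwargs)


def write_standards_csv(standards: list[StandardAcquisition],
                        path: str | Path) -> None:
    pd.DataFrame([{"time_s": s.time_s, "measured_ratio": s.measured_ratio,
                   "certified_ratio": s.certified_ratio}
                  for s in standards]).to_csv(path, index=False)


def read_standards_csv(path: str | Path) -> list[StandardAcquisition]:
    df = pd.read_csv(path)
    for col in ("time_s", "measured_ratio"):
        if col not in df.columns:
            raise ValidationError(f"{Path(path).name}: missing column {col!r}")
    return [StandardAcquisition(
        float(r.time_s), float(r.measured_ratio),
        float(getattr(r, "certified_ratio", C.SRM987_RATIO)))
        for r in df.itertuples()]


# ---------------------------------------------------------------------------
# annuli, profiles, smoothed fits, calls
# ---------------------------------------------------------------------------

def write_annuli_csv(annuli: dict[str, np.ndarray], path: str | Path) -> None:
    rows = [{"otolith_id": oid, "annulus_index": i + 1,
             "distance_um": float(d)}
            for oid, dists in annuli.items() for i, d in enumerate(dists)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annuli_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    for col in ("otolith_id", "annulus_index", "distance_um"):
        if col not in df.columns:
            raise ValidationError(f"{Path(path).name}: missing column {col!r}")
    out = {}
    for oid, grp in df.groupby("otolith_id", sort=False):
        grp = grp.sort_values("annulus_index")
        out[str(oid)] = grp["distance_um"].to_numpy(float)
    return out


def write_profile_csv(profile: OtolithProfile, path: str | Path) -> None:
    pd.DataFrame({
        "position_um": profile.positions_um, "ratio": profile.ratio,
        "v88": profile.v88, "sr_mgkg": profile.sr_mgkg, "age": profile.age,
    }).to_csv(path, index=False)


def read_profile_csv(path: str | Path, annuli_um: np.ndarray,
                     otolith_id: str = "",
                     quality_flag: str = "ok") -> OtolithProfile:
    df = pd.read_csv(path)
    for col in ("position_um", "ratio", "v88", "sr_mgkg", "age"):
        if col not in df.columns:
            raise ValidationError(f"{Path(path).name}: missing column {col!r}")
    return OtolithProfile(
        positions_um=df["position_um"].to_numpy(float),
        ratio=df["ratio"].to_numpy(float),
        v88=df["v88"].to_numpy(float),
        sr_mgkg=df["sr_mgkg"].to_numpy(float),
        annuli_um=np.asarray(annuli_um, float),
        age=df["age"].to_numpy(float),
        quality_flag=quality_flag, otolith_id=otolith_id)


def write_smoothed_csv(sm: SmoothedProfile, path: str | Path) -> None:
    pd.DataFrame({"position_um": sm.positions_um, "fit": sm.fit,
                  "lower": sm.lower, "upper": sm.upper,
                  }).to_csv(path, index=False)


def call_to_dict(call: LifeHistoryCall) -> dict:
    d = dataclasses.asdict(call)
    return _jsonable(d)


def write_calls_csv(calls: list[LifeHistoryCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append({
            "otolith_id": c.otolith_id, "status": c.status,
            "type_id": c.type_id if c.type_id is not None else "",
            "entry_age": c.entry_age if c.entry_age is not None else "",
            "natal_mean": c.natal.mean_ratio if c.natal else "",
            "natal_se": c.natal.se_ratio if c.natal else "",
            "juvenile_mean": c.juvenile.mean_ratio if c.juvenile else "",
            "juvenile_se": c.juvenile.se_ratio if c.juvenile else "",
            "truth_label": c.truth_label if c.truth_label is not None else "",
            "reason": c.reason})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Paths, stage settings and the seed for one cohort analysis."""

    runs_dir: str = "runs"
    annuli_csv: str = "annuli.csv"
    out_dir: str = "out"
    #: optional CSV (otolith_id, core_um, edge_um) overriding run metadata.
    crops_csv: str | None = None
    #: optional CSV (otolith_id, quality_flag) marking cracked otoliths.
    quality_csv: str | None = None
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0
    log_level: str = "INFO"
    make_plots: bool = False

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key, cls in (("reduction", ReductionConfig),
                         ("smoothing", SmoothingConfig),
                         ("classifier", ClassifierConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = cls(**d[key])
        return PipelineConfig(**d)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    summary: CohortSummary | None
    calls: list
    excluded: list
    out_dir: Path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def process_run(run: RawAblationRun, standards, annuli_um,
                config: PipelineConfig, quality_flag: str = "ok",
                core_um: float | None = None, edge_um: float | None = None,
                ) -> tuple[OtolithProfile, SmoothedProfile, LifeHistoryCall]:
    """Reduce, crop, align, smooth and classify one otolith."""
    reduced = reduce_run(run, standards, config.reduction)
    if core_um is None:
        core_um = float(run.meta.get("core_offset_um", 0.0))
    if edge_um is None:
        edge_um = core_um + float(run.meta.get(
            "core_to_edge_um", reduced.distances_um()[-1] - core_um))
    profile = crop_profile(reduced, core_um, edge_um, annuli_um,
                           quality_flag=quality_flag)
    if "truth_label" in run.meta:
        profile.meta["truth_label"] = int(run.meta["truth_label"])
    profile, alignment = gmv_align(profile, config.classifier)
    profile.meta["alignment"] = dataclasses.asdict(alignment)
    profile.meta["reduction_report"] = reduction_report(reduced)
    smoothed = smooth_profile(profile, config.smoothing)
    call = classify_otolith(profile, smoothed, config.classifier)
    return profile, smoothed, call


def run_pipeline(config: PipelineConfig,
                 base_dir: str | Path = ".") -> PipelineResult:
    """Analyze every run in ``config.runs_dir`` and write cohort artifacts.

    Per otolith: profile CSV, smoothed CSV, call JSON (and optionally a
    figure); for the cohort: calls CSV, summary JSON and the summary
    tables as CSV. Cracked/excluded otoliths and undetermined calls are
    quarantined, not fatal. Deterministic for fixed inputs and seed.
    """
    base = Path(base_dir)
    runs_dir = base / config.runs_dir
    if not runs_dir.is_dir():
        raise ValidationError(f"runs directory not found: {runs_dir}")
    annuli_path = base / config.annuli_csv
    if not annuli_path.exists():
        raise ValidationError(f"annuli table not found: {annuli_path}")
    annuli = read_annuli_csv(annuli_path)
    out = base / config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    quality = {}
    if config.quality_csv:
        qdf = pd.read_csv(base / config.quality_csv)
        quality = dict(zip(qdf["otolith_id"].astype(str),
                           qdf["quality_flag"].astype(str)))
    crops = {}
    if config.crops_csv:
        cdf = pd.read_csv(base / config.crops_csv)
        crops = {str(r.otolith_id): (float(r.core_um), float(r.edge_um))
                 for r in cdf.itertuples()}

    run_files = sorted(p for p in runs_dir.glob("*.csv")
                       if not p.name.endswith(".standards.csv"))
    calls, excluded = [], []
    for run_path in run_files:
        run = read_run_table(run_path)
        oid = str(run.meta.get("otolith_id", run_path.stem))
        flag = quality.get(oid, "ok")
        if flag != "ok":
            log.info("%s: excluded (quality flag %r)", oid, flag)
            excluded.append({"otolith_id": oid, "reason": flag})
            continue
        std_path = run_path.with_name(run_path.stem + ".standards.csv")
        if not std_path.exists():
            excluded.append({"otolith_id": oid, "reason": "no standards file"})
            continue
        standards = read_standards_csv(std_path)
        ann = annuli.get(oid)
        if ann is None:
            excluded.append({"otolith_id": oid, "reason": "no annuli"})
            continue
        core_edge = crops.get(oid, (None, None))
        try:
            profile, smoothed, call = process_run(
                run, standards, ann, config, quality_flag=flag,
                core_um=core_edge[0], edge_um=core_edge[1])
        except ValidationError as err:
            log.warning("%s: quarantined (%s)", oid, err)
            excluded.append({"otolith_id": oid, "reason": str(err)})
            continue
        calls.append(call)
        write_profile_csv(profile, out / f"{oid}.profile.csv")
        write_smoothed_csv(smoothed, out / f"{oid}.smoothed.csv")
        (out / f"{oid}.call.json").write_text(
            json.dumps(call_to_dict(call), indent=1, sort_keys=True))
        if config.make_plots:
            from .plots import plot_profile
            plot_profile(profile, smoothed, out / f"{oid}.png")

    ok_calls = [c for c in calls if c.status == "ok"]
    summary = summarize_cohort(calls) if ok_calls else None
    write_calls_csv(calls, out / "cohort_calls.csv")
    report = {
        "n_runs": len(run_files),
        "n_classified": len(ok_calls),
        "n_undetermined": sum(1 for c in calls if c.status != "ok"),
        "n_excluded": len(excluded),
        "excluded": excluded,
        "seed": config.seed,
    }
    if summary is not None:
        report.update(counts={str(k): v for k, v in summary.counts.items()},
                      percents={str(k): v for k, v in summary.percents.items()},
                      pct_anadromous=summary.pct_anadromous,
                      pct_nonanadromous=summary.pct_nonanadromous)
        summary.migration_table.to_csv(out / "migration_table.csv")
        summary.region_table.to_csv(out / "region_table.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(_jsonable(report), indent=1, sort_keys=True))
    return PipelineResult(summary=summary, calls=calls, excluded=excluded,
                          out_dir=out)


def write_cohort(otoliths, out_dir: str | Path,
                 truth: bool = True) -> None:
    """Write a simulated cohort in the pipeline's on-disk layout."""
    out = Path(out_dir)
    (out / "runs").mkdir(parents=True, exist_ok=True)
    annuli = {}
    truths = {}
    for oto in otoliths:
        write_run_csv(oto.raw_run, out / "runs" / f"{oto.otolith_id}.csv")
        write_standards_csv(
            oto.standards, out / "runs" / f"{oto.otolith_id}.standards.csv")
        annuli[oto.otolith_id] = oto.annuli_um
        truths[oto.otolith_id] = {
            "truth_label": oto.truth_label,
            "truth_entry_age": oto.truth_entry_age,
            "core_offset_um": oto.core_offset_um,
            "core_to_edge_um": oto.core_to_edge_um,
        }
    write_annuli_csv(annuli, out / "annuli.csv")
    if truth:
        (out / "truth.json").write_text(
            json.dumps(_jsonable(truths), indent=1, sort_keys=True))
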