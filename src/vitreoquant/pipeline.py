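"""Orchestration: simulate → score → analyse, reproducibly.

Each stage reads/writes plain files (PNG stacks + JSON sidecars, tidy
CSVs, a JSON report) and drops the effective configuration and package
version next to its outputs, so a run is fully reconstructible. All
randomness flows from the single top-level seed through per-eye
substreams.
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

from . import __version__
from .errors import GatedVolumeError, SegmentationError, ValidationError
from .io import read_volume, write_volume
from .selection import thin_every_other
from .stats import AnalysisConfig, ReliabilityReport, run_reliability_analysis
from .synthetic import SyntheticConfig, generate_cohort
from .vi import VIParams, compute_vi, compute_volume_vi

log = logging.getLogger("vitreoquant")

__all__ = [
    "CohortSpec",
    "PipelineConfig",
    "cmd_simulate",
    "cmd_score",
    "cmd_analyse",
    "run_all",
    "run_study",
]


@dataclass
class CohortSpec:
    """Synthetic cohort: size and severity distribution."""

    n_eyes: int = 49
    level_distribution: dict = field(
        default_factory=lambda: {"kind": "lognormal", "median": 2.0, "sigma": 0.8}
    )
    curvature_range: tuple = (-0.4, 0.8)


@dataclass
class PipelineConfig:
    seed: int = 1
    cohort: CohortSpec = field(default_factory=CohortSpec)
    scan: SyntheticConfig = field(default_factory=SyntheticConfig)
    vi: VIParams = field(default_factory=VIParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, section):
            values = dict(raw.get(section, {}))
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(values) - names
            if unknown:
                raise ValidationError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
            for k, v in values.items():
                if isinstance(v, list):
                    values[k] = tuple(tuple(e) if isinstance(e, list) else e for e in v)
            return klass(**values)

        return cls(
            seed=int(raw.get("seed", 1)),
            cohort=build(CohortSpec, "cohort"),
            scan=build(SyntheticConfig, "scan"),
            vi=build(VIParams, "vi"),
            analysis=build(AnalysisConfig, "analysis"),
        )

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = dataclasses.asdict(self)
        d["scan"]["inflammation_gradient"] = (
            None
            if self.scan.inflammation_gradient is None
            else [float(g) for g in self.scan.inflammation_gradient]
        )
        return plain(d)


def _write_effective_config(config: PipelineConfig, out_dir: Path) -> None:
    payload = {"version": __version__, **config.to_dict()}
    with open(out_dir / "effective_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def cmd_simulate(config: PipelineConfig, out_dir) -> Path:
    """Write a synthetic cohort (PNG stacks + ground-truth JSON) to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(
        n_eyes=config.cohort.n_eyes,
        level_distribution=config.cohort.level_distribution,
        base_config=config.scan,
        seed=config.seed,
        curvature_range=tuple(config.cohort.curvature_range),
        quantize=True,
    )
    truths = {}
    for volume, truth in cohort:
        write_volume(volume, out_dir / "eyes" / volume.eye_id)
        truths[volume.eye_id] = truth.summary()
    with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    _write_effective_config(config, out_dir)
    log.info("simulated %d eyes into %s", len(cohort), out_dir)
    return out_dir


def cmd_score(cohort_dir, config: PipelineConfig, out_dir) -> Path:
    """Score every volume of a cohort; tidy per-scan VI CSV + gating log."""
    cohort_dir, out_dir = Path(cohort_dir), Path(out_dir)
    eye_dirs = sorted(p for p in (cohort_dir / "eyes").iterdir() if p.is_dir())
    if not eye_dirs:
        raise ValidationError(f"no eye directories under {cohort_dir / 'eyes'}")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, excluded = [], []
    for eye_dir in eye_dirs:
        volume = read_volume(eye_dir)
        try:
            indices = thin_every_other(volume.n_scans)
        except ValidationError as exc:
            excluded.append({"eye_id": volume.eye_id, "reason": str(exc)})
            continue
        from .io import quality_gate

        gate = quality_gate(volume)
        if not gate.included:
            excluded.append(
                {
                    "eye_id": volume.eye_id,
                    "reason": f"quality gate: {gate.n_low_quality} scans below {gate.threshold}",
                }
            )
            continue
        for pos, idx in enumerate(indices):
            try:
                score = compute_vi(volume.scans[idx], config.vi)
                rows.append(
                    {
                        "eye_id": volume.eye_id,
                        "scan_index": idx,
                        "scan_pos": pos,
                        "vi": score.vi,
                        "vitreous_signal": score.vitreous_signal,
                        "rpe_signal": score.rpe_signal,
                        "n_vitreous_px": score.n_vitreous_px,
                        "n_rpe_px": score.n_rpe_px,
                    }
                )
            except (SegmentationError, GatedVolumeError) as exc:
                rows.append(
                    {
                        "eye_id": volume.eye_id,
                        "scan_index": idx,
                        "scan_pos": pos,
                        "vi": np.nan,
                        "vitreous_signal": np.nan,
                        "rpe_signal": np.nan,
                        "n_vitreous_px": 0,
                        "n_rpe_px": 0,
                    }
                )
                log.warning("scan %s/%d failed: %s", volume.eye_id, idx, exc)
    if not rows:
        raise ValidationError("no scoreable volumes in the cohort")
    scores = pd.DataFrame(rows)
    scores.to_csv(out_dir / "scores.csv", index=False)
    with open(out_dir / "excluded.json", "w", encoding="utf-8") as fh:
        json.dump(excluded, fh, indent=1, sort_keys=True)
    _write_effective_config(config, out_dir)
    log.info("scored %d eyes (%d excluded)", scores["eye_id"].nunique(), len(excluded))
    return out_dir / "scores.csv"


def _summary_text(report: ReliabilityReport) -> str:
    lines = [
        f"vitreoquant reliability report (n = {report.n_eyes} eyes)",
        f"median reference VI {report.median_reference_vi:.4f} (IQR {report.iqr_reference_vi:.4f})",
        f"ICC ({report.icc.model}) {report.icc.icc:.3f} "
        f"[{report.icc.ci_low:.3f}, {report.icc.ci_high:.3f}]",
        "",
        "deviation from the 9-scan reference standard:",
    ]
    for a in report.agreement.values():
        lines.append(
            f"  {a.scheme:>3}: median |diff| {a.median_abs_diff:.4f} (IQR {a.iqr:.4f}), "
            f"LoA [{a.loa_low:.4f}, {a.loa_high:.4f}]"
        )
    if report.roc.get("median"):
        lines.append("")
        lines.append("AUC, median split of the reference:")
        for r in report.roc["median"]:
            lines.append(f"  {r.scheme:>3}: {r.auc:.3f} [{r.ci_low:.3f}, {r.ci_high:.3f}]")
    for w in report.wilcoxon:
        lines.append(
            f"  {w.scheme_a} vs {w.scheme_b}: p_raw {w.p_raw:.4f}, p_holm {w.p_adjusted:.4f}"
        )
    if report.flags:
        lines.append("")
        lines.append("flags: " + "; ".join(report.flags))
    return "\n".join(lines) + "\n"


def cmd_analyse(scores_csv, config: PipelineConfig, out_dir) -> ReliabilityReport:
    """Reliability analysis from a per-scan VI CSV; report files on disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(scores_csv)
    required = {"eye_id", "scan_pos", "vi"}
    if not required.issubset(scores.columns):
        raise ValidationError(f"scores CSV must have columns {sorted(required)}")
    vi_wide = scores.pivot(index="eye_id", columns="scan_pos", values="vi").sort_index()
    if vi_wide.shape[1] != 9:
        raise ValidationError(f"expected 9 scan positions per eye, got {vi_wide.shape[1]}")
    report = run_reliability_analysis(vi_wide, config.analysis)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    report.table1().to_csv(out_dir / "table1_deviation.csv", index=False)
    if report.roc.get("median"):
        report.table2("median").to_csv(out_dir / "table2_auc.csv", index=False)
    with open(out_dir / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(_summary_text(report))
    _write_effective_config(config, out_dir)
    return report


def run_all(config: PipelineConfig, out_dir) -> ReliabilityReport:
    """simulate → score → analyse under one seed, in one output tree."""
    out_dir = Path(out_dir)
    cmd_simulate(config, out_dir / "cohort")
    scores_csv = cmd_score(out_dir / "cohort", config, out_dir / "scores")
    return cmd_analyse(scores_csv, config, out_dir / "analysis")


def run_study(config: PipelineConfig):
    """simulate → score → analyse fully in memory (no files).

    Returns ``(vi_wide, report)``: the eyes × 9 per-scan VI table and the
    reliability report computed from it.
    """
    cohort = generate_cohort(
        n_eyes=config.cohort.n_eyes,
        level_distribution=config.cohort.level_distribution,
        base_config=config.scan,
        seed=config.seed,
        curvature_range=tuple(config.cohort.curvature_range),
    )
    rows = {}
    for volume, _ in cohort:
        scores = compute_volume_vi(volume, config.vi)
        rows[volume.eye_id] = [s.vi if s is not None else np.nan for s in scores]
    vi_wide = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return vi_wide, run_reliability_analysis(vi_wide, config.analysis)
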