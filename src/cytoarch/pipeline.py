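"""Scene quantification and cross-condition reporting.

``quantify_scene`` runs every analysis on one scene and returns a flat
metric dict; ``run_pipeline`` maps it over scene bundles grouped by
condition, aggregates per-condition mean +/- SEM (the scene is the
statistical unit), runs the configured tests, and writes tables and maps.

All thresholds are carried in :class:`PipelineConfig` and recorded, with a
config hash, in every report.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anchoring import (
    ANCHOR_THRESHOLD_NM,
    NEIGHBOR_RADIUS_NM,
    anchored_angle_map,
    anchored_summary,
    classify_anchored,
    neighbor_pairs,
    periphery_height,
)
from .architecture import (
    QUASI_ORTHOGONAL_DEG,
    actin_pair_samples,
    orientation_distribution,
    volume_ratio,
)
from .errors import CytoarchError, ValidationError
from .io import read_scene
from .model import Scene
from .organelles import (
    ISG_WINDOW_NM,
    actin_nearest_mt,
    filament_organelle_distances,
)
from .stats import GroupSummary, anova_tukey


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the quantification pipeline, in one place."""

    resample_nm: float = 4.0
    anchor_threshold_nm: float = ANCHOR_THRESHOLD_NM
    neighbor_radius_nm: float = NEIGHBOR_RADIUS_NM
    isg_window_nm: float = ISG_WINDOW_NM
    vm_proximity_nm: float = 300.0
    orientation_bin_deg: float = 10.0
    anchored_angle_bin_deg: float = 15.0
    pair_distance_bin_nm: float = 10.0
    actin_isg_bin_nm: float = 75.0
    mt_isg_bin_nm: float = 100.0
    quasi_orthogonal_deg: float = QUASI_ORTHOGONAL_DEG
    strict: bool = False  # fail the whole run on the first bad scene

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def quantify_scene(
    scene: Scene, config: PipelineConfig = PipelineConfig()
) -> dict[str, float]:
    """Run all quantifications on one scene; returns a flat metric dict.

    Metrics that need absent components (no dorsal membrane, no ISGs, no
    MTs) come back as NaN rather than failing the scene.
    """
    vm = scene.membrane("vm")
    if vm is None:
        raise ValidationError("scene has no VM membrane")
    actin = scene.filaments_of("actin")
    mts = scene.filaments_of("mt")
    if not actin:
        raise ValidationError("scene has no actin filaments")

    metrics: dict[str, float] = {}
    dist = orientation_distribution(actin, vm, config.orientation_bin_deg)
    metrics["quasi_orthogonal_fraction"] = dist.fraction_quasi_orthogonal
    metrics["semi_parallel_fraction"] = dist.fraction_semi_parallel
    metrics["steep_band_fraction"] = dist.band_fraction(60.0, 90.0)
    metrics["n_actin"] = float(len(actin))
    metrics["n_mt"] = float(len(mts))
    metrics["actin_volume_ratio"] = volume_ratio(actin, scene.frame, kind="actin")
    metrics["mt_volume_ratio"] = (
        volume_ratio(mts, scene.frame, kind="mt") if mts else np.nan
    )

    anchored, _ = classify_anchored(actin, vm, config.anchor_threshold_nm)
    count, percent = anchored_summary(anchored, actin)
    metrics["anchored_count"] = float(count)
    metrics["anchored_percent"] = percent

    dorsal = scene.membrane("dorsal")
    metrics["periphery_height_nm"] = (
        periphery_height(vm, dorsal) if dorsal is not None else np.nan
    )

    isg = scene.organelle_set("isg")
    if isg is not None and len(isg) > 0:
        actin_isg = filament_organelle_distances(
            actin, isg, vm, config.resample_nm, max_range_nm=config.isg_window_nm)
        metrics["actin_isg_mean_nm"] = (
            float(actin_isg.distance_nm.mean()) if len(actin_isg) else np.nan)
        mt_isg = (filament_organelle_distances(mts, isg, vm, config.resample_nm)
                  if mts else None)
        metrics["mt_isg_mean_nm"] = (
            float(mt_isg.distance_nm.mean())
            if mt_isg is not None and len(mt_isg) else np.nan)
    else:
        metrics["actin_isg_mean_nm"] = np.nan
        metrics["mt_isg_mean_nm"] = np.nan

    if mts:
        nearest = actin_nearest_mt(actin, mts, vm, config.resample_nm)
        metrics["shortest_mt_distance_mean_nm"] = float(
            nearest.shortest_mt_distance_nm.mean())
    else:
        metrics["shortest_mt_distance_mean_nm"] = np.nan
    return metrics


def scene_detail_tables(
    scene: Scene, config: PipelineConfig = PipelineConfig()
) -> dict[str, pd.DataFrame]:
    """Per-scene sample tables (pair samples, anchored maps, distances)."""
    vm = scene.membrane("vm")
    actin = scene.filaments_of("actin")
    out: dict[str, pd.DataFrame] = {}
    if len(actin) >= 2:
        out["actin_pair_samples"] = actin_pair_samples(
            actin, vm, config.resample_nm)
    anchored, _ = classify_anchored(actin, vm, config.anchor_threshold_nm)
    pairs = neighbor_pairs(anchored, config.neighbor_radius_nm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples, _hists = anchored_angle_map(
            anchored, pairs, config.anchored_angle_bin_deg)
    out["anchored_angle_samples"] = samples
    isg = scene.organelle_set("isg")
    if isg is not None and len(isg) > 0:
        out["actin_isg_samples"] = filament_organelle_distances(
            actin, isg, vm, config.resample_nm, max_range_nm=config.isg_window_nm)
    mts = scene.filaments_of("mt")
    if mts:
        out["shortest_mt_distances"] = actin_nearest_mt(
            actin, mts, vm, config.resample_nm)
    return out


@dataclass
class PipelineReport:
    """Aggregated result of a multi-condition run."""

    per_scene: pd.DataFrame  # condition, scene, metric columns
    summaries: dict[str, list[GroupSummary]]  # metric -> per-condition
    tests: dict[str, dict]  # metric -> {"F":, "p":, "tukey": records}
    failures: list[str] = field(default_factory=list)
    config_hash: str = ""
    version: str = __version__


def run_pipeline(
    scene_dirs_by_condition: dict[str, list],
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
) -> PipelineReport:
    """Quantify scene bundles per condition, aggregate, and test.

    Scenes failing validation are named in the report and skipped unless
    ``config.strict``. Group tests run only when >= 2 conditions each have
    >= 2 scenes.
    """
    rows = []
    failures = []
    for condition in sorted(scene_dirs_by_condition):
        for path in sorted(str(p) for p in scene_dirs_by_condition[condition]):
            try:
                scene = read_scene(path)
                metrics = quantify_scene(scene, config)
            except CytoarchError as exc:
                if config.strict:
                    raise
                failures.append(f"{condition}:{path}: {exc}")
                continue
            rows.append({"condition": condition, "scene": str(path), **metrics})
    if not rows:
        raise ValidationError("no scene was quantified successfully")
    per_scene = pd.DataFrame(rows)

    metric_cols = [c for c in per_scene.columns if c not in ("condition", "scene")]
    summaries: dict[str, list[GroupSummary]] = {}
    tests: dict[str, dict] = {}
    conditions = sorted(per_scene.condition.unique())
    for metric in metric_cols:
        summaries[metric] = [
            GroupSummary.from_values(
                c, per_scene.loc[per_scene.condition == c, metric].dropna())
            for c in conditions
            if per_scene.loc[per_scene.condition == c, metric].notna().any()
        ]
        groups = [s.values for s in summaries[metric] if s.n >= 2]
        labels = [s.condition for s in summaries[metric] if s.n >= 2]
        if len(groups) >= 2:
            try:
                res = anova_tukey(groups, labels)
                tests[metric] = {
                    "F": res.F, "p": res.p,
                    "tukey": res.tukey.to_dict(orient="records"),
                }
            except CytoarchError as exc:
                tests[metric] = {"error": str(exc)}

    report = PipelineReport(
        per_scene=per_scene, summaries=summaries, tests=tests,
        failures=failures, config_hash=config.hash(),
    )
    if out_dir is not None:
        write_report(report, config, out_dir)
    return report


def write_report(report: PipelineReport, config: PipelineConfig, out_dir) -> None:
    """Write the per-scene table (CSV) and summary/tests (JSON) to a directory."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    report.per_scene.to_csv(d / "per_scene_metrics.csv", index=False)
    payload = {
        "version": report.version,
        "config": asdict(config),
        "config_hash": report.config_hash,
        "failures": report.failures,
        "summaries": {
            metric: [
                {"condition": s.condition, "mean": s.mean,
                 "sem": None if np.isnan(s.sem) else s.sem, "n": s.n}
                for s in summaries
            ]
            for metric, summaries in report.summaries.items()
        },
        "tests": report.tests,
    }
    (d / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
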