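"""Reproducible pipeline: simulate -> adc -> measure -> match -> evaluate.

Each stage reads its predecessors' outputs from disk, so every number in a
rendered report can be recomputed from the files alone.  A run manifest
records the tool version, a hash of the configuration, timestamps and a
SHA-256 checksum of every artifact; identical config + seed reproduce
identical checksums for every deterministic stage (and all stages are
deterministic because randomness flows from the seeded generators).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adc import DWISeries, SUBSETS, compute_adc_map
from .colocalization import (
    match_cohorts,
    profiles_from_frame,
    profiles_to_frame,
    write_match_report,
)
from .diagnostics import DiagnosticSummary, evaluate_indicator
from .phantom import (
    BENIGN_GROUP,
    BENIGN_NODULE,
    INDICATORS,
    Nodule,
    PTC_GROUP,
    PTC_NODULE,
    PhantomConfig,
    generate_cohort,
    generate_location_pairs,
    generate_phantom,
)
from .roi import apply_exclusions, measure_nodules

log = logging.getLogger("thyrodwi")

__all__ = ["PipelineConfig", "run_pipeline", "report_tables", "load_config"]


@dataclass
class PipelineConfig:
    """Settings for one end-to-end run."""

    outdir: Path = Path("thyrodwi_out")
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "adc", "measure", "match", "evaluate", "report")
    subsets: tuple[str, ...] = ("b0-800", "b0-2000", "b0-800-2000")
    grid_shape: tuple[int, int, int] = (48, 48, 8)
    noise_sigma: float = 0.0
    n_location_pairs: int = 30
    jitter_fraction: float = 0.05
    shrinkage_fraction: float = 0.12
    us_threshold: float = 10.0
    specimen_threshold: float = 20.0
    cohort_groups: str = "table"  # draw the published group summaries
    report_format: str = "csv"  # or "json"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key {key!r}")
        default = getattr(cfg, key)
        if isinstance(default, tuple):
            value = tuple(value)
        elif isinstance(default, Path):
            value = Path(value)
        setattr(cfg, key, value)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()


def summaries_to_frame(summaries: list[DiagnosticSummary]) -> pd.DataFrame:
    """Render diagnostic summaries as an accuracy table.

    Column layout mirrors the usual reporting: cutoff with direction, AUC
    to 3 decimals with its CI, then percentage metrics to 2 decimals and
    Youden's index to 2 decimals.
    """
    rows = []
    for s in summaries:
        op = "<=" if s.direction == "positive-if-low" else ">"
        rows.append({
            "comparison_group": s.comparison_group,
            "indicator": s.indicator,
            "cutoff": f"{op} {s.cutoff:g}",
            "AUC": round(s.auc, 3),
            "AUC_95CI": f"{s.auc_ci[0]:.3f}-{s.auc_ci[1]:.3f}",
            "sensitivity_pct": round(s.sensitivity, 2),
            "sensitivity_95CI": f"{s.sensitivity_ci[0]:.1f}-{s.sensitivity_ci[1]:.1f}",
            "specificity_pct": round(s.specificity, 2),
            "specificity_95CI": f"{s.specificity_ci[0]:.1f}-{s.specificity_ci[1]:.1f}",
            "PPV_pct": round(s.ppv, 2),
            "NPV_pct": round(s.npv, 2),
            "FPR_pct": round(s.fpr, 2),
            "FNR_pct": round(s.fnr, 2),
            "youden_index": round(s.youden, 2),
            "TP": s.table.tp, "FP": s.table.fp, "FN": s.table.fn, "TN": s.table.tn,
        })
    columns = ["comparison_group", "indicator", "cutoff", "AUC", "AUC_95CI",
               "sensitivity_pct", "sensitivity_95CI", "specificity_pct",
               "specificity_95CI", "PPV_pct", "NPV_pct", "FPR_pct", "FNR_pct",
               "youden_index", "TP", "FP", "FN", "TN"]
    return pd.DataFrame(rows, columns=columns)


def report_tables(summaries: list[DiagnosticSummary], outdir: str | Path,
                  fmt: str = "csv") -> list[Path]:
    """Write accuracy tables as CSV and/or JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = summaries_to_frame(summaries)
    paths = []
    if fmt in ("csv", "both"):
        p = outdir / "diagnostic_report.csv"
        frame.to_csv(p, index=False)
        paths.append(p)
    if fmt in ("json", "both"):
        p = outdir / "diagnostic_report.json"
        p.write_text(frame.to_json(orient="records", indent=2))
        paths.append(p)
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    Stage outputs land under ``config.outdir``; counts after every filter
    step are logged at INFO so the cohort accounting stays auditable.
    Returns the manifest dictionary (also written as JSON).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    t0 = time.time()

    def register(path: Path) -> None:
        artifacts[str(path.relative_to(outdir))] = _sha256(path)

    if "simulate" in config.stages:
        nx, ny, nz = config.grid_shape
        phantom_cfg = PhantomConfig(
            grid_shape=config.grid_shape,
            noise_sigma=config.noise_sigma,
            seed=config.seed,
            nodules=(
                Nodule((nx // 4, ny // 4, nz // 2), 4.0, BENIGN_NODULE),
                Nodule((3 * nx // 4, 3 * ny // 4, nz // 2), 4.0, PTC_NODULE),
            ),
        )
        series, labels, tissues = generate_phantom(phantom_cfg)
        nii, bval = series.to_nifti(outdir / "dwi")
        register(nii)
        register(bval)
        np.save(outdir / "labels.npy", labels)  # intermediate, not reported
        (outdir / "tissues.json").write_text(json.dumps(
            {str(k): dataclasses.asdict(t) for k, t in tissues.items()}, indent=2))
        cohort = generate_cohort(seed=config.seed)
        cohort_path = outdir / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        register(cohort_path)
        mr, other, pair_table = generate_location_pairs(
            config.n_location_pairs, config.jitter_fraction,
            config.shrinkage_fraction, seed=config.seed,
        )
        mr_path = outdir / "locations_mr.csv"
        other_path = outdir / "locations_other.csv"
        profiles_to_frame(mr).to_csv(mr_path, index=False)
        profiles_to_frame(other).to_csv(other_path, index=False)
        register(mr_path)
        register(other_path)
        log.info("simulate: %d-voxel grid, %d nodules, cohort of %d, %d location pairs",
                 int(np.prod(config.grid_shape)), len(phantom_cfg.nodules),
                 len(cohort), config.n_location_pairs)
        # kept in memory for later stages as well
        _state = {"series": series, "labels": labels, "tissues": tissues}
    else:
        _state = {}

    if "adc" in config.stages:
        series = _state.get("series") or DWISeries.from_nifti(outdir / "dwi.nii")
        for name in config.subsets:
            amap = compute_adc_map(series, SUBSETS[name])
            map_path, mask_path = amap.to_nifti(outdir / "map")
            register(map_path)
            register(mask_path)
            log.info("adc: subset %s, %d invalid voxels", name, int((~amap.valid).sum()))

    if "measure" in config.stages:
        series = _state.get("series") or DWISeries.from_nifti(outdir / "dwi.nii")
        labels = _state.get("labels")
        if labels is None:
            labels = np.load(outdir / "labels.npy")
        tissues = _state.get("tissues")
        if tissues is None:
            from .phantom import TissueSpec

            raw = json.loads((outdir / "tissues.json").read_text())
            tissues = {int(k): TissueSpec(**v) for k, v in raw.items()}
        measured = measure_nodules(series, labels, tissues)
        retained, report = apply_exclusions(measured)
        meas_path = outdir / "measurements.csv"
        retained.to_csv(meas_path, index=False)
        register(meas_path)
        log.info("measure: %d nodules in, %d retained (%s)",
                 report["n_input"], report["n_retained"],
                 {k: v for k, v in report.items() if not k.startswith("n_")})

    if "match" in config.stages:
        mr = profiles_from_frame(pd.read_csv(outdir / "locations_mr.csv"))
        other = profiles_from_frame(pd.read_csv(outdir / "locations_other.csv"))
        pairs, un_mr, un_other = match_cohorts(
            mr, other, us_threshold=config.us_threshold,
            specimen_threshold=config.specimen_threshold,
        )
        match_path = write_match_report(outdir / "match_report.json", pairs, un_mr, un_other)
        register(match_path)
        log.info("match: %d/%d matched, %d MR unmatched", len(pairs), len(mr), len(un_mr))

    if "evaluate" in config.stages:
        cohort = pd.read_csv(outdir / "cohort.csv")
        summaries = [evaluate_indicator(cohort, ind, "PTC") for ind in INDICATORS]
        _state["summaries"] = summaries
        log.info("evaluate: %d indicators against %d PTC / %d benign",
                 len(summaries), summaries[0].n_positive, summaries[0].n_negative)

    if "report" in config.stages and "summaries" in _state:
        for p in report_tables(_state["summaries"], outdir, fmt=config.report_format):
            register(p)

    manifest = {
        "tool": "thyrodwi",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "started_unix": t0,
        "elapsed_s": time.time() - t0,
        "artifacts_sha256": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
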