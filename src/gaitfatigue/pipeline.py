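"""End-to-end orchestration: simulate → preprocess → segment → evaluate.

A :class:`RunConfig` fully determines a run; the emitted run manifest
records its content hash, the seed and package versions, so identical
configs reproduce identical metrics. A single preprocessed segment set is
reused across combination sweeps (channel selection happens after
normalization, so each combination is a pure slice of the full set).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from gaitfatigue import __version__
from gaitfatigue.combinations import REGISTRY, get_combination
from gaitfatigue.evaluation import EvalReport, run_cv, render_reports
from gaitfatigue.model import ModelConfig
from gaitfatigue.preprocess import PreprocessConfig, preprocess_recording
from gaitfatigue.recordings_io import (
    CohortManifest, read_manifest, read_recording, STATES, FS_IMU,
)
from gaitfatigue.segmentation import SegmentSet, assemble_dataset, WINDOW_FRAMES, HOP_FRAMES
from gaitfatigue.synthetic_gait import SimulationParams, SimulatedCohort, simulate_cohort

log = logging.getLogger("gaitfatigue")


@dataclass
class RunConfig:
    combination_id: int = 13
    protocol: str = "losocv"
    model: ModelConfig = field(default_factory=ModelConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    simulation: SimulationParams | None = field(default_factory=SimulationParams)
    data_dir: str | None = None     # read an existing cohort instead of simulating
    windows_per_recording: int = 9
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"


def validate_config(cfg: RunConfig) -> list[str]:
    """Cross-field constraint checks; returns the full list of problems."""
    errors: list[str] = []
    if cfg.combination_id not in REGISTRY:
        errors.append(f"combination id {cfg.combination_id} not in 1–14")
    if cfg.protocol not in ("losocv", "kfold9"):
        errors.append(f"unknown protocol {cfg.protocol!r}")
    pp = cfg.preprocess
    for band, fs, name in (
        (pp.accel_band, 148.0, "accel"),
        (pp.gyro_band, 148.0, "gyro"),
        (pp.emg_band, 1259.0, "emg"),
    ):
        try:
            band.validate(fs)
        except ValueError as e:
            errors.append(f"{name} band: {e}")
    if cfg.simulation is not None:
        sim = cfg.simulation
        needed_frames = WINDOW_FRAMES + (cfg.windows_per_recording - 1) * HOP_FRAMES
        if sim.duration_s * FS_IMU < needed_frames:
            errors.append(
                f"duration {sim.duration_s}s gives {int(sim.duration_s * FS_IMU)} frames; "
                f"{cfg.windows_per_recording} windows need ≥ {needed_frames}"
            )
        try:
            sim.validate()
        except ValueError as e:
            errors.append(str(e))
    if cfg.simulation is None and cfg.data_dir is None:
        errors.append("either simulation params or a data_dir is required")
    if cfg.protocol == "kfold9" and cfg.windows_per_recording != 9:
        errors.append("kfold9 requires exactly 9 windows per recording")
    return errors


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_cohort_groups(manifest: CohortManifest, base_dir: str | Path) -> list[dict]:
    """Read all complete recording groups named by a manifest."""
    groups = []
    for (_sid, _state), entries in sorted(manifest.groups().items()):
        groups.append({site: read_recording(e, base_dir) for site, e in entries.items()})
    return groups


def build_segments(cfg: RunConfig,
                   cohort: SimulatedCohort | None = None) -> SegmentSet:
    """Simulate-or-load, preprocess, and assemble the full segment set."""
    if cohort is None:
        if cfg.data_dir is not None:
            manifest = read_manifest(Path(cfg.data_dir) / "manifest.json")
            groups = load_cohort_groups(manifest, cfg.data_dir)
        else:
            sim = SimulationParams(**{**asdict(cfg.simulation), "seed": cfg.seed})
            cohort = simulate_cohort(sim)
            groups = [cohort.recordings[k] for k in sorted(cohort.recordings)]
    else:
        groups = [cohort.recordings[k] for k in sorted(cohort.recordings)]
    log.info("preprocessing %d recording groups", len(groups))
    processed = [preprocess_recording(g, cfg.preprocess) for g in groups]
    return assemble_dataset(processed, windows_per_recording=cfg.windows_per_recording)


def run_experiment(cfg: RunConfig,
                   segments: SegmentSet | None = None) -> EvalReport:
    """Execute the full pipeline for one combination/protocol.

    ``segments`` lets a caller (e.g. a combination sweep) reuse one
    preprocessed segment set across runs.
    """
    logging.basicConfig(level=cfg.log_level, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid run config: " + "; ".join(errors))

    if segments is None:
        segments = build_segments(cfg)
    spec = get_combination(cfg.combination_id)
    log.info("evaluating combination %d (%d features) under %s",
             spec.id, spec.n_features, cfg.protocol)
    report = run_cv(segments, spec, cfg.protocol, cfg.model, seed=cfg.seed)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        files = render_reports(report, out)
        manifest = {
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "package_version": __version__,
            "numpy_version": np.__version__,
            "combination_id": cfg.combination_id,
            "protocol": cfg.protocol,
            "pooled_accuracy": report.pooled_accuracy,
            "artifacts": [f.name for f in files],
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return report


def sweep_combinations(cfg: RunConfig, combination_ids=None) -> pd.DataFrame:
    """Evaluate several combinations on one shared preprocessed segment set.

    Returns a table of pooled and macro accuracies per combination
    (the multi-combination analogue of a results summary).
    """
    errors = [e for e in validate_config(cfg) if "combination id" not in e]
    if errors:
        raise ValueError("invalid run config: " + "; ".join(errors))
    ids = list(combination_ids or sorted(REGISTRY))
    segments = build_segments(cfg)  # cached across the sweep
    rows = []
    for cid in ids:
        spec = get_combination(cid)
        report = run_cv(segments, spec, cfg.protocol, cfg.model, seed=cfg.seed)
        rows.append({
            "combination": cid,
            "category": spec.category,
            "features": spec.n_features,
            "pooled_accuracy": report.pooled_accuracy,
            "macro_accuracy": report.macro_accuracy,
        })
        log.info("combination %d: pooled accuracy %.4f", cid, report.pooled_accuracy)
    df = pd.DataFrame(rows)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"sweep_{cfg.protocol}.csv", index=False)
    return df
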