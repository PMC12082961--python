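"""End-to-end orchestration: simulate -> segment -> breaths -> ensemble ->
spectrum -> statistics, under a single validated configuration.

The default run generates a synthetic cohort (21 participants x 3 breathing
conditions x 3 repetitions), renders and segments image frames for a small
subset of recordings as an imaging round-trip check, detects breaths from
every respiration trace, aligns paced recordings to the first inspiration
onset, ensemble-averages per condition, computes per-recording baselines and
band log-powers, and runs the statistical comparisons.  Every stage persists
its artifacts and the whole run is deterministic given the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import segmentation, spectral, stats, synthetic, timeseries
from .errors import ConfigError, PipelineError, UnsupportedConditionError
from .respiration import detect_peaks
from .segmentation import ROI, DEFAULT_THRESHOLD
from .timeseries import Alignment
from .types import Condition

logger = logging.getLogger("veinmod.pipeline")

__all__ = ["RunConfig", "run_end_to_end"]


@dataclass
class RunConfig:
    """Validated configuration of one full pipeline run.

    All analysis defaults mirror the study constants: binarization threshold
    70, AR order 7, bands 0.099-0.101 Hz (PB10) and 0.332-0.334 Hz (PB3),
    50-s recordings at 1 Hz, respiration at 100 Hz.
    """

    out_dir: str = "veinmod_run"
    seed: int = 0
    n_participants: int = 21
    n_reps: int = 3
    conditions: tuple = ("SB", "PB3", "PB10")
    design: synthetic.CohortDesign = field(default_factory=synthetic.CohortDesign)

    # imaging round-trip subset: first N participants get rendered + segmented
    render_participants: int = 1
    scene: synthetic.SceneParams = field(default_factory=synthetic.SceneParams)
    roi: tuple = (0, 0, 0, 0)            # (r0, r1, c0, c1); zeros = full frame
    threshold: float = DEFAULT_THRESHOLD
    diameter_mode: str = "minor_axis"

    ar_order: int = spectral.DEFAULT_AR_ORDER
    detrend: str = "mean"

    peak_min_separation_s: float = 1.5
    peak_min_prominence: float = 0.2
    peak_smooth_window_s: float = 0.5

    save_intermediates: bool = True

    def validate(self) -> "RunConfig":
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        if not (0 <= self.threshold <= 255):
            raise ConfigError("threshold must be a gray level in [0, 255]")
        if self.ar_order < 1:
            raise ConfigError("ar_order must be >= 1")
        if self.render_participants < 0:
            raise ConfigError("render_participants must be >= 0")
        if self.diameter_mode not in ("minor_axis", "equivalent_circle"):
            raise ConfigError(f"unknown diameter_mode {self.diameter_mode!r}")
        if self.peak_min_separation_s <= 0 or not (0 < self.peak_min_prominence < 1):
            raise ConfigError("invalid peak-detector parameters")
        [Condition.coerce(c) for c in self.conditions]
        if any(v != 0 for v in self.roi):
            self.effective_roi(self.scene.image_size_px)  # raises if invalid
        return self

    def effective_roi(self, frame_shape) -> ROI:
        if all(v == 0 for v in self.roi):
            return ROI.full(frame_shape)
        roi = ROI(*[int(v) for v in self.roi])
        roi.check_within(frame_shape)
        return roi

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        design = raw.pop("design", None)
        scene = raw.pop("scene", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if design:
            cfg.design = synthetic.CohortDesign(**design)
        if scene:
            cfg.scene = synthetic.SceneParams(**scene)
        return cfg.validate()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []

    def _stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)

        def done(**info):
            stage_log.append({"stage": name,
                              "seconds": round(time.perf_counter() - t0, 3),
                              **info})
            logger.info("stage %s finished in %.2fs", name,
                        time.perf_counter() - t0)
        return done

    # --- simulate -----------------------------------------------------
    done = _stage("simulate")
    try:
        cohort = synthetic.make_cohort(
            n_participants=config.n_participants, conditions=config.conditions,
            n_reps=config.n_reps, design=config.design, seed=config.seed)
    except Exception as exc:
        raise PipelineError(f"simulate failed: {exc}") from exc
    if config.save_intermediates:
        (out_dir / "manifest.json").write_text(cohort.manifest_json())
    done(recordings=len(cohort.recordings))

    # --- segment (imaging round-trip on a subset) ---------------------
    done = _stage("segment")
    seg_errors = []
    rendered_ids = {f"P{p + 1:02d}" for p in range(config.render_participants)}
    for rec in cohort.recordings:
        if rec.participant_id not in rendered_ids:
            continue
        scene = synthetic.SceneParams(**{**asdict(config.scene),
                                         "seed": rec.seed_key[-1] + 1})
        try:
            seq = synthetic.render_frames(rec.series, scene)
            roi = config.effective_roi(seq.frame_shape)
            extracted = segmentation.extract_series(
                seq, roi, threshold=config.threshold,
                diameter_mode=config.diameter_mode,
                participant_id=rec.participant_id, condition=rec.condition,
                repetition=rec.repetition)
        except Exception as exc:
            raise PipelineError(
                f"segment failed on {rec.participant_id}/"
                f"{rec.condition.value}/r{rec.repetition}: {exc}") from exc
        seg_errors.append(float(np.max(np.abs(
            extracted.values_mm - rec.series.values_mm))))
    done(sequences=len(seg_errors))

    # --- breaths + align + per-recording measures ---------------------
    done = _stage("measure")
    rows = []
    aligned_by_cond: dict[str, list] = {}
    for rec in cohort.recordings:
        annotation = detect_peaks(
            rec.respiration, min_separation_s=config.peak_min_separation_s,
            min_prominence=config.peak_min_prominence,
            smooth_window_s=config.peak_smooth_window_s) \
            if rec.respiration is not None else None
        mode = (Alignment.INSPIRATION_ONSET
                if rec.condition in (Condition.PB3, Condition.PB10)
                and annotation is not None else Alignment.RECORD_START)
        aligned = timeseries.align_series(rec.series, annotation, mode)
        aligned_by_cond.setdefault(rec.condition.value, []).append(aligned)

        row = {"participant": rec.participant_id,
               "condition": rec.condition.value,
               "repetition": rec.repetition,
               "baseline_mm": timeseries.baseline_mean(rec.series).value_mm}
        if annotation is not None:
            row["respiratory_rate_bpm"] = (
                annotation.n_breaths * 60.0 / rec.series.times_s.size)
        try:
            row["log_power"] = spectral.modulation_magnitude(
                rec.series, rec.condition, order=config.ar_order,
                detrend=config.detrend).value
        except UnsupportedConditionError:
            row["log_power"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    done(rows=len(rows))

    # --- ensemble ------------------------------------------------------
    done = _stage("ensemble")
    ensembles = {cond: timeseries.ensemble_average(
        series_list,
        alignment=(Alignment.RECORD_START if cond == Condition.SB.value
                   else Alignment.INSPIRATION_ONSET))
        for cond, series_list in aligned_by_cond.items()}
    done(conditions=len(ensembles))

    # --- statistics ----------------------------------------------------
    done = _stage("analyze")
    rep = stats.report(table, ensembles=ensembles)
    if seg_errors:
        rep["segmentation_roundtrip"] = {
            "n_sequences": len(seg_errors),
            "max_abs_error_mm": max(seg_errors),
            "mean_abs_error_mm": float(np.mean(seg_errors)),
        }
    rep["config"] = {"seed": config.seed,
                     "n_participants": config.n_participants,
                     "n_reps": config.n_reps,
                     "conditions": list(config.conditions),
                     "threshold": config.threshold,
                     "ar_order": config.ar_order}
    stats.write_report(rep, table, out_dir, ensembles=ensembles)
    done()

    # --- structured run log (timings + artifact hashes) ----------------
    hashes = {p.name: _sha256(p) for p in sorted(out_dir.glob("*.json"))
              if p.name != "run_log.json"}
    hashes.update({p.name: _sha256(p) for p in sorted(out_dir.glob("*.csv"))})
    (out_dir / "run_log.json").write_text(json.dumps(
        {"stages": stage_log, "artifact_sha256": hashes}, indent=2))
    return rep
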