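"""Readers/writers, run configuration and the end-to-end pipeline.

Gaze recordings travel as plain delimited text with a documented header
(``subject_id, trial_id, stimulus_id, t_ms, x_px, y_px, valid``) — one row
per sample — which keeps the format vendor-neutral.  The pipeline runs
preprocess -> detect -> features -> {stats, similarity, reliability,
classification} and writes a bundle of CSV/JSON outputs, each stamped with
a hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .event_detection import detect_events, events_to_frame
from .features import FEATURE_NAMES, cohort_features
from .geometry import ScreenGeometry
from .group_stats import compare_feature_table
from .ml_pipeline import evaluate_feature_sets
from .preprocessing import GazeTrial, preprocess_trial
from .reliability import AoiRect, aoi_proportions, icc_trial_subsets
from .scanpath_similarity import (inter_individual_similarity,
                                  intra_individual_similarity,
                                  scanpath_from_events)
from .synthetic import GROUP_CASE, GROUP_CONTROL, Cohort

log = logging.getLogger("oculoscreen")

GAZE_COLUMNS = ["subject_id", "trial_id", "stimulus_id", "t_ms", "x_px", "y_px", "valid"]

__all__ = ["GAZE_COLUMNS", "RunConfig", "read_gaze_table", "write_gaze_table",
           "load_config", "config_hash", "run_pipeline"]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    geometry: dict = field(default_factory=dict)        # ScreenGeometry kwargs
    preprocessing: dict = field(default_factory=dict)   # preprocess_trial kwargs
    detection: dict = field(default_factory=dict)       # detect_events kwargs
    features: dict = field(default_factory=dict)        # trial_features kwargs
    similarity: dict = field(default_factory=dict)      # modulation/method
    stats: dict = field(default_factory=dict)           # compare_feature_table kwargs
    reliability: dict = field(default_factory=dict)     # aoi + icc settings
    ml: dict = field(default_factory=dict)              # evaluate_feature_sets kwargs
    seed: int = 0
    output_dir: str = "oculoscreen_run"

    _ALLOWED = {
        "geometry": {"width_px", "height_px", "diagonal_mm", "viewing_distance_mm"},
        "preprocessing": {"max_gap_ms", "blink_min_ms", "blink_max_ms",
                          "blink_margin_samples", "max_missing_frac"},
        "detection": {"velocity_threshold_deg_s", "min_fixation_ms", "detector",
                      "dispersion_px"},
        "features": {"units", "entropy_grid", "link_radius_deg", "roi_min_members",
                     "vwi_orientation", "inflection_floor_px"},
        "similarity": {"modulation", "method"},
        "stats": {"unit", "alpha_normality", "n_boot", "holm"},
        "reliability": {"aoi_width", "aoi_height", "aoi_center_x", "aoi_center_y",
                        "subsets", "form"},
        "ml": {"n_trials", "k", "model_families", "feature_sets"},
    }

    def __post_init__(self) -> None:
        for block, allowed in self._ALLOWED.items():
            extra = set(getattr(self, block)) - allowed
            if extra:
                raise ValueError(f"unknown keys in config block {block!r}: {sorted(extra)}")

    def screen_geometry(self) -> ScreenGeometry:
        return ScreenGeometry(**self.geometry)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__ if not f.startswith("_")}
    extra = set(raw) - known
    if extra:
        raise ValueError(f"unknown top-level config keys: {sorted(extra)}")
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# gaze tables

def write_gaze_table(trials: list[GazeTrial], path: str | Path) -> None:
    frames = []
    for tr in trials:
        frames.append(pd.DataFrame({
            "subject_id": tr.subject_id, "trial_id": tr.trial_id,
            "stimulus_id": tr.stimulus_id, "t_ms": tr.t,
            "x_px": tr.x, "y_px": tr.y, "valid": tr.valid.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gaze_table(path: str | Path, sampling_hz: float = 90.0) -> list[GazeTrial]:
    """Load a gaze CSV into trials; non-monotone trials are rejected with a log entry."""
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze table {path} is missing required columns: {missing}")
    bad = df[["t_ms", "x_px", "y_px"]].apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        log.warning("dropping %d malformed rows at lines %s", bad.sum(), lines[:20])
        df = df[~bad]
    trials = []
    for (subject, trial, stim), grp in df.groupby(
            ["subject_id", "trial_id", "stimulus_id"], sort=True):
        t = grp["t_ms"].to_numpy(dtype=float)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            log.warning("rejecting trial %s/%s: timestamps not strictly increasing",
                        subject, trial)
            continue
        trials.append(GazeTrial(
            subject_id=str(subject), trial_id=str(trial), stimulus_id=str(stim),
            t=t, x=grp["x_px"].to_numpy(dtype=float), y=grp["y_px"].to_numpy(dtype=float),
            valid=grp["valid"].to_numpy().astype(bool), sampling_hz=sampling_hz,
        ))
    return trials


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig, trials: list[GazeTrial],
                 groups: dict[str, str]) -> dict:
    """Execute the full analysis on raw trials and write the report bundle.

    Returns a dict with the in-memory results; files are written under
    ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    geom = config.screen_geometry()

    # 1. preprocess + QC
    kept, qc_log = [], []
    for trial in trials:
        cleaned, qc = preprocess_trial(trial, **config.preprocessing)
        if qc.keep:
            kept.append(cleaned)
        qc_log.append({"subject_id": trial.subject_id, "trial_id": trial.trial_id,
                       "missing_frac": qc.missing_frac, "kept": qc.keep})
    qc_df = pd.DataFrame(qc_log)

    # 2. events + features
    events_by_trial = [(t.subject_id, t.trial_id, t.stimulus_id,
                        detect_events(t, geom, **config.detection)) for t in kept]
    feats = cohort_features(events_by_trial, geom, **config.features)
    feats.insert(0, "config_hash", chash)
    feats.to_csv(outdir / "features.csv", index=False)

    events_rows = []
    for subject, trial, _stim, ev in events_by_trial:
        frame = events_to_frame(ev)
        frame.insert(0, "subject_id", subject)
        frame.insert(1, "trial_id", trial)
        events_rows.append(frame)
    events_df = (pd.concat(events_rows, ignore_index=True) if events_rows
                 else pd.DataFrame(columns=["subject_id", "trial_id", "type"]))
    events_df.to_csv(outdir / "events.csv", index=False)

    # 3. group statistics
    stats_df = compare_feature_table(
        feats, groups, GROUP_CONTROL, GROUP_CASE, FEATURE_NAMES,
        seed=config.seed, **config.stats)
    stats_df.insert(0, "config_hash", chash)
    stats_df.to_csv(outdir / "group_stats.csv", index=False)

    # 4. scanpath similarity
    sim_cfg = dict(config.similarity)
    paths = {}
    for subject, trial, stim, ev in events_by_trial:
        if ev.fixations:
            paths.setdefault(subject, []).append(
                scanpath_from_events(ev, geom, subject, trial, stim))
    intra = {s: intra_individual_similarity(p, **sim_cfg) for s, p in paths.items()}
    inter = {}
    for glabel in (GROUP_CONTROL, GROUP_CASE):
        flat = [p for s, ps in paths.items() if groups.get(s) == glabel for p in ps]
        inter[glabel] = inter_individual_similarity(flat, **sim_cfg)
    sim_df = pd.DataFrame({
        "subject_id": list(intra),
        "group": [groups.get(s, "?") for s in intra],
        "intra_similarity": list(intra.values()),
    })
    sim_df.insert(0, "config_hash", chash)
    sim_df.to_csv(outdir / "similarity_intra.csv", index=False)
    pd.DataFrame(inter).rename_axis("stimulus_id").to_csv(outdir / "similarity_inter.csv")

    # 5. reliability
    rel_cfg = dict(config.reliability)
    aoi = AoiRect(center_x=rel_cfg.pop("aoi_center_x", geom.width_px / 2),
                  center_y=rel_cfg.pop("aoi_center_y", geom.height_px / 2),
                  width=rel_cfg.pop("aoi_width", 600.0),
                  height=rel_cfg.pop("aoi_height", 450.0))
    aoi_rows = [{"subject_id": s, "trial_id": t,
                 "prop_fix_count": p[0], "prop_fix_duration": p[1]}
                for s, t, _stim, ev in events_by_trial
                for p in [aoi_proportions(ev.fixations, aoi)] if ev.fixations]
    aoi_df = pd.DataFrame(aoi_rows)
    matrices = ({name: feats.pivot_table(index="subject_id", columns="trial_id",
                                         values=name, sort=True)
                 for name in FEATURE_NAMES} if len(feats) else {})
    icc_df = icc_trial_subsets(matrices, subsets=tuple(rel_cfg.pop("subsets", (3, 5, 7))),
                               form=rel_cfg.pop("form", "icc3k"))
    reliability_report = {
        "config_hash": chash,
        "aoi": asdict(aoi),
        "aoi_mean_prop_fix_count": float(aoi_df["prop_fix_count"].mean()) if len(aoi_df) else None,
        "aoi_mean_prop_fix_duration": float(aoi_df["prop_fix_duration"].mean()) if len(aoi_df) else None,
        "icc": icc_df.to_dict(orient="records"),
    }
    (outdir / "reliability.json").write_text(json.dumps(reliability_report, indent=2))

    # 6. classification (needs at least two subjects per class after QC)
    ml_cfg = dict(config.ml)
    n_trials = ml_cfg.pop("n_trials", int(qc_df.groupby("subject_id")["kept"].sum().max()))
    class_counts = (feats["subject_id"].map(groups).value_counts()
                    if len(feats) else pd.Series(dtype=int))
    if len(class_counts) == 2 and class_counts.min() >= 2:
        reports = evaluate_feature_sets(feats, groups, GROUP_CASE, n_trials,
                                        seed=config.seed, **ml_cfg)
    else:
        log.warning("classification skipped: fewer than 2 subjects per class after QC")
        reports = []
    classification = {"config_hash": chash,
                      "reports": [r.to_dict() for r in reports]}
    (outdir / "classification.json").write_text(json.dumps(classification, indent=2))

    # run log
    run_log = {
        "config_hash": chash, "seed": config.seed,
        "package_version": __version__,
        "n_trials_in": len(trials), "n_trials_kept": len(kept),
        "n_trials_dropped": int((~qc_df["kept"]).sum()),
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    qc_df.to_csv(outdir / "qc_log.csv", index=False)

    return {"qc": qc_df, "features": feats, "stats": stats_df,
            "similarity_intra": sim_df, "similarity_inter": inter,
            "reliability": reliability_report, "classification": reports,
            "run_log": run_log}


def run_pipeline_on_cohort(config: RunConfig, cohort: Cohort) -> dict:
    return run_pipeline(config, cohort.trials, cohort.groups)
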