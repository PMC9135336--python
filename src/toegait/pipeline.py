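"""End-to-end orchestration: raw trials -> stance cycles -> pattern
library -> synthetic cohort -> feature table -> fitted predictor.

`segment_trial` is the glue between the raw-recording world and the
101-point stance-cycle world: filter forces, detect and screen stance
phases, derive kinematic channels, and time-normalize.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from . import kinematics as kin
from . import preprocessing as prep
from .datatypes import StanceCycle, SubjectRecord, TrialRecording
from .patterns import BINS, learn_pattern_library, loocv_evaluate
from .predictor import KamReductionModel, split_by_subject
from .synthesis import synthesize_cohort

logger = logging.getLogger("toegait")


@dataclass
class PipelineConfig:
    """All tunables of the full pipeline, serialized next to every output."""

    seed: int = 0
    filter_cutoff_hz: float = 15.0
    filter_order: int = 4
    stance_threshold_n: float = 20.0
    fpa_window: Sequence[float] = (0.15, 0.40)
    kjc_half_width_mm: float = 50.0
    spline_order: int = 12
    n_interior_knots: int = 0
    include_shear_term: bool = True
    angles: Sequence[int] = tuple(BINS)
    split_fractions: Sequence[float] = (0.8, 0.1, 0.1)
    log_level: str = "INFO"
    # simulation settings used by run-all when cohorts are simulated
    sim_pattern_subjects: int = 12
    sim_target_subjects: int = 138
    sim_steps_per_condition: int = 10

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def segment_trial(
    record: TrialRecording,
    config: Optional[PipelineConfig] = None,
) -> List[StanceCycle]:
    """Segment one trial into clean, time-normalized stance cycles.

    The record is mirrored to the canonical left-leg frame first.  Force
    and COP channels are low-pass filtered; stance phases come from the
    20 N vertical-GRF rule; steps touching the other plate or containing
    unfillable marker gaps are dropped.  ``rel_toe_in_deg`` is left at
    NaN here — it needs the subject's baseline mean FPA, assigned by
    :func:`build_subject_record`.
    """
    cfg = config or PipelineConfig()
    record = kin.mirror_to_canonical(record)

    grf_f = np.column_stack(
        [
            prep.lowpass_filter(record.grf_series[:, j], record.force_rate,
                                cfg.filter_cutoff_hz, cfg.filter_order)
            for j in range(3)
        ]
    )
    cop_f = np.column_stack(
        [
            prep.lowpass_filter(record.cop_series[:, j], record.force_rate,
                                cfg.filter_cutoff_hz, cfg.filter_order)
            for j in range(3)
        ]
    )
    events = prep.detect_stance_phases(
        grf_f[:, 2], record.force_rate, cfg.stance_threshold_n
    )

    # fill short marker gaps per scalar channel; long gaps stay NaN and
    # cause the enclosing step to be dropped below
    from .datatypes import interpolate_gaps

    markers = {}
    for lab, arr in record.marker_series.items():
        filled = np.asarray(arr, float).copy()
        for j in range(3):
            filled[:, j] = interpolate_gaps(filled[:, j])
        markers[lab] = filled

    pelvis = kin.pelvis_center(
        markers["LASI"], markers["RASI"], markers["LPSI"], markers["RPSI"]
    )
    kjc = kin.knee_joint_center(
        markers["LEPI"], markers["MEPI"], half_width_mm=cfg.kjc_half_width_mm
    )
    kjc_ml, kjc_ap = kin.to_pelvis_relative(kjc, pelvis)

    cycles: List[StanceCycle] = []
    ratio = record.marker_rate / record.force_rate
    for step_idx, ev in enumerate(events):
        if not prep.is_clean_step(ev, record.plate_vertical_other, cfg.stance_threshold_n):
            continue
        m0 = ev.heel_strike_idx * ratio
        m1 = ev.toe_off_idx * ratio
        if m1 >= record.n_marker_frames:
            continue

        def mwin(values: np.ndarray) -> np.ndarray:
            return prep.resample_window(values, m0, m1)

        marker_windows = {}
        nan_found = False
        for lab in ("CALC", "MET2"):
            w = np.stack([mwin(markers[lab][:, j]) for j in range(3)], axis=1)
            if np.isnan(w).any():
                nan_found = True
            marker_windows[lab] = w
        kjc_ml_n = mwin(kjc_ml)
        kjc_ap_n = mwin(kjc_ap)
        kjc_z_n = mwin(kjc[:, 2])
        if nan_found or np.isnan(kjc_ml_n).any() or np.isnan(kjc_ap_n).any():
            continue

        # pelvis-relative COP at force rate
        pel_ml_f = np.interp(
            np.arange(len(record.cop_series)) * ratio,
            np.arange(len(pelvis)),
            pelvis[:, 0],
        )
        pel_ap_f = np.interp(
            np.arange(len(record.cop_series)) * ratio,
            np.arange(len(pelvis)),
            pelvis[:, 1],
        )
        channels = {
            "KJC_ML": kjc_ml_n,
            "KJC_AP": kjc_ap_n,
            "FCP_ML": prep.time_normalize_stance(cop_f[:, 0] - pel_ml_f, ev),
            "FCP_AP": prep.time_normalize_stance(cop_f[:, 1] - pel_ap_f, ev),
            "KJC_LAB_ML": mwin(kjc[:, 0]),
            "KJC_LAB_Z": kjc_z_n,
            "COP_LAB_ML": prep.time_normalize_stance(cop_f[:, 0], ev),
            "COP_LAB_Z": prep.time_normalize_stance(cop_f[:, 2], ev),
            "GRF_ML": prep.time_normalize_stance(grf_f[:, 0], ev),
            "GRF_AP": prep.time_normalize_stance(grf_f[:, 1], ev),
            "GRF_V": np.maximum(prep.time_normalize_stance(grf_f[:, 2], ev), 0.0),
        }
        fpa = kin.step_fpa_from_markers(
            marker_windows["CALC"], marker_windows["MET2"], tuple(cfg.fpa_window)
        )
        cycles.append(
            StanceCycle(
                subject_id=record.subject_id,
                condition=record.condition,
                step_index=step_idx,
                channels=channels,
                fpa_deg=float(fpa),
                rel_toe_in_deg=float("nan"),
                duration_s=ev.duration_s,
            )
        )
    return cycles


def build_subject_record(
    baseline: TrialRecording,
    toe_in: Optional[TrialRecording] = None,
    static_valgus_deg: float = 0.0,
    config: Optional[PipelineConfig] = None,
) -> SubjectRecord:
    """Segment a subject's trials and assign relative toe-in angles from
    the baseline mean FPA."""
    base_cycles = segment_trial(baseline, config)
    if not base_cycles:
        raise ValueError(f"no clean baseline steps for subject {baseline.subject_id}")
    base_fpa = float(np.mean([c.fpa_deg for c in base_cycles]))
    for c in base_cycles:
        c.rel_toe_in_deg = kin.relative_toe_in_angle(c.fpa_deg, base_fpa)
    toe_cycles: List[StanceCycle] = []
    if toe_in is not None:
        toe_cycles = segment_trial(toe_in, config)
        for c in toe_cycles:
            c.rel_toe_in_deg = kin.relative_toe_in_angle(c.fpa_deg, base_fpa)
    return SubjectRecord(
        subject_id=baseline.subject_id,
        height=baseline.height,
        weight=baseline.weight,
        walking_speed=baseline.walking_speed,
        static_valgus_deg=static_valgus_deg,
        baseline_fpa_deg=base_fpa,
        baseline_cycles=base_cycles,
        toe_in_cycles=toe_cycles,
    )


def load_cohort_dir(cohort_dir, config: Optional[PipelineConfig] = None) -> List[SubjectRecord]:
    """Load every subject from a directory of ``<id>_<condition>`` trials
    written in the gait_io schema."""
    cohort_dir = Path(cohort_dir)
    metas = sorted(cohort_dir.glob("*_baseline.meta.json"))
    subjects = []
    for meta_path in metas:
        stem = meta_path.name[: -len("_baseline.meta.json")]
        base = gio.read_trial(
            cohort_dir / f"{stem}_baseline.markers.csv", meta_path
        )
        sidecar = gio.read_sidecar(meta_path)
        toe_meta = cohort_dir / f"{stem}_toe_in.meta.json"
        toe = None
        if toe_meta.exists():
            toe = gio.read_trial(cohort_dir / f"{stem}_toe_in.markers.csv", toe_meta)
        subjects.append(
            build_subject_record(
                base, toe,
                static_valgus_deg=float(sidecar.get("static_valgus_deg", 0.0)),
                config=config,
            )
        )
    return subjects


def run_full_pipeline(
    config: PipelineConfig,
    out_dir,
    pattern_cohort: Optional[List[SubjectRecord]] = None,
    target_cohort: Optional[List[SubjectRecord]] = None,
    run_loocv: bool = False,
) -> dict:
    """Run learn -> synthesize -> features -> split -> train -> evaluate.

    If cohorts are not supplied they are simulated (segmented-cycle fast
    path) at the configured sizes.  Writes patterns.json, entries.csv,
    features.json, model.json, eval.json and config.yaml into ``out_dir``
    and returns the bundle as a dict.
    """
    from .simulate import SimulationConfig, simulate_cohort

    t_start = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))

    def stage(name):
        logger.info("stage %-12s t=%.1fs", name, time.time() - t_start)

    if pattern_cohort is None:
        stage("simulate")
        pattern_cohort, _ = simulate_cohort(
            SimulationConfig(
                seed=config.seed,
                n_subjects=config.sim_pattern_subjects,
                steps_per_condition=config.sim_steps_per_condition,
            )
        )
    if target_cohort is None:
        target_cohort, _ = simulate_cohort(
            SimulationConfig(
                seed=config.seed + 1,
                n_subjects=config.sim_target_subjects,
                steps_per_condition=config.sim_steps_per_condition,
            ),
            with_toe_in=False,
        )

    stage("learn")
    library = learn_pattern_library(
        pattern_cohort, order=config.spline_order,
        n_interior_knots=config.n_interior_knots, bins=config.angles,
    )
    library.provenance["pipeline_config_hash"] = config.config_hash()
    gio.persist_artifact(library, out_dir / "patterns.json")

    loocv_report = None
    if run_loocv:
        stage("loocv")
        loocv_report = loocv_evaluate(
            pattern_cohort, order=config.spline_order,
            include_shear_term=config.include_shear_term,
        )
        with open(out_dir / "loocv.json", "w") as fh:
            json.dump(loocv_report, fh, indent=1, sort_keys=True)

    stage("synthesize")
    entries = synthesize_cohort(
        target_cohort, library, bins=config.angles,
        include_shear_term=config.include_shear_term,
    )
    entries_df = pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in entries],
            "toe_in_deg": [e.toe_in_deg for e in entries],
            "baseline_first_peak": [e.baseline_kam.first_peak for e in entries],
            "synthetic_first_peak": [e.synthetic_kam.first_peak for e in entries],
            "reduction": [e.first_peak_reduction for e in entries],
            "second_peak_change": [
                e.baseline_kam.second_peak - e.synthetic_kam.second_peak for e in entries
            ],
            "impulse_change": [
                e.baseline_kam.impulse - e.synthetic_kam.impulse for e in entries
            ],
        }
    )
    entries_df.to_csv(out_dir / "entries.csv", index=False, float_format="%.10g")

    stage("features")
    from .predictor import build_feature_table

    features = build_feature_table(entries, target_cohort)
    features = split_by_subject(
        features, fractions=tuple(config.split_fractions), seed=config.seed
    )
    gio.persist_artifact(features, out_dir / "features.json")

    stage("train")
    results = KamReductionModel(features).fit(split="train")
    gio.persist_artifact(results, out_dir / "model.json")

    stage("evaluate")
    report = {
        "config_hash": config.config_hash(),
        "n_entries": len(entries),
        "train": results.evaluate(features[features["split"] == "train"]),
        "val": results.evaluate(features[features["split"] == "val"]),
        "test": results.evaluate(features[features["split"] == "test"]),
    }
    if loocv_report is not None:
        report["loocv"] = loocv_report
    with open(out_dir / "eval.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    config.to_yaml(out_dir / "config.yaml")

    stage("done")
    return {
        "library": library,
        "entries": entries_df,
        "features": features,
        "results": results,
        "report": report,
    }
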