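"""Synthetic treadmill-gait cohorts with known ground truth.

The generator emulates the features of instrumented-treadmill walking
that the pipeline consumes, with every quantity of interest known
exactly:

* a double-hump vertical GRF (two Gaussian bumps plus a smooth trough,
  solved so the peaks and trough hit configured fractions of body
  weight, tapered to zero at heel strike and toe-off);
* heel-to-toe COP progression on a belt moving at the walking speed;
* pelvis-relative knee-joint-center and foot-COP trajectories of
  physiologic magnitude, with the mediolateral lever arm between COP and
  KJC producing a realistic two-peaked KAM (~3 %BW*HT first peak);
* a parametric toe-in response: channel offsets theta * g_c(t) added to
  the baseline trajectories, theta drawn per step around the subject's
  target angle (KJC shifts medially, FCP laterally in early stance);
* clinical features drawn from configurable distributions.

Two product levels: :func:`simulate_cohort` returns segmented
:class:`SubjectRecord` cycles directly (fast path used by learning and
synthesis oracles), while :func:`simulate_trial_recording` produces raw
marker/force time series for the I/O, event-detection and full-pipeline
paths.  A fixed seed makes the whole cohort reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    N_STANCE_SAMPLES,
    StanceCycle,
    SubjectRecord,
    TrialRecording,
)
from .kam import GRAVITY
from .predictor import FEATURE_COLUMNS, RESPONSE_COLUMN

_SGRID = np.linspace(0.0, 1.0, N_STANCE_SAMPLES)

#: Analytic SD of the toe-in-angle feature when every subject contributes
#: the integer angles 1..10 (discrete uniform).
TOE_IN_SD = float(np.std(np.arange(1, 11)))


def _default_offset_slopes() -> Dict[str, np.ndarray]:
    """Ground-truth per-degree offset shapes g_c(t) in mm/deg.

    Early-stance envelope for the mediolateral channels (the toe-in
    mechanism acts in the first half of stance: KJC medial = +X, FCP
    lateral = -X for the canonical left leg); a broader mid-stance
    envelope for the smaller anterior-posterior responses.
    """
    early = np.exp(-0.5 * ((_SGRID - 0.25) / 0.15) ** 2)
    mid = np.exp(-0.5 * ((_SGRID - 0.55) / 0.25) ** 2)
    return {
        "KJC_ML": 1.2 * early,
        "FCP_ML": -2.0 * early,
        "KJC_AP": 0.6 * mid,
        "FCP_AP": -1.5 * mid,
    }


@dataclass
class SimulationConfig:
    """Everything that defines a simulated cohort; the seed fixes it all."""

    seed: int = 0
    n_subjects: int = 12
    steps_per_condition: int = 10
    marker_rate_hz: float = 100.0
    force_rate_hz: float = 1000.0
    # vertical GRF shape, fractions of body weight
    grf_peak1_frac: float = 1.10
    grf_peak2_frac: float = 1.05
    grf_trough_frac: float = 0.75
    # per-step variability
    step_noise_mm: float = 1.5
    fpa_jitter_deg: float = 1.0
    stance_duration_s: float = 0.65
    stance_duration_jitter_s: float = 0.02
    # baseline geometry (mm unless noted)
    lever_ml_mm: float = 25.0
    lever_ml_amp_mm: float = 14.0
    lever_valgus_slope_mm_per_deg: float = 1.5
    grf_ml_frac: float = 0.03
    grf_ap_frac: float = 0.15
    # toe-in response
    offset_slopes: Dict[str, np.ndarray] = field(default_factory=_default_offset_slopes)
    toein_targets: Optional[Sequence[int]] = None  # default: cycle 1..10
    # clinical feature distributions (means/SDs)
    height_mean_m: float = 1.716
    height_sd_m: float = 0.089
    weight_mean_kg: float = 70.2
    weight_sd_kg: float = 12.4
    speed_mean_mps: float = 1.25
    speed_sd_mps: float = 0.12
    valgus_mean_deg: float = 0.0
    valgus_sd_deg: float = 3.0
    fpa_mean_deg: float = 3.97
    fpa_sd_deg: float = 4.91
    # direct feature-response generator (regression oracle), standardized scale
    beta_true: Dict[str, float] = field(
        default_factory=lambda: {
            "height_m": -0.0041,
            "weight_kg": -0.014,
            "speed_mps": 0.0034,
            "valgus_deg": -0.015,
            "baseline_fpa_deg": -0.0049,
            "toe_in_deg": 0.30,
        }
    )
    response_intercept: float = 0.44
    sigma_y: float = 0.05
    # raw-trial extras
    crossover_rate: float = 0.05  # fraction of steps contaminating the other plate

    def __post_init__(self):
        if self.step_noise_mm < 0 or self.fpa_jitter_deg < 0 or self.sigma_y < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass
class SubjectTruth:
    """Per-subject ground truth retained by the generator."""

    subject_id: str
    target_toe_in_deg: int
    baseline_channels: Dict[str, np.ndarray]  # noise-free 101-point curves
    step_thetas: List[float] = field(default_factory=list)


@dataclass
class SimTruth:
    """Cohort-level ground truth: offset slopes and per-subject curves."""

    config: SimulationConfig
    offset_slopes: Dict[str, np.ndarray]
    subjects: Dict[str, SubjectTruth]

    def true_offsets(self, theta_deg: float) -> Dict[str, np.ndarray]:
        return {c: theta_deg * g for c, g in self.offset_slopes.items()}

    def true_toe_in_channels(self, subject_id: str, theta_deg: float) -> Dict[str, np.ndarray]:
        """Noise-free toe-in cycle channels for one subject at theta."""
        base = self.subjects[subject_id].baseline_channels
        offs = self.true_offsets(theta_deg)
        out = {k: v.copy() for k, v in base.items()}
        for c, d in offs.items():
            out[c] = out[c] + d
        out["KJC_LAB_ML"] = out["KJC_LAB_ML"] + offs["KJC_ML"]
        out["COP_LAB_ML"] = out["COP_LAB_ML"] + offs["FCP_ML"]
        return out


# ---------------------------------------------------------------------------
# waveforms


def grf_vertical_shape(
    s: np.ndarray,
    peak1_frac: float = 1.10,
    peak2_frac: float = 1.05,
    trough_frac: float = 0.75,
) -> np.ndarray:
    """Vertical GRF over stance (fraction of BW) at stance fractions s.

    Two Gaussian bumps (25% / 75% stance) plus a broad mid-stance trough
    term, scaled so the curve passes through the configured peak and
    trough fractions, multiplied by a sqrt-sine taper that forces zero
    force at heel strike and toe-off.
    """
    s = np.asarray(s, float)

    def taper(x):
        return np.sqrt(np.clip(np.sin(np.pi * x), 0.0, None))

    def basis(x):
        g1 = np.exp(-0.5 * ((x - 0.25) / 0.09) ** 2)
        g2 = np.exp(-0.5 * ((x - 0.75) / 0.09) ** 2)
        gt = np.exp(-0.5 * ((x - 0.50) / 0.18) ** 2)
        return np.stack([g1, g2, gt], axis=-1)

    anchors = np.array([0.25, 0.75, 0.50])
    M = basis(anchors) * taper(anchors)[:, None]
    amps = np.linalg.solve(M, np.array([peak1_frac, peak2_frac, trough_frac]))
    return np.clip((basis(s) @ amps) * taper(s), 0.0, None)


def _baseline_channels(cfg: SimulationConfig, subject: dict) -> Dict[str, np.ndarray]:
    """Noise-free 101-point baseline channels for one subject."""
    s = _SGRID
    bw = subject["weight_kg"] * GRAVITY
    h_mm = subject["height_m"] * 1000.0
    duration = subject["stance_duration_s"]
    kjc_x0 = -0.055 * h_mm  # left leg: lateral of midline
    kjc_ml = kjc_x0 + 4.0 * np.sin(np.pi * s)
    lever = (
        cfg.lever_ml_mm
        + cfg.lever_ml_amp_mm * np.sin(np.pi * s)
        - cfg.lever_valgus_slope_mm_per_deg * subject["valgus_deg"]
    )
    cop_ml = kjc_ml + lever
    kjc_ap = 170.0 - 420.0 * s
    belt = 1000.0 * subject["speed_mps"] * duration
    progression = -110.0 + 260.0 * (3 * s**2 - 2 * s**3)
    fcp_ap = belt * (0.45 - s) + progression
    grf_v = bw * grf_vertical_shape(
        s, cfg.grf_peak1_frac, cfg.grf_peak2_frac, cfg.grf_trough_frac
    )
    grf_ml = cfg.grf_ml_frac * bw * np.sin(np.pi * s)
    grf_ap = -cfg.grf_ap_frac * bw * np.sin(2 * np.pi * s)
    return {
        # pelvis fixed at the lab origin in ML/AP: relative == lab for ML/AP
        "KJC_ML": kjc_ml.copy(),
        "KJC_AP": kjc_ap.copy(),
        "FCP_ML": cop_ml.copy(),
        "FCP_AP": fcp_ap.copy(),
        "KJC_LAB_ML": kjc_ml.copy(),
        "KJC_LAB_Z": np.full_like(s, 0.285 * h_mm),
        "COP_LAB_ML": cop_ml.copy(),
        "COP_LAB_Z": np.zeros_like(s),
        "GRF_ML": grf_ml,
        "GRF_AP": grf_ap,
        "GRF_V": grf_v,
    }


def _sample_subject(cfg: SimulationConfig, rng: np.random.Generator, idx: int) -> dict:
    targets = (
        list(cfg.toein_targets)
        if cfg.toein_targets is not None
        else [(i % 10) + 1 for i in range(cfg.n_subjects)]
    )
    return {
        "subject_id": f"S{idx + 1:03d}",
        "height_m": float(np.clip(rng.normal(cfg.height_mean_m, cfg.height_sd_m), 1.45, 2.05)),
        "weight_kg": float(np.clip(rng.normal(cfg.weight_mean_kg, cfg.weight_sd_kg), 40.0, 130.0)),
        "speed_mps": float(np.clip(rng.normal(cfg.speed_mean_mps, cfg.speed_sd_mps), 0.8, 1.8)),
        "valgus_deg": float(np.clip(rng.normal(cfg.valgus_mean_deg, cfg.valgus_sd_deg), -12.0, 12.0)),
        "baseline_fpa_deg": float(np.clip(rng.normal(cfg.fpa_mean_deg, cfg.fpa_sd_deg), -12.0, 18.0)),
        "stance_duration_s": cfg.stance_duration_s,
        "target_toe_in_deg": int(targets[idx % len(targets)]),
    }


def _draw_theta(cfg: SimulationConfig, rng: np.random.Generator, target: float) -> float:
    """Per-step relative toe-in angle: Gaussian around the target,
    truncated to the learnable range [0.5, 10.5)."""
    if cfg.fpa_jitter_deg == 0:
        return float(target)
    for _ in range(100):
        theta = rng.normal(target, cfg.fpa_jitter_deg)
        if 0.5 <= theta < 10.5:
            return float(theta)
    return float(np.clip(target, 0.5, 10.4))


def _make_cycle(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    subject: dict,
    base: Dict[str, np.ndarray],
    condition: str,
    step_index: int,
    theta: float,
) -> StanceCycle:
    channels = {k: v.copy() for k, v in base.items()}
    if condition == "toe_in":
        for c, g in cfg.offset_slopes.items():
            channels[c] = channels[c] + theta * g
        channels["KJC_LAB_ML"] = channels["KJC_LAB_ML"] + theta * cfg.offset_slopes["KJC_ML"]
        channels["COP_LAB_ML"] = channels["COP_LAB_ML"] + theta * cfg.offset_slopes["FCP_ML"]
    if cfg.step_noise_mm > 0:
        for c in ("KJC_ML", "KJC_AP", "FCP_ML", "FCP_AP", "KJC_LAB_ML", "COP_LAB_ML"):
            channels[c] = channels[c] + rng.normal(0.0, cfg.step_noise_mm, N_STANCE_SAMPLES)
    duration = subject["stance_duration_s"] + (
        rng.normal(0.0, cfg.stance_duration_jitter_s)
        if cfg.stance_duration_jitter_s > 0
        else 0.0
    )
    if condition == "toe_in":
        fpa = subject["baseline_fpa_deg"] - theta
        rel = theta
    else:
        jitter = rng.normal(0.0, cfg.fpa_jitter_deg) if cfg.fpa_jitter_deg > 0 else 0.0
        fpa = subject["baseline_fpa_deg"] + jitter
        rel = -jitter
    return StanceCycle(
        subject_id=subject["subject_id"],
        condition=condition,
        step_index=step_index,
        channels=channels,
        fpa_deg=float(fpa),
        rel_toe_in_deg=float(rel),
        duration_s=float(duration),
    )


def simulate_cohort(
    cfg: SimulationConfig, with_toe_in: bool = True
) -> Tuple[List[SubjectRecord], SimTruth]:
    """Generate a cohort of segmented subjects plus its ground truth.

    Every subject gets ``steps_per_condition`` baseline cycles and (if
    requested) the same number of toe-in cycles built by adding
    theta * g_c(t) plus noise to the noise-free baseline, with theta
    drawn per step around the subject's integer target angle.
    """
    rng = np.random.default_rng(cfg.seed)
    subjects: List[SubjectRecord] = []
    truth_subjects: Dict[str, SubjectTruth] = {}
    for i in range(cfg.n_subjects):
        sub = _sample_subject(cfg, rng, i)
        base = _baseline_channels(cfg, sub)
        st = SubjectTruth(
            subject_id=sub["subject_id"],
            target_toe_in_deg=sub["target_toe_in_deg"],
            baseline_channels=base,
        )
        baseline_cycles = [
            _make_cycle(cfg, rng, sub, base, "baseline", j, 0.0)
            for j in range(cfg.steps_per_condition)
        ]
        toe_in_cycles: List[StanceCycle] = []
        if with_toe_in:
            for j in range(cfg.steps_per_condition):
                theta = _draw_theta(cfg, rng, sub["target_toe_in_deg"])
                st.step_thetas.append(theta)
                toe_in_cycles.append(
                    _make_cycle(cfg, rng, sub, base, "toe_in", j, theta)
                )
        subjects.append(
            SubjectRecord(
                subject_id=sub["subject_id"],
                height=sub["height_m"],
                weight=sub["weight_kg"],
                walking_speed=sub["speed_mps"],
                static_valgus_deg=sub["valgus_deg"],
                baseline_fpa_deg=float(
                    np.mean([c.fpa_deg for c in baseline_cycles])
                ),
                baseline_cycles=baseline_cycles,
                toe_in_cycles=toe_in_cycles,
            )
        )
        truth_subjects[sub["subject_id"]] = st
    return subjects, SimTruth(
        config=cfg, offset_slopes=dict(cfg.offset_slopes), subjects=truth_subjects
    )


# ---------------------------------------------------------------------------
# raw trial generation


def simulate_trial_recording(
    cfg: SimulationConfig,
    subject: dict,
    condition: str,
    rng: np.random.Generator,
    n_steps: Optional[int] = None,
) -> Tuple[TrialRecording, dict]:
    """Raw marker + force series for one trial, plus per-step truth.

    ``subject`` is a dict as produced by the cohort sampler (or built by
    hand with the same keys).  Returns the recording and a truth dict
    with the 20 N threshold-crossing frame indices of each generated
    stance and the per-step toe-in angles.
    """
    n_steps = n_steps or cfg.steps_per_condition
    stride_s = 1.05
    lead_s = 0.5
    total_s = lead_s + n_steps * stride_s + 0.5
    n_f = int(round(total_s * cfg.force_rate_hz))
    n_m = int(round(total_s * cfg.marker_rate_hz))
    t_f = np.arange(n_f) / cfg.force_rate_hz
    t_m = np.arange(n_m) / cfg.marker_rate_hz

    bw = subject["weight_kg"] * GRAVITY
    h_mm = subject["height_m"] * 1000.0
    kjc_x0 = -0.055 * h_mm
    foot_x = kjc_x0 - 15.0
    belt_mm_s = 1000.0 * subject["speed_mps"]

    grf = np.zeros((n_f, 3))
    cop = np.zeros((n_f, 3))
    other = np.zeros(n_f)

    slopes_s = {c: g for c, g in cfg.offset_slopes.items()}

    def slope_at(channel: str, s: np.ndarray) -> np.ndarray:
        return np.interp(s, _SGRID, slopes_s[channel])

    # per-step stance timing and angles
    steps = []
    for k in range(n_steps):
        t0 = lead_s + k * stride_s + (rng.normal(0.0, 0.01) if cfg.stance_duration_jitter_s else 0.0)
        dur = subject["stance_duration_s"] + (
            rng.normal(0.0, cfg.stance_duration_jitter_s)
            if cfg.stance_duration_jitter_s > 0
            else 0.0
        )
        if condition == "toe_in":
            theta = _draw_theta(cfg, rng, subject["target_toe_in_deg"])
            fpa = subject["baseline_fpa_deg"] - theta
        else:
            theta = 0.0
            jit = rng.normal(0.0, cfg.fpa_jitter_deg) if cfg.fpa_jitter_deg > 0 else 0.0
            fpa = subject["baseline_fpa_deg"] + jit
        contaminated = bool(rng.random() < cfg.crossover_rate)
        steps.append({"t0": t0, "dur": dur, "theta": theta, "fpa": fpa,
                      "contaminated": contaminated})

    # force channels
    for st in steps:
        mask = (t_f >= st["t0"]) & (t_f <= st["t0"] + st["dur"])
        s = (t_f[mask] - st["t0"]) / st["dur"]
        grf[mask, 2] = bw * grf_vertical_shape(
            s, cfg.grf_peak1_frac, cfg.grf_peak2_frac, cfg.grf_trough_frac
        )
        grf[mask, 0] = cfg.grf_ml_frac * bw * np.sin(np.pi * s)
        grf[mask, 1] = -cfg.grf_ap_frac * bw * np.sin(2 * np.pi * s)
        kjc_ml = kjc_x0 + 4.0 * np.sin(np.pi * s)
        lever = (
            cfg.lever_ml_mm
            + cfg.lever_ml_amp_mm * np.sin(np.pi * s)
            - cfg.lever_valgus_slope_mm_per_deg * subject["valgus_deg"]
        )
        cop_ml = kjc_ml + lever + st["theta"] * slope_at("FCP_ML", s)
        start_ap = 0.5 * belt_mm_s * st["dur"]
        progression = -110.0 + 260.0 * (3 * s**2 - 2 * s**3)
        cop[mask, 0] = cop_ml
        cop[mask, 1] = start_ap - belt_mm_s * (t_f[mask] - st["t0"]) + progression
        if st["contaminated"]:
            mid = st["t0"] + 0.5 * st["dur"]
            other += 120.0 * np.exp(-0.5 * ((t_f - mid) / 0.03) ** 2)

    # truth stance events from the generated (unfiltered) force series
    truth_events = []
    above = grf[:, 2] >= 20.0
    for st in steps:
        i0 = int(np.searchsorted(t_f, st["t0"]))
        i1 = int(np.searchsorted(t_f, st["t0"] + st["dur"]))
        idx = np.flatnonzero(above[i0 : i1 + 1])
        if len(idx):
            truth_events.append(
                {"heel_strike_idx": int(i0 + idx[0]), "toe_off_idx": int(i0 + idx[-1]),
                 "theta": st["theta"], "contaminated": st["contaminated"]}
            )

    # marker channels
    markers: Dict[str, np.ndarray] = {}
    pelvis_z = 0.53 * h_mm
    pelvis_offsets = {
        "LASI": (-120.0, 85.0, 0.0),
        "RASI": (120.0, 85.0, 0.0),
        "LPSI": (-60.0, -85.0, 0.0),
        "RPSI": (60.0, -85.0, 0.0),
    }
    for lab, (ox, oy, oz) in pelvis_offsets.items():
        arr = np.zeros((n_m, 3))
        arr[:, 0] = ox
        arr[:, 1] = oy
        arr[:, 2] = pelvis_z + oz
        markers[lab] = arr

    # knee + foot markers: build stance-time profiles then interpolate swing
    def stance_profile(values_fn):
        """Evaluate a per-stance function of s over all stances; linear
        interpolation across swing phases (and constant extrapolation at
        the trial edges)."""
        knot_t: List[float] = []
        knot_v: List[np.ndarray] = []
        for st in steps:
            ss = np.linspace(0.0, 1.0, 40)
            tt = st["t0"] + ss * st["dur"]
            vv = values_fn(st, ss, tt)
            knot_t.extend(tt.tolist())
            knot_v.extend(list(vv))
        knot_t = np.asarray(knot_t)
        knot_v = np.asarray(knot_v)
        out = np.empty((n_m, knot_v.shape[1]))
        for j in range(knot_v.shape[1]):
            out[:, j] = np.interp(t_m, knot_t, knot_v[:, j])
        return out

    def kjc_fn(st, ss, tt):
        ml = kjc_x0 + 4.0 * np.sin(np.pi * ss) + st["theta"] * slope_at("KJC_ML", ss)
        ap = 170.0 - 420.0 * ss + st["theta"] * slope_at("KJC_AP", ss)
        z = np.full_like(ss, 0.285 * h_mm)
        return np.stack([ml, ap, z], axis=1)

    def foot_fn(st, ss, tt):
        start_ap = 0.5 * belt_mm_s * st["dur"]
        ap = start_ap - belt_mm_s * (tt - st["t0"])
        ml = np.full_like(ss, foot_x)
        z = np.full_like(ss, 30.0)
        return np.stack([ml, ap, z], axis=1)

    def fpa_fn(st, ss, tt):
        return np.full((len(ss), 1), st["fpa"])

    kjc_m = stance_profile(kjc_fn)
    foot_m = stance_profile(foot_fn)
    fpa_m = stance_profile(fpa_fn)[:, 0]

    foot_len = 180.0
    phi = np.radians(fpa_m)
    d = np.stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=1)
    markers["CALC"] = foot_m.copy()
    markers["MET2"] = foot_m + foot_len * d
    markers["MET2"][:, 2] = 25.0
    markers["LEPI"] = kjc_m + np.array([-45.0, 0.0, 0.0])
    markers["MEPI"] = kjc_m + np.array([45.0, 0.0, 0.0])
    markers["LMAL"] = foot_m + np.array([-30.0, 10.0, 50.0])
    hjc = np.zeros((n_m, 3))
    hjc[:, 0] = kjc_x0 + 15.0
    hjc[:, 2] = 0.53 * h_mm
    markers["HJC"] = hjc

    if cfg.step_noise_mm > 0:
        for lab in markers:
            markers[lab] = markers[lab] + rng.normal(
                0.0, cfg.step_noise_mm, markers[lab].shape
            )

    record = TrialRecording(
        subject_id=subject["subject_id"],
        condition=condition,
        side="left",
        marker_series=markers,
        grf_series=grf,
        cop_series=cop,
        plate_vertical_other=other,
        marker_rate=cfg.marker_rate_hz,
        force_rate=cfg.force_rate_hz,
        walking_speed=subject["speed_mps"],
        height=subject["height_m"],
        weight=subject["weight_kg"],
    )
    truth = {"events": truth_events,
             "thetas": [st["theta"] for st in steps],
             "fpas": [st["fpa"] for st in steps]}
    return record, truth


def write_cohort_trials(
    cfg: SimulationConfig,
    out_dir,
    conditions: Sequence[str] = ("baseline", "toe_in"),
) -> List[dict]:
    """Generate and write raw trials for a whole cohort in the gait_io
    schema; returns the per-subject metadata (also written to
    ``truth.json``-style sidecars via each trial's meta file)."""
    from .io import write_trial

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest = []
    for i in range(cfg.n_subjects):
        sub = _sample_subject(cfg, rng, i)
        entry = {k: sub[k] for k in (
            "subject_id", "height_m", "weight_kg", "speed_mps", "valgus_deg",
            "baseline_fpa_deg", "target_toe_in_deg",
        )}
        for cond in conditions:
            rec, _ = simulate_trial_recording(cfg, sub, cond, rng)
            stem = out_dir / f"{sub['subject_id']}_{cond}"
            write_trial(
                rec,
                f"{stem}.markers.csv",
                f"{stem}.meta.json",
                extra_meta={
                    "static_valgus_deg": sub["valgus_deg"],
                    "target_toe_in_deg": sub["target_toe_in_deg"],
                },
            )
        manifest.append(entry)
    return manifest


# ---------------------------------------------------------------------------
# direct feature-response generator (regression oracle)


def simulate_feature_response(cfg: SimulationConfig) -> Tuple[pd.DataFrame, dict]:
    """Feature rows with a known linear response.

    Each subject contributes one row per toe-in angle 1..10.  The
    response is linear in the raw features with slopes
    ``beta_true[j] / SD_j`` (so the standardized-scale coefficients are
    exactly ``beta_true``) plus Gaussian noise ``sigma_y``.  Returns the
    table and a truth dict with the raw-scale slopes and intercept.
    """
    rng = np.random.default_rng(cfg.seed)
    sds = {
        "height_m": cfg.height_sd_m,
        "weight_kg": cfg.weight_sd_kg,
        "speed_mps": cfg.speed_sd_mps,
        "valgus_deg": cfg.valgus_sd_deg,
        "baseline_fpa_deg": cfg.fpa_sd_deg,
        "toe_in_deg": TOE_IN_SD,
    }
    means = {
        "height_m": cfg.height_mean_m,
        "weight_kg": cfg.weight_mean_kg,
        "speed_mps": cfg.speed_mean_mps,
        "valgus_deg": cfg.valgus_mean_deg,
        "baseline_fpa_deg": cfg.fpa_mean_deg,
        "toe_in_deg": 5.5,
    }
    beta_raw = {f: cfg.beta_true[f] / sds[f] for f in FEATURE_COLUMNS}
    intercept_raw = cfg.response_intercept - sum(
        beta_raw[f] * means[f] for f in FEATURE_COLUMNS
    )

    rows = []
    for i in range(cfg.n_subjects):
        sub = _sample_subject(cfg, rng, i)
        for angle in range(1, 11):
            x = {
                "height_m": sub["height_m"],
                "weight_kg": sub["weight_kg"],
                "speed_mps": sub["speed_mps"],
                "valgus_deg": sub["valgus_deg"],
                "baseline_fpa_deg": sub["baseline_fpa_deg"],
                "toe_in_deg": float(angle),
            }
            y = intercept_raw + sum(beta_raw[f] * x[f] for f in FEATURE_COLUMNS)
            if cfg.sigma_y > 0:
                y += rng.normal(0.0, cfg.sigma_y)
            rows.append({"subject_id": sub["subject_id"], **x, RESPONSE_COLUMN: y})
    truth = {
        "beta_raw": beta_raw,
        "beta_std": dict(cfg.beta_true),
        "intercept_raw": intercept_raw,
        "sigma_y": cfg.sigma_y,
        "feature_sds": sds,
    }
    return pd.DataFrame(rows), truth
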