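"""Marker-derived kinematic quantities in the canonical left-leg frame.

Everything downstream (pattern learning, synthesis, KAM) assumes the
canonical frame defined in :mod:`toegait.datatypes`: X mediolateral
(+ right), Y anterior-posterior (+ walking direction), Z up, instrumented
leg = left so that medial = +X.  Foot progression angle is signed with
toe-out positive; static frontal-plane alignment is signed with valgus
positive.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Tuple

import numpy as np

from .datatypes import TrialRecording

#: Within-stance window (fractions of stance) over which the per-step FPA
#: is evaluated: the foot-flat part of stance, away from heel-strike and
#: push-off transients.
FPA_WINDOW = (0.15, 0.40)


def mirror_to_canonical(record: TrialRecording) -> TrialRecording:
    """Reflect a right-side trial into the canonical left-leg frame.

    Negates every X (mediolateral) coordinate of markers, GRF and COP and
    relabels the side.  Left-side records are returned unchanged (same
    object).  Mirroring twice restores the original geometry.
    """
    if record.side == "left":
        return record
    if record.side != "right":
        raise ValueError(f"unknown side {record.side!r}")
    markers = {}
    for lab, arr in record.marker_series.items():
        m = arr.copy()
        m[:, 0] = -m[:, 0]
        markers[lab] = m
    grf = record.grf_series.copy()
    grf[:, 0] = -grf[:, 0]
    cop = record.cop_series.copy()
    cop[:, 0] = -cop[:, 0]
    return replace(
        record,
        side="left",
        marker_series=markers,
        grf_series=grf,
        cop_series=cop,
        plate_vertical_other=record.plate_vertical_other.copy(),
    )


def pelvis_center(lasi, rasi, lpsi, rpsi) -> np.ndarray:
    """Centroid of the four iliac-crest markers; works frame-wise on
    (n, 3) arrays or single 3-vectors."""
    return (
        np.asarray(lasi, float)
        + np.asarray(rasi, float)
        + np.asarray(lpsi, float)
        + np.asarray(rpsi, float)
    ) / 4.0


def to_pelvis_relative(traj: np.ndarray, pelvis: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Express a lab-frame trajectory relative to the pelvis center.

    Returns the (ML, AP) component sequences in mm; the vertical component
    is discarded (the learned patterns are planar).
    """
    traj = np.atleast_2d(np.asarray(traj, float))
    pelvis = np.atleast_2d(np.asarray(pelvis, float))
    if traj.shape[0] != pelvis.shape[0]:
        raise ValueError(
            f"trajectory length {traj.shape[0]} != pelvis length {pelvis.shape[0]}"
        )
    rel = traj - pelvis
    return rel[:, 0], rel[:, 1]


def foot_progression_angle(calc, met2) -> float:
    """Signed FPA (degrees) of the horizontal foot vector calcaneus -> 2nd
    metatarsal head, measured from the walking direction (+Y).

    Positive = toe-out for the canonical left leg (foot vector rotated
    toward -X):  fpa = degrees(atan2(-vX, vY)).
    """
    v = np.asarray(met2, float) - np.asarray(calc, float)
    vx, vy = float(v[0]), float(v[1])
    if vx == 0.0 and vy == 0.0:
        raise ValueError("zero-length horizontal foot vector")
    return float(np.degrees(np.arctan2(-vx, vy)))


def relative_toe_in_angle(step_fpa_deg: float, baseline_mean_fpa_deg: float) -> float:
    """Toe-in magnitude of one step relative to the subject's mean baseline
    FPA; positive = toeing in."""
    if not (np.isfinite(step_fpa_deg) and np.isfinite(baseline_mean_fpa_deg)):
        raise ValueError("FPA inputs must be finite")
    return float(baseline_mean_fpa_deg - step_fpa_deg)


def knee_joint_center(lepi, mepi=None, half_width_mm: float = 50.0) -> np.ndarray:
    """Knee joint center from the femoral epicondyle markers.

    Midpoint of lateral and medial epicondyles.  If the medial marker is
    missing (None or all-NaN), falls back to the lateral marker offset
    medially (+X, canonical left leg) by ``half_width_mm``; callers should
    flag the fallback in provenance.
    """
    lepi = np.asarray(lepi, float)
    if mepi is None or np.all(np.isnan(np.asarray(mepi, float))):
        out = lepi.copy()
        out[..., 0] = out[..., 0] + half_width_mm
        return out
    return (lepi + np.asarray(mepi, float)) / 2.0


def static_valgus_angle(lmal, lepi, hjc) -> float:
    """Static frontal-plane knee alignment (degrees), valgus positive.

    Signed angle between the shank vector a = lepi - lmal and the thigh
    vector b = hjc - lepi, both projected onto the frontal (X, Z) plane:
    angle = degrees(atan2(aX*bZ - aZ*bX, a.b)).  For the canonical left
    leg a knee medial to the ankle-hip line (knock-knee) gives a positive
    angle.
    """
    a = np.asarray(lepi, float) - np.asarray(lmal, float)
    b = np.asarray(hjc, float) - np.asarray(lepi, float)
    ax, az = float(a[0]), float(a[2])
    bx, bz = float(b[0]), float(b[2])
    if (ax == 0.0 and az == 0.0) or (bx == 0.0 and bz == 0.0):
        raise ValueError("zero-length projected segment vector")
    cross = ax * bz - az * bx
    dot = ax * bx + az * bz
    return float(np.degrees(np.arctan2(cross, dot)))


def step_fpa_from_markers(
    calc: np.ndarray,
    met2: np.ndarray,
    window: Tuple[float, float] = FPA_WINDOW,
) -> float:
    """Per-step FPA from marker trajectories over one stance phase.

    ``calc``/``met2`` are (n, 3) arrays spanning the stance.  The markers
    are averaged over the foot-flat window (default 15-40% of stance)
    before the angle is taken.
    """
    calc = np.asarray(calc, float)
    met2 = np.asarray(met2, float)
    n = calc.shape[0]
    i0 = int(round(window[0] * (n - 1)))
    i1 = max(i0 + 1, int(round(window[1] * (n - 1))) + 1)
    return foot_progression_angle(
        np.nanmean(calc[i0:i1], axis=0), np.nanmean(met2[i0:i1], axis=0)
    )
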