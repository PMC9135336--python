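"""Lever-arm knee adduction moment (KAM): computation, normalization and
stance-phase summary metrics.

The lever-arm method treats the external frontal-plane knee moment as the
quasi-static moment of the ground reaction force about the knee joint
center: with the moment arm r = COP - KJC (in metres) and the GRF vector
F (in newtons),

    KAM = rX * FZ - rZ * FX        [N*m]

i.e. the anterior-posterior component of r x F with the sign flipped so
that adduction is positive for the canonical left leg (positive whenever
the GRF line of action passes medial to the knee).  The ``rZ * FX`` term
carries the mediolateral shear contribution; it can be disabled to mimic
vertical-force-only implementations.

Moments are reported in %BW*HT: 100 * M / (mass * g * height).
"""

from __future__ import annotations

import numpy as np

from .datatypes import KamTrace, N_STANCE_SAMPLES, StanceCycle

GRAVITY = 9.81  # m/s^2

#: Stance percent at which the first/second-peak windows split.
PEAK_SPLIT_PERCENT = 50


def lever_arm_kam(kjc_lab_m, cop_lab_m, grf_n, include_shear_term: bool = True):
    """Frontal-plane knee moment (N*m) from lab-frame KJC, COP and GRF.

    Accepts single 3-vectors or (n, 3) arrays (positions in metres,
    forces in newtons); returns a scalar or length-n array.
    """
    kjc = np.asarray(kjc_lab_m, float)
    cop = np.asarray(cop_lab_m, float)
    grf = np.asarray(grf_n, float)
    r = cop - kjc
    moment = r[..., 0] * grf[..., 2]
    if include_shear_term:
        moment = moment - r[..., 2] * grf[..., 0]
    return moment


def normalize_moment(moment_nm, mass_kg: float, height_m: float, g: float = GRAVITY):
    """Convert a moment in N*m to %BW*HT = 100 * M / (m * g * h)."""
    if mass_kg <= 0 or height_m <= 0:
        raise ValueError("mass and height must be positive")
    return 100.0 * np.asarray(moment_nm, float) / (mass_kg * g * height_m)


def kam_summary(values, duration_s: float) -> KamTrace:
    """Summarize a 101-point normalized KAM trace.

    First peak = max over 0-50% stance, second peak = max over 50-100%,
    impulse = trapezoidal integral over the stance duration.
    """
    values = np.asarray(values, float)
    if values.shape != (N_STANCE_SAMPLES,):
        raise ValueError(
            f"expected {N_STANCE_SAMPLES} samples, got shape {values.shape}"
        )
    split = PEAK_SPLIT_PERCENT
    t = np.linspace(0.0, duration_s, N_STANCE_SAMPLES)
    return KamTrace(
        values=values,
        first_peak=float(values[: split + 1].max()),
        second_peak=float(values[split:].max()),
        impulse=float(np.trapezoid(values, t)),
        duration_s=duration_s,
    )


def kam_trace_from_cycle(
    cycle: StanceCycle,
    mass_kg: float,
    height_m: float,
    include_shear_term: bool = True,
    g: float = GRAVITY,
) -> KamTrace:
    """Normalized KAM trace of one stance cycle.

    Uses the cycle's lab-frame KJC/COP mediolateral and vertical channels
    (mm, converted to metres here) and the mediolateral + vertical GRF.
    """
    cycle.require_channels(
        ("KJC_LAB_ML", "KJC_LAB_Z", "COP_LAB_ML", "COP_LAB_Z", "GRF_ML", "GRF_V")
    )
    ch = cycle.channels
    rx = (ch["COP_LAB_ML"] - ch["KJC_LAB_ML"]) / 1000.0
    rz = (ch["COP_LAB_Z"] - ch["KJC_LAB_Z"]) / 1000.0
    moment = rx * ch["GRF_V"]
    if include_shear_term:
        moment = moment - rz * ch["GRF_ML"]
    return kam_summary(normalize_moment(moment, mass_kg, height_m, g), cycle.duration_s)
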