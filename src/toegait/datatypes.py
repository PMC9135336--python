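"""Core in-memory containers for gait trials, stance cycles and KAM traces.

Frame convention (fixed throughout the package): X is mediolateral
(positive toward the subject's right), Y is anterior-posterior (positive =
walking direction), Z is vertical up.  The canonical analysis side is the
*left* leg, for which medial = +X.  Right-side recordings must be mirrored
(:func:`toegait.kinematics.mirror_to_canonical`) before entering any
learning or synthesis path.

Canonical units: positions mm, forces N, moments N*m, height m, weight kg,
walking speed m/s.  Moments are converted to %BW*HT only inside the KAM
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .exceptions import IntegrityError

#: Marker labels required in every trial file.
REQUIRED_MARKERS = (
    "CALC", "MET2", "LASI", "RASI", "LPSI", "RPSI", "LEPI", "MEPI", "LMAL", "HJC",
)

#: Pelvis-relative trajectory channels that pattern learning operates on.
PELVIS_CHANNELS = ("KJC_ML", "KJC_AP", "FCP_ML", "FCP_AP")

#: Lab-frame channels required by the lever-arm KAM computation.
LAB_CHANNELS = ("KJC_LAB_ML", "KJC_LAB_Z", "COP_LAB_ML", "COP_LAB_Z")

#: Ground-reaction-force channels (held fixed under synthesis).
GRF_CHANNELS = ("GRF_ML", "GRF_AP", "GRF_V")

ALL_CYCLE_CHANNELS = PELVIS_CHANNELS + LAB_CHANNELS + GRF_CHANNELS

#: Number of samples per time-normalized stance (0..100% inclusive).
N_STANCE_SAMPLES = 101


@dataclass
class TrialRecording:
    """One subject/condition treadmill trial: raw marker and force series.

    Marker series are dicts label -> (n_marker_frames, 3) arrays in mm,
    lab frame.  Force/COP series run at their own (usually higher) rate.
    ``plate_vertical_other`` is the vertical force on the non-assigned
    force plate, used to reject steps that did not land cleanly.
    """

    subject_id: str
    condition: str  # "baseline" | "toe_in"
    side: str  # "left" | "right"
    marker_series: Dict[str, np.ndarray]
    grf_series: np.ndarray  # (n_force_frames, 3) N
    cop_series: np.ndarray  # (n_force_frames, 3) mm
    plate_vertical_other: np.ndarray  # (n_force_frames,) N
    marker_rate: float  # Hz
    force_rate: float  # Hz
    walking_speed: float  # m/s
    height: float  # m
    weight: float  # kg

    def __post_init__(self):
        if self.condition not in ("baseline", "toe_in"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.marker_rate <= 0 or self.force_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if not (0.5 < self.height < 2.5):
            raise ValueError(f"implausible height {self.height} m")
        if not (20.0 < self.weight < 250.0):
            raise ValueError(f"implausible weight {self.weight} kg")
        lengths = {lab: len(arr) for lab, arr in self.marker_series.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"marker series lengths differ: {lengths}")
        n_force = len(self.grf_series)
        if len(self.cop_series) != n_force or len(self.plate_vertical_other) != n_force:
            raise ValueError("force, COP and other-plate series lengths differ")
        if n_force == 0 or (lengths and min(lengths.values()) == 0):
            raise ValueError("zero-length series are not allowed")

    @property
    def n_marker_frames(self) -> int:
        return len(next(iter(self.marker_series.values())))

    def equals(self, other: "TrialRecording", atol: float = 0.0) -> bool:
        """Field-by-field equality (NaNs compare equal); used by round-trip tests."""
        if (
            self.subject_id != other.subject_id
            or self.condition != other.condition
            or self.side != other.side
            or set(self.marker_series) != set(other.marker_series)
        ):
            return False
        scal = ("marker_rate", "force_rate", "walking_speed", "height", "weight")
        if any(
            not np.isclose(getattr(self, f), getattr(other, f), atol=atol)
            for f in scal
        ):
            return False
        for lab in self.marker_series:
            if not np.allclose(
                self.marker_series[lab], other.marker_series[lab],
                atol=atol, equal_nan=True,
            ):
                return False
        return all(
            np.allclose(getattr(self, f), getattr(other, f), atol=atol, equal_nan=True)
            for f in ("grf_series", "cop_series", "plate_vertical_other")
        )


@dataclass
class StanceEvent:
    """One detected stance phase on the force time base."""

    heel_strike_idx: int
    toe_off_idx: int
    duration_s: float

    def __post_init__(self):
        if self.toe_off_idx <= self.heel_strike_idx:
            raise ValueError("toe-off must follow heel strike")
        if not (0.2 <= self.duration_s <= 2.0):
            raise ValueError(f"stance duration {self.duration_s} s outside [0.2, 2.0]")


@dataclass
class StanceCycle:
    """One stance phase with every channel resampled to 101 points (0-100%).

    ``fpa_deg`` is the signed foot progression angle of this step (toe-out
    positive); ``rel_toe_in_deg`` is the toe-in magnitude relative to the
    subject's mean baseline FPA (positive = toeing in).
    """

    subject_id: str
    condition: str
    step_index: int
    channels: Dict[str, np.ndarray]
    fpa_deg: float
    rel_toe_in_deg: float
    duration_s: float

    def __post_init__(self):
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (N_STANCE_SAMPLES,):
                raise ValueError(
                    f"channel {name} has shape {arr.shape}, expected ({N_STANCE_SAMPLES},)"
                )
            self.channels[name] = arr
        grf_v = self.channels.get("GRF_V")
        if grf_v is not None and np.any(grf_v < 0):
            raise ValueError("GRF_V must be non-negative at every sample")

    def require_channels(self, names) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ValueError(f"cycle is missing channels: {missing}")

    def copy(self) -> "StanceCycle":
        return replace(self, channels={k: v.copy() for k, v in self.channels.items()})


@dataclass
class SubjectRecord:
    """A subject's clinical features plus segmented stance cycles."""

    subject_id: str
    height: float  # m
    weight: float  # kg
    walking_speed: float  # m/s
    static_valgus_deg: float  # valgus positive
    baseline_fpa_deg: float
    baseline_cycles: List[StanceCycle] = field(default_factory=list)
    toe_in_cycles: List[StanceCycle] = field(default_factory=list)

    def require_baseline(self) -> None:
        if not self.baseline_cycles:
            raise ValueError(
                f"subject {self.subject_id} has no baseline cycles"
            )


@dataclass
class KamTrace:
    """Normalized knee adduction moment over one stance phase.

    first_peak is the maximum over 0-50% stance, second_peak over
    50-100%; impulse is the trapezoidal time integral over the stance
    duration.  All values in %BW*HT (impulse %BW*HT*s).
    """

    values: np.ndarray
    first_peak: float
    second_peak: float
    impulse: float
    duration_s: float


@dataclass
class SyntheticEntry:
    """One synthesized subject x toe-in-angle outcome."""

    subject_id: str
    toe_in_deg: int
    synthetic_cycle: StanceCycle
    baseline_kam: KamTrace
    synthetic_kam: KamTrace
    first_peak_reduction: float  # %BW*HT, baseline - synthetic

    def __post_init__(self):
        if not np.isfinite(self.first_peak_reduction):
            raise IntegrityError("first-peak reduction is not finite")


def interpolate_gaps(values: np.ndarray, max_gap: int = 10) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap; longer runs stay NaN.

    Applied per scalar channel; steps whose window still contains NaN after
    filling are dropped by the segmentation stage.
    """
    out = np.asarray(values, dtype=float).copy()
    isnan = np.isnan(out)
    if not isnan.any():
        return out
    idx = np.arange(len(out))
    # locate NaN runs
    run_start: Optional[int] = None
    for i in range(len(out) + 1):
        if i < len(out) and isnan[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run_len = i - run_start
            interior = run_start > 0 and i < len(out)
            if run_len <= max_gap and interior:
                out[run_start:i] = np.interp(
                    idx[run_start:i],
                    [run_start - 1, i],
                    [out[run_start - 1], out[i]],
                )
            run_start = None
    return out
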