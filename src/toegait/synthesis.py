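"""Synthesizing toe-in gait from baseline walking with a learned pattern
library.

The learned (channel, bin) offset curves are added to a new subject's
mean baseline pelvis-relative KJC/FCP trajectories.  The mediolateral
offsets are carried over to the lab-frame KJC/COP channels used by the
lever-arm KAM (the pelvis is treated as stationary relative to the lab
over the cycle average); the vertical KJC coordinate and all ground
reaction force channels are taken from baseline unchanged — GRF does not
change with toe-in gait.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .datatypes import (
    GRF_CHANNELS,
    LAB_CHANNELS,
    PELVIS_CHANNELS,
    StanceCycle,
    SubjectRecord,
    SyntheticEntry,
)
from .kam import kam_trace_from_cycle
from .patterns import BINS, PatternLibrary


def baseline_mean_cycle(cycles: Sequence[StanceCycle]) -> StanceCycle:
    """Pointwise mean of a subject's clean baseline cycles (all channels,
    duration and FPA averaged)."""
    cycles = list(cycles)
    if not cycles:
        raise ValueError("cannot average an empty list of cycles")
    common = set(cycles[0].channels)
    for c in cycles[1:]:
        common &= set(c.channels)
    channels: Dict[str, np.ndarray] = {
        name: np.mean([c.channels[name] for c in cycles], axis=0) for name in common
    }
    if "GRF_V" in channels:
        channels["GRF_V"] = np.maximum(channels["GRF_V"], 0.0)
    return StanceCycle(
        subject_id=cycles[0].subject_id,
        condition=cycles[0].condition,
        step_index=-1,
        channels=channels,
        fpa_deg=float(np.mean([c.fpa_deg for c in cycles])),
        rel_toe_in_deg=float(np.mean([c.rel_toe_in_deg for c in cycles])),
        duration_s=float(np.mean([c.duration_s for c in cycles])),
    )


def apply_pattern(
    baseline_mean: StanceCycle, library: PatternLibrary, toe_in_deg: int
) -> StanceCycle:
    """Synthesize a toe-in stance cycle at an integer toe-in angle.

    Pelvis-relative channels get the learned offsets added; lab-frame
    KJC/COP mediolateral channels are shifted by the same ML offsets; GRF
    channels and vertical coordinates are copied from baseline unchanged.
    Extrapolation outside the library's bins is refused.
    """
    toe_in_deg = int(toe_in_deg)
    offsets = library.offsets_on_grid(toe_in_deg)  # raises IntegrityError if absent
    baseline_mean.require_channels(PELVIS_CHANNELS + LAB_CHANNELS + GRF_CHANNELS)

    channels: Dict[str, np.ndarray] = {}
    for name, arr in baseline_mean.channels.items():
        channels[name] = arr.copy()
    for c in PELVIS_CHANNELS:
        channels[c] = channels[c] + offsets[c]
    channels["KJC_LAB_ML"] = channels["KJC_LAB_ML"] + offsets["KJC_ML"]
    channels["COP_LAB_ML"] = channels["COP_LAB_ML"] + offsets["FCP_ML"]

    return StanceCycle(
        subject_id=baseline_mean.subject_id,
        condition="toe_in",
        step_index=-1,
        channels=channels,
        fpa_deg=baseline_mean.fpa_deg - toe_in_deg,
        rel_toe_in_deg=float(toe_in_deg),
        duration_s=baseline_mean.duration_s,
    )


def synthesize_cohort(
    subjects: Sequence[SubjectRecord],
    library: PatternLibrary,
    bins: Sequence[int] = BINS,
    include_shear_term: bool = True,
) -> List[SyntheticEntry]:
    """Apply the library to every subject at every toe-in angle.

    Returns |subjects| x |bins| entries; each entry carries the baseline
    and synthetic KAM traces and the first-peak reduction (the response
    variable of the predictive model).
    """
    entries: List[SyntheticEntry] = []
    for subj in subjects:
        subj.require_baseline()
        base_mean = baseline_mean_cycle(subj.baseline_cycles)
        base_kam = kam_trace_from_cycle(
            base_mean, subj.weight, subj.height, include_shear_term=include_shear_term
        )
        for b in bins:
            synth = apply_pattern(base_mean, library, b)
            synth_kam = kam_trace_from_cycle(
                synth, subj.weight, subj.height, include_shear_term=include_shear_term
            )
            entries.append(
                SyntheticEntry(
                    subject_id=subj.subject_id,
                    toe_in_deg=int(b),
                    synthetic_cycle=synth,
                    baseline_kam=base_kam,
                    synthetic_kam=synth_kam,
                    first_peak_reduction=base_kam.first_peak - synth_kam.first_peak,
                )
            )
    return entries
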