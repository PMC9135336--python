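"""Force-signal conditioning, stance-phase detection and time normalization.

Force and COP signals are low-pass filtered with a zero-lag (forward-
backward) Butterworth filter at 15 Hz.  Stance phases are detected as
rising/falling crossings of a 20 N vertical-GRF threshold with a short
debounce, the treadmill convention.  Each stance is resampled to 101
points spanning 0-100% of stance inclusive.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
from scipy import signal as sps

from .datatypes import N_STANCE_SAMPLES, StanceEvent

FILTER_CUTOFF_HZ = 15.0
FILTER_ORDER = 4
STANCE_THRESHOLD_N = 20.0
DEBOUNCE_FRAMES = 5
MIN_STANCE_S = 0.2
MAX_STANCE_S = 2.0


def lowpass_filter(
    values: Sequence[float],
    rate_hz: float,
    cutoff_hz: float = FILTER_CUTOFF_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-lag Butterworth low-pass filter (applied forward and backward).

    DC gain is exactly 1 and symmetric features keep their location.
    """
    values = np.asarray(values, float)
    if rate_hz <= 2.0 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    if values.size <= 3 * order:
        raise ValueError(
            f"signal of length {values.size} too short for order-{order} filtering"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, values)


def detect_stance_phases(
    grf_v: Sequence[float],
    rate_hz: float,
    threshold_n: float = STANCE_THRESHOLD_N,
    debounce_frames: int = DEBOUNCE_FRAMES,
) -> List[StanceEvent]:
    """Stance phases from a (filtered) vertical-GRF series.

    Contiguous above-threshold runs are candidate stances; below-threshold
    gaps shorter than the debounce are bridged and above-threshold blips
    shorter than the debounce are discarded.  Runs touching either edge of
    the series (partial phases) and runs outside the [0.2, 2.0] s duration
    bounds are dropped.
    """
    grf_v = np.asarray(grf_v, float)
    above = grf_v >= threshold_n
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]  # half-open [start, end)

    # bridge short gaps, then drop short runs
    merged = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < debounce_frames:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events: List[StanceEvent] = []
    for s, e in merged:
        if e - s < debounce_frames:
            continue
        if s == 0 or e >= len(grf_v):  # partial phase at a series edge
            continue
        duration = (e - 1 - s) / rate_hz
        if not (MIN_STANCE_S <= duration <= MAX_STANCE_S):
            continue
        events.append(StanceEvent(heel_strike_idx=int(s), toe_off_idx=int(e - 1),
                                  duration_s=float(duration)))
    return events


def is_clean_step(
    event: StanceEvent,
    other_plate_fz: Sequence[float],
    threshold_n: float = STANCE_THRESHOLD_N,
) -> bool:
    """True iff the non-assigned plate stays below threshold for the whole
    stance (the step landed cleanly on a single plate)."""
    other = np.asarray(other_plate_fz, float)
    if event.toe_off_idx >= len(other):
        raise ValueError("stance event extends beyond the other-plate series")
    window = other[event.heel_strike_idx : event.toe_off_idx + 1]
    return bool(np.all(window < threshold_n))


def time_normalize_stance(channel: Sequence[float], event: StanceEvent) -> np.ndarray:
    """Resample one channel over a stance to 101 points (0-100% inclusive).

    Sample i corresponds to i% of stance; values between frames are
    linearly interpolated, so the endpoints equal the channel at heel
    strike and toe-off exactly.
    """
    channel = np.asarray(channel, float)
    hs, to = event.heel_strike_idx, event.toe_off_idx
    if to - hs + 1 < 10:
        raise ValueError("stance spans fewer than 10 frames")
    if to >= len(channel):
        raise ValueError("stance event extends beyond the channel")
    src = np.arange(hs, to + 1)
    dst = np.linspace(hs, to, N_STANCE_SAMPLES)
    return np.interp(dst, src, channel[hs : to + 1])


def resample_window(values: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Resample ``values`` over the fractional frame window [start, stop]
    to 101 points (linear interpolation).  Used to cut marker-rate windows
    that correspond to force-rate stance events."""
    values = np.asarray(values, float)
    dst = np.linspace(start, stop, N_STANCE_SAMPLES)
    return np.interp(dst, np.arange(len(values)), values)
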