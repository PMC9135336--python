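"""Learning toe-in gait modification patterns from paired baseline/toe-in
trials.

For every toe-in step, the pelvis-relative knee-joint-center (KJC) and
foot-center-of-pressure (FCP) trajectories are expressed as offsets from
the same subject's mean baseline trajectory.  Steps are labelled by their
relative toe-in angle, pooled across subjects into 1-degree bins from 1 to
10 degrees, averaged within each bin, and smoothed with a least-squares
B-spline (order 12, i.e. degree 11, open uniform knot vector).  The
resulting :class:`PatternLibrary` is portable: applied to a new subject's
baseline gait it yields a synthetic toe-in trajectory at any integer
toe-in angle from 1 to 10 degrees.

The model/fit surface follows the statsmodels convention:
``ToeInPatternModel(cohort).fit(order=12)`` returns the fitted
:class:`PatternLibrary`, which also serves as the results object (it
carries per-bin provenance and evaluation hooks).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import BSpline, make_lsq_spline

from .datatypes import (
    N_STANCE_SAMPLES,
    PELVIS_CHANNELS,
    StanceCycle,
    SubjectRecord,
)
from .exceptions import IntegrityError
from .kam import kam_trace_from_cycle

DEFAULT_SPLINE_ORDER = 12
BINS = tuple(range(1, 11))

_GRID = np.linspace(0.0, 100.0, N_STANCE_SAMPLES)


def assign_bin(theta_deg: float) -> Optional[int]:
    """Map a relative toe-in angle to its 1-degree bin.

    Bin k covers [k - 0.5, k + 0.5) for k = 1..10; angles outside
    [0.5, 10.5) are not learned from and return None.
    """
    if not np.isfinite(theta_deg):
        return None
    if theta_deg < 0.5 or theta_deg >= 10.5:
        return None
    k = int(np.floor(theta_deg + 0.5))
    return k if 1 <= k <= 10 else None


def compute_step_offsets(
    toe_in_cycle: StanceCycle, baseline_mean: StanceCycle
) -> Dict[str, np.ndarray]:
    """Per-channel 101-point offsets of one toe-in step from the subject's
    mean baseline cycle (pelvis-relative channels only, mm)."""
    toe_in_cycle.require_channels(PELVIS_CHANNELS)
    baseline_mean.require_channels(PELVIS_CHANNELS)
    return {
        c: toe_in_cycle.channels[c] - baseline_mean.channels[c]
        for c in PELVIS_CHANNELS
    }


def _open_uniform_knots(order: int, n_interior: int) -> np.ndarray:
    k = order - 1  # spline degree
    interior = np.linspace(0.0, 100.0, n_interior + 2)[1:-1]
    return np.concatenate([np.zeros(k + 1), interior, np.full(k + 1, 100.0)])


@dataclass
class OffsetCurve:
    """Smoothed mean offset of one channel in one toe-in-angle bin."""

    channel: str
    bin_deg: int
    knots: np.ndarray
    coefs: np.ndarray
    n_steps: int
    order: int = DEFAULT_SPLINE_ORDER

    def __call__(self, stance_percent) -> np.ndarray:
        x = np.clip(np.asarray(stance_percent, float), 0.0, 100.0)
        return BSpline(self.knots, self.coefs, self.order - 1, extrapolate=False)(x)

    def on_grid(self) -> np.ndarray:
        return self(_GRID)


def fit_bin_curve(
    offsets: Sequence[np.ndarray],
    bin_deg: int,
    channel: str,
    order: int = DEFAULT_SPLINE_ORDER,
    n_interior_knots: int = 0,
) -> OffsetCurve:
    """Average the offset sequences of one bin and smooth with a
    least-squares B-spline of the given order over [0, 100]% stance."""
    if len(offsets) == 0:
        raise IntegrityError(f"empty bin {bin_deg} for channel {channel}")
    mean = np.mean(np.asarray(offsets, float), axis=0)
    if mean.shape != (N_STANCE_SAMPLES,):
        raise ValueError("offset sequences must have 101 samples")
    knots = _open_uniform_knots(order, n_interior_knots)
    spl = make_lsq_spline(_GRID, mean, knots, k=order - 1)
    return OffsetCurve(
        channel=channel,
        bin_deg=bin_deg,
        knots=np.asarray(spl.t, float),
        coefs=np.asarray(spl.c, float),
        n_steps=len(offsets),
        order=order,
    )


@dataclass
class PatternLibrary:
    """Fitted per-channel, per-bin offset curves plus provenance.

    ``provenance`` records cohort size, per-bin step counts, bins that had
    to be synthesized by neighbor interpolation, and the fit settings.
    """

    curves: Dict[Tuple[str, int], OffsetCurve]
    spline_order: int = DEFAULT_SPLINE_ORDER
    n_interior_knots: int = 0
    bins: Tuple[int, ...] = BINS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [
            (c, b) for c in PELVIS_CHANNELS for b in self.bins
            if (c, b) not in self.curves
        ]
        if missing:
            raise IntegrityError(f"pattern library missing curves: {missing}")

    def curve(self, channel: str, bin_deg: int) -> OffsetCurve:
        try:
            return self.curves[(channel, int(bin_deg))]
        except KeyError:
            raise IntegrityError(
                f"pattern library has no curve for ({channel}, {bin_deg})"
            ) from None

    def offsets_on_grid(self, bin_deg: int) -> Dict[str, np.ndarray]:
        return {c: self.curve(c, bin_deg).on_grid() for c in PELVIS_CHANNELS}

    # -- persistence -------------------------------------------------------

    def to_payload(self) -> dict:
        curves = {}
        for c in PELVIS_CHANNELS:
            curves[c] = {}
            for b in self.bins:
                cv = self.curve(c, b)
                curves[c][str(b)] = {
                    "knots": cv.knots.tolist(),
                    "coefs": cv.coefs.tolist(),
                    "n_steps": cv.n_steps,
                }
        return {
            "version": "1",
            "kind": "pattern_library",
            "spline_order": self.spline_order,
            "n_interior_knots": self.n_interior_knots,
            "bins": list(self.bins),
            "channels": list(PELVIS_CHANNELS),
            "curves": curves,
            "provenance": self.provenance,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "PatternLibrary":
        order = int(payload["spline_order"])
        bins = tuple(int(b) for b in payload["bins"])
        curves: Dict[Tuple[str, int], OffsetCurve] = {}
        for c in PELVIS_CHANNELS:
            chan = payload.get("curves", {}).get(c)
            if chan is None:
                raise IntegrityError(f"pattern file missing channel {c}")
            for b in bins:
                entry = chan.get(str(b))
                if entry is None:
                    raise IntegrityError(f"pattern file missing bin {b} for channel {c}")
                curves[(c, b)] = OffsetCurve(
                    channel=c,
                    bin_deg=b,
                    knots=np.asarray(entry["knots"], float),
                    coefs=np.asarray(entry["coefs"], float),
                    n_steps=int(entry["n_steps"]),
                    order=order,
                )
        return cls(
            curves=curves,
            spline_order=order,
            n_interior_knots=int(payload.get("n_interior_knots", 0)),
            bins=bins,
            provenance=dict(payload.get("provenance", {})),
        )


class ToeInPatternModel:
    """Pattern-learning model over a cohort with paired baseline/toe-in
    trials.

    Parameters
    ----------
    cohort : list of SubjectRecord
        Every subject must have baseline cycles; subjects without toe-in
        cycles contribute nothing to learning.
    """

    def __init__(self, cohort: Sequence[SubjectRecord]):
        self.cohort = list(cohort)
        for s in self.cohort:
            s.require_baseline()

    def fit(
        self,
        order: int = DEFAULT_SPLINE_ORDER,
        n_interior_knots: int = 0,
        bins: Sequence[int] = BINS,
    ) -> PatternLibrary:
        """Pool per-step offsets across the cohort, bin by relative toe-in
        angle, and fit each (channel, bin) offset curve.

        Bins empty across the whole cohort are synthesized by linear
        interpolation between the nearest populated neighbor bins and
        flagged in provenance.
        """
        from .synthesis import baseline_mean_cycle

        bins = tuple(int(b) for b in bins)
        pooled: Dict[Tuple[str, int], List[np.ndarray]] = {}
        per_bin_counts = {b: 0 for b in bins}
        for subj in self.cohort:
            if not subj.toe_in_cycles:
                continue
            base_mean = baseline_mean_cycle(subj.baseline_cycles)
            for cyc in subj.toe_in_cycles:
                b = assign_bin(cyc.rel_toe_in_deg)
                if b is None or b not in bins:
                    continue
                offs = compute_step_offsets(cyc, base_mean)
                for c in PELVIS_CHANNELS:
                    pooled.setdefault((c, b), []).append(offs[c])
                per_bin_counts[b] += 1

        if not pooled:
            raise ValueError("no toe-in steps fell inside the learnable bin range")

        curves: Dict[Tuple[str, int], OffsetCurve] = {}
        populated = sorted({b for (_, b) in pooled})
        interpolated_bins = [b for b in bins if b not in populated]
        for c in PELVIS_CHANNELS:
            for b in populated:
                curves[(c, b)] = fit_bin_curve(
                    pooled[(c, b)], b, c, order=order, n_interior_knots=n_interior_knots
                )
            for b in interpolated_bins:
                lower = [p for p in populated if p < b]
                upper = [p for p in populated if p > b]
                if lower and upper:
                    lo, hi = lower[-1], upper[0]
                elif len(lower) >= 2:  # edge bin: extrapolate from the two nearest
                    lo, hi = lower[-2], lower[-1]
                elif len(upper) >= 2:
                    lo, hi = upper[0], upper[1]
                else:
                    lo = hi = (lower or upper)[0]
                if lo == hi:
                    filled = curves[(c, lo)].on_grid()
                else:
                    w = (b - lo) / (hi - lo)
                    filled = (1 - w) * curves[(c, lo)].on_grid() + w * curves[
                        (c, hi)
                    ].on_grid()
                curves[(c, b)] = fit_bin_curve(
                    [filled], b, c, order=order, n_interior_knots=n_interior_knots
                )
                curves[(c, b)].n_steps = 0

        provenance = {
            "n_subjects": len(self.cohort),
            "per_bin_steps": {str(b): per_bin_counts[b] for b in bins},
            "interpolated_bins": interpolated_bins,
            "spline_order": order,
            "n_interior_knots": n_interior_knots,
        }
        provenance["config_hash"] = hashlib.sha256(
            json.dumps(provenance, sort_keys=True).encode()
        ).hexdigest()[:12]
        return PatternLibrary(
            curves=curves,
            spline_order=order,
            n_interior_knots=n_interior_knots,
            bins=bins,
            provenance=provenance,
        )


def learn_pattern_library(
    cohort: Sequence[SubjectRecord],
    order: int = DEFAULT_SPLINE_ORDER,
    n_interior_knots: int = 0,
    bins: Sequence[int] = BINS,
) -> PatternLibrary:
    """Functional wrapper: fit a :class:`ToeInPatternModel` on the cohort."""
    return ToeInPatternModel(cohort).fit(
        order=order, n_interior_knots=n_interior_knots, bins=bins
    )


def loocv_evaluate(
    cohort: Sequence[SubjectRecord],
    order: int = DEFAULT_SPLINE_ORDER,
    include_shear_term: bool = True,
) -> dict:
    """Exhaustive leave-one-out cross-validation of the learned patterns.

    For each subject: learn a library from the other subjects, synthesize
    a toe-in cycle at the left-out subject's mean relative toe-in angle
    from their own baseline, and compare against the subject's measured
    toe-in gait.  Synthetic KAM uses the subject's baseline ground
    reaction force (GRF does not change with toe-in).

    Returns a report dict with per-channel trajectory RMSE (mean/std over
    subjects, mm), KAM-trace RMSE (mean/std, %BW*HT) and first-peak KAM
    MAE (mean/std, %BW*HT).
    """
    from .synthesis import apply_pattern, baseline_mean_cycle

    cohort = list(cohort)
    if len(cohort) < 3:
        raise ValueError("LOOCV needs at least 3 subjects")

    traj_rmse: Dict[str, List[float]] = {c: [] for c in PELVIS_CHANNELS}
    kam_rmse: List[float] = []
    peak_err: List[float] = []
    n_evaluated = 0
    for i, subj in enumerate(cohort):
        if not subj.toe_in_cycles:
            warnings.warn(f"subject {subj.subject_id} has no toe-in cycles; skipped")
            continue
        thetas = [c.rel_toe_in_deg for c in subj.toe_in_cycles]
        target_bin = assign_bin(float(np.mean(thetas)))
        if target_bin is None:
            warnings.warn(
                f"subject {subj.subject_id} mean toe-in outside 1-10 deg; skipped"
            )
            continue
        train = cohort[:i] + cohort[i + 1 :]
        library = ToeInPatternModel(train).fit(order=order)

        base_mean = baseline_mean_cycle(subj.baseline_cycles)
        synth = apply_pattern(base_mean, library, target_bin)
        real_mean = _mean_cycle_channels(subj.toe_in_cycles)

        for c in PELVIS_CHANNELS:
            traj_rmse[c].append(
                float(np.sqrt(np.mean((synth.channels[c] - real_mean[c]) ** 2)))
            )
        synth_kam = kam_trace_from_cycle(
            synth, subj.weight, subj.height, include_shear_term=include_shear_term
        )
        real_kams = [
            kam_trace_from_cycle(
                cyc, subj.weight, subj.height, include_shear_term=include_shear_term
            )
            for cyc in subj.toe_in_cycles
        ]
        real_kam_trace = np.mean([k.values for k in real_kams], axis=0)
        real_first_peak = float(np.mean([k.first_peak for k in real_kams]))
        kam_rmse.append(
            float(np.sqrt(np.mean((synth_kam.values - real_kam_trace) ** 2)))
        )
        peak_err.append(abs(synth_kam.first_peak - real_first_peak))
        n_evaluated += 1

    if n_evaluated == 0:
        raise ValueError("no subject could be evaluated")

    def _agg(vals):
        return {"mean": float(np.mean(vals)), "std": float(np.std(vals))}

    return {
        "n_subjects": n_evaluated,
        "trajectory_rmse_mm": {c: _agg(traj_rmse[c]) for c in PELVIS_CHANNELS},
        "kam_rmse_pct_bwht": _agg(kam_rmse),
        "first_peak_mae_pct_bwht": _agg(peak_err),
    }


def _mean_cycle_channels(cycles: Sequence[StanceCycle]) -> Dict[str, np.ndarray]:
    common = set(cycles[0].channels)
    for c in cycles[1:]:
        common &= set(c.channels)
    return {
        name: np.mean([c.channels[name] for c in cycles], axis=0) for name in common
    }
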