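"""Reading and writing gait trials and pipeline artifacts.

Trial format (documented convention of this package; the underlying
studies' raw formats are not public):

* ``<stem>.markers.csv`` — wide CSV, one row per marker frame:
  ``time_s, <LABEL>_X, <LABEL>_Y, <LABEL>_Z`` in mm for the labels in
  :data:`toegait.datatypes.REQUIRED_MARKERS`.
* ``<stem>.forces.csv`` — force-plate CSV at its own rate:
  ``time_s, GRF_X, GRF_Y, GRF_Z (N), COP_X, COP_Y, COP_Z (mm),
  OTHER_PLATE_FZ (N)``.
* ``<stem>.meta.json`` — sidecar with subject metadata and unit
  declarations.

Artifacts (pattern libraries, regression models, feature tables) are
stored as versioned JSON; loading checks the version tag and structural
integrity before reconstructing the object.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import REQUIRED_MARKERS, TrialRecording
from .exceptions import FormatError, IntegrityError, SchemaError, VersionError

ARTIFACT_VERSION = "1"

_FORCE_COLUMNS = [
    "time_s", "GRF_X", "GRF_Y", "GRF_Z", "COP_X", "COP_Y", "COP_Z", "OTHER_PLATE_FZ",
]

_META_KEYS = [
    "subject_id", "condition", "side", "height_m", "weight_kg", "speed_mps",
    "marker_rate_hz", "force_rate_hz", "units",
]


def _force_path_for(trial_path: Path) -> Path:
    name = trial_path.name
    if name.endswith(".markers.csv"):
        return trial_path.with_name(name[: -len(".markers.csv")] + ".forces.csv")
    return trial_path.with_suffix(".forces.csv")


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged / truncated rows
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc


def _check_time(df: pd.DataFrame, path: Path) -> None:
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing required column time_s")
    t = df["time_s"].to_numpy(float)
    if np.isnan(t).any():
        raise FormatError(f"{path}: time column contains missing values (truncated file?)")
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")


def read_trial(
    trial_path, meta_path, force_path: Optional[str] = None
) -> TrialRecording:
    """Read one trial (marker CSV + force CSV + JSON sidecar).

    Positions are converted to mm if the sidecar declares metres.  The
    returned record keeps its recorded side; mirroring to the canonical
    left-leg frame is a separate, explicit step.
    """
    trial_path = Path(trial_path)
    meta_path = Path(meta_path)
    force_path = Path(force_path) if force_path else _force_path_for(trial_path)

    with open(meta_path) as fh:
        meta = json.load(fh)
    missing_meta = [k for k in _META_KEYS if k not in meta]
    if missing_meta:
        raise FormatError(f"{meta_path}: sidecar missing keys {missing_meta}")
    units = meta["units"]
    if "position" not in units or "force" not in units:
        raise FormatError(f"{meta_path}: unit declaration must name position and force")
    if units["position"] not in ("mm", "m") or units["force"] != "N":
        raise FormatError(f"{meta_path}: unsupported units {units}")
    pos_scale = 1000.0 if units["position"] == "m" else 1.0

    mdf = _read_csv(trial_path)
    _check_time(mdf, trial_path)
    markers = {}
    for lab in REQUIRED_MARKERS:
        cols = [f"{lab}_X", f"{lab}_Y", f"{lab}_Z"]
        missing = [c for c in cols if c not in mdf.columns]
        if missing:
            raise SchemaError(f"{trial_path}: missing marker columns for {lab}: {missing}")
        markers[lab] = mdf[cols].to_numpy(float) * pos_scale

    fdf = _read_csv(force_path)
    _check_time(fdf, force_path)
    missing = [c for c in _FORCE_COLUMNS if c not in fdf.columns]
    if missing:
        raise SchemaError(f"{force_path}: missing force columns: {missing}")
    grf = fdf[["GRF_X", "GRF_Y", "GRF_Z"]].to_numpy(float)
    cop = fdf[["COP_X", "COP_Y", "COP_Z"]].to_numpy(float) * pos_scale
    other = fdf["OTHER_PLATE_FZ"].to_numpy(float)
    if np.isnan(grf).any() or np.isnan(other).any():
        raise FormatError(f"{force_path}: force channels contain missing values")

    return TrialRecording(
        subject_id=str(meta["subject_id"]),
        condition=str(meta["condition"]),
        side=str(meta["side"]),
        marker_series=markers,
        grf_series=grf,
        cop_series=cop,
        plate_vertical_other=other,
        marker_rate=float(meta["marker_rate_hz"]),
        force_rate=float(meta["force_rate_hz"]),
        walking_speed=float(meta["speed_mps"]),
        height=float(meta["height_m"]),
        weight=float(meta["weight_kg"]),
    )


def write_trial(record: TrialRecording, trial_path, meta_path,
                force_path: Optional[str] = None, extra_meta: Optional[dict] = None) -> None:
    """Write a trial in the documented CSV + sidecar format.

    Missing marker frames (NaN) are written as empty fields and read back
    as NaN.  Round-trips to a field-by-field equal record.
    """
    trial_path = Path(trial_path)
    meta_path = Path(meta_path)
    force_path = Path(force_path) if force_path else _force_path_for(trial_path)

    n_m = record.n_marker_frames
    mdata = {"time_s": np.arange(n_m) / record.marker_rate}
    for lab in REQUIRED_MARKERS:
        arr = record.marker_series[lab]
        for j, ax in enumerate("XYZ"):
            mdata[f"{lab}_{ax}"] = arr[:, j]
    pd.DataFrame(mdata).to_csv(trial_path, index=False, float_format="%.10g")

    n_f = len(record.grf_series)
    fdata = {
        "time_s": np.arange(n_f) / record.force_rate,
        "GRF_X": record.grf_series[:, 0],
        "GRF_Y": record.grf_series[:, 1],
        "GRF_Z": record.grf_series[:, 2],
        "COP_X": record.cop_series[:, 0],
        "COP_Y": record.cop_series[:, 1],
        "COP_Z": record.cop_series[:, 2],
        "OTHER_PLATE_FZ": record.plate_vertical_other,
    }
    pd.DataFrame(fdata).to_csv(force_path, index=False, float_format="%.10g")

    meta = {
        "subject_id": record.subject_id,
        "condition": record.condition,
        "side": record.side,
        "height_m": record.height,
        "weight_kg": record.weight,
        "speed_mps": record.walking_speed,
        "marker_rate_hz": record.marker_rate,
        "force_rate_hz": record.force_rate,
        "units": {"position": "mm", "force": "N"},
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_sidecar(meta_path) -> dict:
    """Read a trial sidecar JSON (including any extra clinical keys)."""
    with open(meta_path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# versioned artifacts


def persist_artifact(obj, path) -> None:
    """Write a PatternLibrary, fitted regression results, or feature table
    (DataFrame) as versioned JSON."""
    from .patterns import PatternLibrary
    from .predictor import KamReductionResults

    path = Path(path)
    if isinstance(obj, PatternLibrary):
        payload = obj.to_payload()
    elif isinstance(obj, KamReductionResults):
        payload = obj.to_payload()
    elif isinstance(obj, pd.DataFrame):
        df = obj.reset_index(drop=True)
        payload = {
            "version": ARTIFACT_VERSION,
            "kind": "feature_table",
            "columns": list(df.columns),
            "data": [
                [None if (isinstance(v, float) and math.isnan(v)) else v for v in row]
                for row in df.itertuples(index=False)
            ],
        }
    else:
        raise TypeError(f"cannot persist object of type {type(obj).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_artifact(path):
    """Load a versioned artifact written by :func:`persist_artifact`."""
    from .patterns import PatternLibrary
    from .predictor import KamReductionResults

    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("version")
    if version != ARTIFACT_VERSION:
        raise VersionError(f"{path}: unsupported artifact version {version!r}")
    kind = payload.get("kind")
    if kind == "pattern_library":
        return PatternLibrary.from_payload(payload)
    if kind == "regression_model":
        return KamReductionResults.from_payload(payload)
    if kind == "feature_table":
        cols = payload.get("columns")
        data = payload.get("data")
        if cols is None or data is None:
            raise IntegrityError(f"{path}: feature table missing columns/data")
        return pd.DataFrame(data, columns=cols)
    raise IntegrityError(f"{path}: unknown artifact kind {kind!r}")
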