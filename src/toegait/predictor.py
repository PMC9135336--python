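"""Predicting first-peak KAM reduction from six clinical features.

The predictor is an ordinary least-squares linear model on standardized
features: height (m), weight (kg), baseline walking speed (m/s), static
knee alignment (valgus positive, degrees), baseline foot progression
angle (degrees) and target toe-in angle (degrees).  The response is the
first-peak KAM reduction in %BW*HT obtained from synthesized toe-in gait.
Data are split by *subject* (80/10/10 train/validation/test) so no
subject leaks across splits, and features are z-scored with training-set
statistics only.

API shape follows statsmodels: ``KamReductionModel(table).fit()`` returns
a :class:`KamReductionResults` with coefficient estimates, standard
errors, t statistics, p-values and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import SubjectRecord, SyntheticEntry
from .exceptions import CollinearityError

#: Canonical feature order of the six-feature model.
FEATURE_COLUMNS = [
    "height_m",
    "weight_kg",
    "speed_mps",
    "valgus_deg",
    "baseline_fpa_deg",
    "toe_in_deg",
]
RESPONSE_COLUMN = "reduction"


def build_feature_table(
    entries: Sequence[SyntheticEntry], subjects: Sequence[SubjectRecord]
) -> pd.DataFrame:
    """One row per synthetic entry: clinical features from the subject
    record, the entry's toe-in angle, and the first-peak reduction."""
    by_id = {s.subject_id: s for s in subjects}
    rows = []
    for e in entries:
        if e.subject_id not in by_id:
            raise KeyError(f"entry references unknown subject {e.subject_id}")
        s = by_id[e.subject_id]
        rows.append(
            {
                "subject_id": e.subject_id,
                "height_m": s.height,
                "weight_kg": s.weight,
                "speed_mps": s.walking_speed,
                "valgus_deg": s.static_valgus_deg,
                "baseline_fpa_deg": s.baseline_fpa_deg,
                "toe_in_deg": float(e.toe_in_deg),
                RESPONSE_COLUMN: e.first_peak_reduction,
            }
        )
    return pd.DataFrame(rows)


def split_by_subject(
    table: pd.DataFrame,
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    counts: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Assign train/val/test labels at the subject level.

    Subjects are shuffled with the seed; round(0.1 N) subjects each go to
    validation and test, the remainder to train (override with explicit
    ``counts`` = (n_train, n_val, n_test)).  Every row of a subject gets
    the same label.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    subjects = sorted(table["subject_id"].unique().tolist())
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects to split")
    if counts is None:
        n_val = max(1, int(round(fractions[1] * n)))
        n_test = max(1, int(round(fractions[2] * n)))
        n_train = n - n_val - n_test
    else:
        n_train, n_val, n_test = counts
        if n_train + n_val + n_test != n:
            raise ValueError("explicit split counts must sum to the subject count")
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("every split must receive at least one subject")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    label_of: Dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            label = "train"
        elif rank < n_train + n_val:
            label = "val"
        else:
            label = "test"
        label_of[subjects[idx]] = label
    out = table.copy()
    out["split"] = out["subject_id"].map(label_of)
    out.attrs["split_seed"] = int(seed)
    return out


class KamReductionResults:
    """Fitted linear predictor: standardization parameters, coefficients
    and inference, plus prediction and evaluation methods.

    Coefficients are on the standardized-feature scale (the scale on
    which they are comparable across features); ``params_raw`` gives the
    per-raw-unit slopes.
    """

    def __init__(
        self,
        feature_names: List[str],
        means: np.ndarray,
        scales: np.ndarray,
        intercept: float,
        coefficients: np.ndarray,
        stderrs: np.ndarray,
        t_stats: np.ndarray,
        p_values: np.ndarray,
        n_train: int,
        split_seed: Optional[int] = None,
    ):
        self.feature_names = list(feature_names)
        self.means = np.asarray(means, float)
        self.scales = np.asarray(scales, float)
        self.intercept = float(intercept)
        self.coefficients = np.asarray(coefficients, float)
        self.stderrs = np.asarray(stderrs, float)
        self.t_stats = np.asarray(t_stats, float)
        self.p_values = np.asarray(p_values, float)
        self.n_train = int(n_train)
        self.split_seed = split_seed

    # statsmodels-style aliases
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.feature_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.stderrs, index=self.feature_names)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self.p_values, index=self.feature_names)

    @property
    def params_raw(self) -> pd.Series:
        """Slopes per raw feature unit (coefficient / training scale)."""
        return pd.Series(self.coefficients / self.scales, index=self.feature_names)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Z-score the model's features with *training* statistics."""
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        X = table[self.feature_names].to_numpy(float)
        return (X - self.means) / self.scales

    def predict(self, table) -> np.ndarray:
        """Predicted first-peak KAM reduction (%BW*HT) for each row.

        Accepts a DataFrame or a mapping of single feature values.
        """
        if isinstance(table, dict):
            table = pd.DataFrame([table])
        Z = self.transform(table)
        return self.intercept + Z @ self.coefficients

    def evaluate(self, table: pd.DataFrame) -> dict:
        """Prediction-accuracy report on rows with responses.

        MAE (mean/std of |error|), R² of the coefficient of determination
        and of the actual-vs-predicted best-fit line, and the mean signed
        error (actual - predicted) aggregated per subject across that
        subject's angles, with a t-based 95% CI.
        """
        if len(table) == 0:
            raise ValueError("cannot evaluate on an empty table")
        actual = table[RESPONSE_COLUMN].to_numpy(float)
        pred = self.predict(table)
        err = actual - pred
        abs_err = np.abs(err)
        ss_res = float(np.sum(err**2))
        ss_tot = float(np.sum((actual - actual.mean()) ** 2))
        r2_pred = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        if np.std(actual) > 0 and np.std(pred) > 0:
            r = float(np.corrcoef(actual, pred)[0, 1])
            r2_line = r * r
        else:
            r2_line = float("nan")

        if "subject_id" in table.columns:
            signed = (
                pd.DataFrame({"subject_id": table["subject_id"].to_numpy(), "err": err})
                .groupby("subject_id")["err"]
                .mean()
                .to_numpy()
            )
        else:
            signed = err
        mean_signed = float(np.mean(signed))
        if len(signed) > 1 and np.std(signed, ddof=1) > 0:
            half = float(
                stats.t.ppf(0.975, len(signed) - 1)
                * np.std(signed, ddof=1)
                / np.sqrt(len(signed))
            )
        else:
            half = 0.0
        return {
            "n_rows": int(len(table)),
            "mae": float(abs_err.mean()),
            "mae_std": float(abs_err.std()),
            "r2_prediction": r2_pred,
            "r2_fit_line": r2_line,
            "mean_signed_error": mean_signed,
            "signed_error_ci95": [mean_signed - half, mean_signed + half],
            "n_subjects": int(len(signed)),
        }

    def summary(self) -> str:
        lines = [
            "KAM first-peak reduction — OLS on standardized features",
            f"n_train = {self.n_train}",
            f"intercept = {self.intercept:.6g}",
            f"{'feature':<18}{'coef':>12}{'std err':>12}{'t':>10}{'P>|t|':>10}",
        ]
        for j, name in enumerate(self.feature_names):
            lines.append(
                f"{name:<18}{self.coefficients[j]:>12.4g}{self.stderrs[j]:>12.4g}"
                f"{self.t_stats[j]:>10.3f}{self.p_values[j]:>10.4f}"
            )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def to_payload(self) -> dict:
        return {
            "version": "1",
            "kind": "regression_model",
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "beta0": self.intercept,
            "betas": self.coefficients.tolist(),
            "stderrs": self.stderrs.tolist(),
            "t_stats": self.t_stats.tolist(),
            "pvalues": self.p_values.tolist(),
            "n_train": self.n_train,
            "split_seed": self.split_seed,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "KamReductionResults":
        return cls(
            feature_names=list(payload["feature_names"]),
            means=np.asarray(payload["means"], float),
            scales=np.asarray(payload["scales"], float),
            intercept=float(payload["beta0"]),
            coefficients=np.asarray(payload["betas"], float),
            stderrs=np.asarray(payload["stderrs"], float),
            t_stats=np.asarray(payload.get("t_stats", [np.nan] * len(payload["betas"])), float),
            p_values=np.asarray(payload["pvalues"], float),
            n_train=int(payload["n_train"]),
            split_seed=payload.get("split_seed"),
        )


class KamReductionModel:
    """OLS model of first-peak KAM reduction on standardized clinical
    features.

    Parameters
    ----------
    table : DataFrame
        Feature table (one row per subject x toe-in angle) with the
        response column; typically from :func:`build_feature_table`.
    features : sequence of str
        Feature subset to use (default: the six-feature set).  A
        single-feature model, e.g. ``["toe_in_deg"]``, is supported.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        features: Sequence[str] = FEATURE_COLUMNS,
        response: str = RESPONSE_COLUMN,
    ):
        self.table = table
        self.features = list(features)
        self.response = response
        missing = [c for c in self.features + [response] if c not in table.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")

    @classmethod
    def from_entries(
        cls,
        entries: Sequence[SyntheticEntry],
        subjects: Sequence[SubjectRecord],
        **kwargs,
    ) -> "KamReductionModel":
        return cls(build_feature_table(entries, subjects), **kwargs)

    def fit(self, split: Optional[str] = "train") -> KamReductionResults:
        """Fit on the rows with the given split label (all rows if the
        table has no split column or ``split=None``)."""
        table = self.table
        if split is not None and "split" in table.columns:
            table = table[table["split"] == split]
        if len(table) < 10:
            raise ValueError("need at least 10 training rows")
        X = table[self.features].to_numpy(float)
        y = table[self.response].to_numpy(float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")

        means = X.mean(axis=0)
        scales = X.std(axis=0)
        degenerate = [f for f, s in zip(self.features, scales) if s <= 0]
        if degenerate:
            raise CollinearityError(degenerate)
        Z = (X - means) / scales
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            corr = np.corrcoef(Z, rowvar=False)
            bad = set()
            for a in range(len(self.features)):
                for b in range(a + 1, len(self.features)):
                    if abs(corr[a, b]) > 1.0 - 1e-10:
                        bad.update((self.features[a], self.features[b]))
            raise CollinearityError(sorted(bad) or self.features)

        ols = sm.OLS(y, sm.add_constant(Z, has_constant="add")).fit()
        seed = table.attrs.get("split_seed", self.table.attrs.get("split_seed"))
        return KamReductionResults(
            feature_names=self.features,
            means=means,
            scales=scales,
            intercept=float(ols.params[0]),
            coefficients=np.asarray(ols.params[1:], float),
            stderrs=np.asarray(ols.bse[1:], float),
            t_stats=np.asarray(ols.tvalues[1:], float),
            p_values=np.asarray(ols.pvalues[1:], float),
            n_train=len(table),
            split_seed=seed,
        )


def fit_linear_model(
    rows: pd.DataFrame, features: Sequence[str] = FEATURE_COLUMNS
) -> KamReductionResults:
    """Functional wrapper: fit on the given rows directly (no split filter)."""
    return KamReductionModel(rows, features=features).fit(split=None)


def predict_reduction(model: KamReductionResults, features) -> float:
    """Predicted reduction (%BW*HT) for a single feature mapping/row."""
    return float(np.asarray(model.predict(features)).ravel()[0])


def evaluate_predictions(model: KamReductionResults, rows: pd.DataFrame) -> dict:
    """Functional wrapper around :meth:`KamReductionResults.evaluate`."""
    return model.evaluate(rows)
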