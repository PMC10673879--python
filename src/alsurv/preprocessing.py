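"""From a raw visit-level table to an analysis-ready cohort.

The raw table has one row per patient with ISO-8601 dates -- recruitment
(first clinic visit), last contact, an optional composite-respiratory-
failure event date (death, tracheostomy, or >23 h/day non-invasive
ventilation), an optional MAID date -- and first-visit feature values with
missingness.  Outcome derivation:

* event date present        -> (event - recruitment, event = 1)
* MAID date present         -> (MAID - recruitment, event = 0); medical
  assistance in dying is treated as censoring independent of the disease's
  own course
* otherwise                 -> (last contact - recruitment, event = 0)

Days convert to months at 30.44 days/month.  Filtering then removes
patients with follow-up time 0 (no record after the first visit), drops
features missing in more than 80% of patients, and mean-imputes the rest.
Imputation scope is a switch: ``"cohort"`` imputes once on the whole table
(the order the original pipeline describes), while the default
``"fold_safe"`` leaves missing values in place for the cross-validation
engine to impute with training-fold means, avoiding test-set leakage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import CensoredSample
from .models.base import CLINICAL, IMAGE, FeatureMatrix

__all__ = [
    "CohortTable",
    "derive_outcome",
    "derive_outcomes",
    "filter_cohort",
    "load_raw_csv",
    "preprocess",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 30.44
MISSING_THRESHOLD = 0.80

_DATE_COLS = ("recruitment_date", "last_contact_date", "event_date", "maid_date")
_BLOCK_PREFIXES = {"clin_": CLINICAL, "img_": IMAGE}


@dataclass(frozen=True)
class CohortTable:
    """Feature table plus outcomes; features may hold NaN in fold-safe mode."""

    patient_ids: tuple[str, ...]
    times: np.ndarray
    events: np.ndarray
    features: pd.DataFrame
    blocks: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if not (len(self.patient_ids) == t.size == e.size == len(self.features)):
            raise ValueError("cohort components have inconsistent lengths")
        if np.any(t <= 0):
            raise ValueError("all observed times must be positive (filter time-0 rows first)")
        missing_blocks = set(self.features.columns) - set(self.blocks)
        if missing_blocks:
            raise ValueError(f"features without a block label: {sorted(missing_blocks)}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return len(self.patient_ids)

    @property
    def sample(self) -> CensoredSample:
        return CensoredSample(self.times, self.events)

    def subset_rows(self, idx) -> "CohortTable":
        idx = np.asarray(idx)
        return CohortTable(
            tuple(np.asarray(self.patient_ids)[idx]),
            self.times[idx],
            self.events[idx],
            self.features.iloc[idx].reset_index(drop=True),
            self.blocks,
        )

    def restrict_features(self, names) -> "CohortTable":
        names = list(names)
        return CohortTable(
            self.patient_ids,
            self.times,
            self.events,
            self.features[names],
            {k: self.blocks[k] for k in names},
        )

    def restrict_block(self, feature_set: str) -> "CohortTable":
        """Restrict to a feature set: 'clinical', 'image' or 'both'."""
        if feature_set == "both":
            return self
        keep = [c for c in self.features.columns if self.blocks[c] == feature_set]
        if not keep:
            raise ValueError(f"no features in block {feature_set!r}")
        return self.restrict_features(keep)

    def feature_matrix(self) -> FeatureMatrix:
        cols = list(self.features.columns)
        return FeatureMatrix(
            self.features.to_numpy(dtype=float),
            tuple(cols),
            tuple(self.blocks[c] for c in cols),
        )

    def to_csv(self, path) -> None:
        df = self.features.copy()
        df.insert(0, "patient_id", self.patient_ids)
        df.insert(1, "time_months", self.times)
        df.insert(2, "event", self.events)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path)
        feats = df.drop(columns=["patient_id", "time_months", "event"])
        return cls(
            tuple(df["patient_id"].astype(str)),
            df["time_months"].to_numpy(float),
            df["event"].to_numpy(int),
            feats,
            {c: _infer_block(c) for c in feats.columns},
        )


def _infer_block(col: str) -> str:
    for prefix, block in _BLOCK_PREFIXES.items():
        if col.startswith(prefix):
            return block
    raise ValueError(f"cannot infer feature block from column name {col!r}")


def load_raw_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _DATE_COLS:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
    return df


def derive_outcome(row) -> tuple[float, int]:
    """(observed time in months, event indicator) for one patient row."""
    rec = row["recruitment_date"]
    if pd.isna(rec):
        raise ValueError("recruitment date is required")

    def _months(date) -> float:
        days = (date - rec) / pd.Timedelta(days=1)
        if days < 0:
            raise ValueError(f"date {date} precedes recruitment {rec}")
        return float(days) / DAYS_PER_MONTH

    if "event_date" in row and pd.notna(row["event_date"]):
        return _months(row["event_date"]), 1
    if "maid_date" in row and pd.notna(row["maid_date"]):
        return _months(row["maid_date"]), 0
    return _months(row["last_contact_date"]), 0


def derive_outcomes(raw: pd.DataFrame) -> pd.DataFrame:
    """Vectorized outcome derivation; appends time_months and event columns."""
    out = raw.copy()
    outcomes = [derive_outcome(row) for _, row in raw.iterrows()]
    out["time_months"] = [t for t, _ in outcomes]
    out["event"] = [e for _, e in outcomes]
    return out


def filter_cohort(
    table: pd.DataFrame,
    impute: str = "fold_safe",
    missing_threshold: float = MISSING_THRESHOLD,
) -> tuple[CohortTable, dict]:
    """Apply the row and feature filters; returns the cohort and a removal report."""
    if impute not in ("fold_safe", "cohort"):
        raise ValueError("impute must be 'fold_safe' or 'cohort'")
    feature_cols = [c for c in table.columns if any(c.startswith(p) for p in _BLOCK_PREFIXES)]
    n_in = len(table)
    keep_rows = table["time_months"] > 0
    kept = table.loc[keep_rows].reset_index(drop=True)
    if kept.empty:
        raise ValueError("no patients remain after removing zero-time rows")

    miss_frac = kept[feature_cols].isna().mean()
    dropped_features = [c for c in feature_cols if miss_frac[c] > missing_threshold]
    kept_features = [c for c in feature_cols if c not in dropped_features]
    if not kept_features:
        raise ValueError("no features remain after the missingness filter")

    feats = kept[kept_features].astype(float).copy()
    if impute == "cohort":
        feats = feats.fillna(feats.mean())

    report = {
        "rows_in": int(n_in),
        "rows_out": int(len(kept)),
        "rows_dropped": int(n_in - len(kept)),
        "features_in": len(feature_cols),
        "features_out": len(kept_features),
        "features_dropped": len(dropped_features),
        "dropped_feature_names": dropped_features,
        "impute_mode": impute,
        "residual_missing_fraction": float(kept[kept_features].isna().to_numpy().mean()),
    }
    cohort = CohortTable(
        tuple(kept["patient_id"].astype(str)),
        kept["time_months"].to_numpy(float),
        kept["event"].to_numpy(int),
        feats,
        {c: _infer_block(c) for c in kept_features},
    )
    return cohort, report


def preprocess(raw: pd.DataFrame, impute: str = "fold_safe") -> tuple[CohortTable, dict]:
    """Full transform: outcomes then filters. ``raw`` as from :func:`load_raw_csv`."""
    return filter_cohort(derive_outcomes(raw), impute=impute)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
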