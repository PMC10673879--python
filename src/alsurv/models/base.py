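"""Shared infrastructure for the base ISD learners.

Every learner exposes the same surface -- ``fit(X, y)`` /
``predict_curves(X)`` returning one :class:`~alsurv.curves.SurvivalCurve`
per row -- so the SuperLearner can treat them interchangeably.  Feature
standardization (z-scoring with training-fold statistics) happens inside
each wrapper: it makes a single L2 constant meaningful across features of
very different scales (ALSFRS-R scores vs cortical thickness in mm).
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from ..curves import CensoredSample, SurvivalCurve

__all__ = ["FeatureMatrix", "TimeGrid", "Standardizer", "ISDModel", "ConvergenceError"]

CLINICAL = "clinical"
IMAGE = "image"


class ConvergenceError(RuntimeError):
    """An optimizer failed to reach its tolerance; carries diagnostics."""


@dataclass(frozen=True)
class FeatureMatrix:
    """An n x d feature block with names and per-feature block labels."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    block_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.feature_names) != v.shape[1] or len(self.block_labels) != v.shape[1]:
            raise ValueError("feature_names/block_labels must match the number of columns")
        if np.isnan(v).any():
            raise ValueError("feature matrix contains missing values; impute upstream")
        bad = set(self.block_labels) - {CLINICAL, IMAGE}
        if bad:
            raise ValueError(f"unknown block labels: {sorted(bad)}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "block_labels", tuple(self.block_labels))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TimeGrid:
    """Ordered positive bin edges t_1 < ... < t_m partitioning [0, inf)."""

    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, dtype=float)
        if e.ndim != 1 or e.size == 0:
            raise ValueError("bin_edges must be a non-empty 1-D array")
        if np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise ValueError("bin_edges must be positive and strictly increasing")
        object.__setattr__(self, "bin_edges", e)

    @property
    def m(self) -> int:
        return int(self.bin_edges.size)

    @classmethod
    def from_sample(cls, y: CensoredSample) -> "TimeGrid":
        """Grid with m = ceil(sqrt(#events)) edges at empirical quantiles of event times.

        Quantile placement keeps roughly equal information per bin;
        deduplication may shrink m when event times repeat.  The last edge
        is the largest event time so the grid covers the observed range.
        """
        ev = y.times[y.events == 1]
        if ev.size == 0:
            raise ValueError("need at least one event to build a time grid")
        m = int(np.ceil(np.sqrt(ev.size)))
        qs = np.quantile(ev, np.arange(1, m + 1) / m)
        return cls(np.unique(qs))


class Standardizer:
    """Column z-scoring with training statistics; zero-variance columns pass through."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0) if X.shape[1] else np.zeros(0)
        sd = X.std(axis=0, ddof=0) if X.shape[1] else np.zeros(0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        s = cls()
        s.mean_ = np.asarray(d["mean"], dtype=float)
        s.scale_ = np.asarray(d["scale"], dtype=float)
        return s


class ISDModel(ABC):
    """Uniform fit/predict surface for the four base learners."""

    @abstractmethod
    def fit(self, X: FeatureMatrix, y: CensoredSample) -> "ISDModel": ...

    @abstractmethod
    def predict_curves(self, X: np.ndarray) -> list[SurvivalCurve]: ...

    @abstractmethod
    def to_dict(self) -> dict: ...

    def save(self, path) -> None:
        payload = self.to_dict()
        payload["__class__"] = type(self).__name__
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def load(path) -> "ISDModel":
        from . import MODEL_REGISTRY

        with open(path) as fh:
            payload = json.load(fh)
        cls = MODEL_REGISTRY[payload.pop("__class__")]
        return cls.from_dict(payload)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)
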