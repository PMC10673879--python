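"""Random survival forest: log-rank splitting, Nelson-Aalen leaves.

Each tree is grown on a bootstrap resample of the training cohort.  At
every node a random subset of ``mtry`` features is inspected and the split
maximizing the two-sample log-rank statistic is taken, subject to both
children retaining at least ``min_leaf_events`` observed events; nodes
where no valid split exists become leaves.  A leaf predicts
exp(-Nelson-Aalen cumulative hazard) of its sample, evaluated on a common
grid (the distinct training event times); the forest prediction averages
the tree curves on that grid.  All randomness (bootstrap draws, feature
subsets) flows from the single constructor seed, so refits are
bit-identical.
"""

from __future__ import annotations

import numpy as np

from ..curves import CensoredSample, SurvivalCurve
from .base import FeatureMatrix, ISDModel, _as_matrix

__all__ = ["RSFModel"]


def _logrank_best_split(x, times, events, min_leaf_events):
    """Best threshold on one feature by the log-rank statistic.

    Returns ``(stat, threshold)`` or ``(-inf, nan)`` when no valid split
    exists.  Vectorized over all candidate thresholds at once.
    """
    order = np.argsort(x, kind="stable")
    xs, ts, es = x[order], times[order], events[order]
    n = xs.size
    uniq_event_times = np.unique(ts[es == 1])
    if uniq_event_times.size == 0 or n < 2:
        return -np.inf, np.nan
    atrisk = ts[:, None] >= uniq_event_times[None, :]
    death = (ts[:, None] == uniq_event_times[None, :]) & (es[:, None] == 1)
    n_j = atrisk.sum(axis=0).astype(float)
    d_j = death.sum(axis=0).astype(float)
    # row k-1 of the cumsums = left-child counts when the first k sorted rows go left
    N_left = np.cumsum(atrisk, axis=0)[:-1].astype(float)
    D_left = np.cumsum(death, axis=0)[:-1].astype(float)
    U = np.sum(D_left - d_j * N_left / n_j, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_j = np.where(
            n_j > 1,
            d_j * (n_j - d_j) / (n_j - 1) * N_left * (n_j - N_left) / (n_j * n_j),
            0.0,
        )
    V = var_j.sum(axis=1)
    ev_left = np.cumsum(es)[:-1]
    ev_right = es.sum() - ev_left
    valid = (
        (xs[:-1] < xs[1:])
        & (ev_left >= min_leaf_events)
        & (ev_right >= min_leaf_events)
        & (V > 0)
    )
    if not valid.any():
        return -np.inf, np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(valid, U * U / V, -np.inf)
    k = int(np.argmax(stat))
    return float(stat[k]), float(0.5 * (xs[k] + xs[k + 1]))


def _na_survival(times, events, grid) -> np.ndarray:
    """exp(-Nelson-Aalen cumulative hazard) of a sample, evaluated at grid times."""
    uniq = np.unique(times[events == 1])
    if uniq.size == 0:
        return np.ones(grid.size)
    n_j = (times[:, None] >= uniq[None, :]).sum(axis=0).astype(float)
    d_j = ((times[:, None] == uniq[None, :]) & (events[:, None] == 1)).sum(axis=0)
    increments = d_j / n_j
    cumhaz = np.cumsum(increments)
    idx = np.searchsorted(uniq, grid, side="right")
    H = np.where(idx > 0, cumhaz[np.maximum(idx - 1, 0)], 0.0)
    return np.exp(-H)


class RSFModel(ISDModel):
    def __init__(
        self,
        n_trees: int = 100,
        mtry: int | None = None,
        min_leaf_events: int = 3,
        max_depth: int | None = None,
        seed: int = 0,
    ):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_leaf_events = min_leaf_events
        self.max_depth = max_depth
        self.seed = seed
        self.trees_: list[dict] | None = None
        self.grid_: np.ndarray | None = None
        self.bootstrap_indices_: list[np.ndarray] | None = None

    def _grow(self, X, times, events, rng, depth) -> dict:
        n_events = int(events.sum())
        at_depth_cap = self.max_depth is not None and depth >= self.max_depth
        if at_depth_cap or n_events < 2 * self.min_leaf_events or X.shape[0] < 2:
            return {"leaf": _na_survival(times, events, self.grid_).tolist()}
        d = X.shape[1]
        mtry = self.mtry if self.mtry is not None else int(np.ceil(np.sqrt(d)))
        feats = rng.choice(d, size=min(mtry, d), replace=False)
        best = (-np.inf, np.nan, -1)
        for f in feats:
            stat, thr = _logrank_best_split(X[:, f], times, events, self.min_leaf_events)
            if stat > best[0]:
                best = (stat, thr, int(f))
        if not np.isfinite(best[0]):
            return {"leaf": _na_survival(times, events, self.grid_).tolist()}
        stat, thr, f = best
        mask = X[:, f] <= thr
        return {
            "feature": f,
            "threshold": thr,
            "left": self._grow(X[mask], times[mask], events[mask], rng, depth + 1),
            "right": self._grow(X[~mask], times[~mask], events[~mask], rng, depth + 1),
        }

    def fit(self, X: FeatureMatrix, y: CensoredSample) -> "RSFModel":
        Xv = _as_matrix(X)
        n = Xv.shape[0]
        self.grid_ = np.unique(y.times[y.events == 1])
        if self.grid_.size == 0:
            raise ValueError("need at least one event to fit a survival forest")
        ss = np.random.SeedSequence(self.seed)
        self.trees_ = []
        self.bootstrap_indices_ = []
        for child in ss.spawn(self.n_trees):
            rng = np.random.default_rng(child)
            idx = rng.integers(0, n, size=n)
            self.bootstrap_indices_.append(idx)
            self.trees_.append(self._grow(Xv[idx], y.times[idx], y.events[idx], rng, 0))
        self.d_ = Xv.shape[1]
        return self

    def _tree_predict(self, node: dict, x: np.ndarray) -> np.ndarray:
        while "leaf" not in node:
            node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
        return np.asarray(node["leaf"], dtype=float)

    def predict_curves(self, X) -> list[SurvivalCurve]:
        if self.trees_ is None:
            raise RuntimeError("model not fitted")
        Xv = _as_matrix(X)
        if Xv.shape[1] != self.d_:
            raise ValueError(f"expected {self.d_} features, got {Xv.shape[1]}")
        knots = np.concatenate(([0.0], self.grid_))
        out = []
        for x in Xv:
            avg = np.mean([self._tree_predict(t, x) for t in self.trees_], axis=0)
            vals = np.concatenate(([1.0], np.clip(avg, 0, 1)))
            out.append(SurvivalCurve(knots, np.minimum.accumulate(vals), interpolation="step"))
        return out

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "min_leaf_events": self.min_leaf_events,
            "max_depth": self.max_depth,
            "seed": self.seed,
            "trees": self.trees_,
            "grid": self.grid_.tolist(),
            "d": self.d_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RSFModel":
        m = cls(
            n_trees=d["n_trees"],
            mtry=d["mtry"],
            min_leaf_events=d["min_leaf_events"],
            max_depth=d["max_depth"],
            seed=d["seed"],
        )
        m.trees_ = d["trees"]
        m.grid_ = np.asarray(d["grid"], dtype=float)
        m.d_ = d["d"]
        return m
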