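"""Survival-curve primitives: representation, Kaplan-Meier estimation and queries.

A :class:`SurvivalCurve` is a patient-level (or cohort-level) survival
function S(t) stored at a finite set of knots.  Two interpolation
conventions coexist in this package:

* ``"step"`` -- right-continuous step functions, the natural form of the
  Kaplan-Meier product-limit estimator and of Nelson-Aalen-based forest
  leaves;
* ``"linear"`` -- piecewise-linear curves, used for discrete-time model
  output (MTLR) and for parametric curves sampled onto a grid, where a
  coarse knot grid would otherwise make the median ill-defined.

Curves that never reach zero are extended with a bounded linear tail (see
:func:`tail_extension`) so that medians and conditional tail means always
exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalCurve",
    "CensoredSample",
    "km_fit",
    "survival_at",
    "median_survival_time",
    "conditional_mean_beyond",
    "tail_extension",
    "curves_to_csv",
    "curves_from_csv",
    "ZeroSurvivalError",
]

_MONO_TOL = 1e-12  # monotonicity slack before we declare a curve invalid


class ZeroSurvivalError(ValueError):
    """Raised when a query conditions on an event the curve rules out (S(c) = 0)."""


@dataclass(frozen=True)
class SurvivalCurve:
    """A survival function S(t) stored at knots.

    Parameters
    ----------
    knot_times:
        Strictly increasing times in months; the first knot must be 0.
    knot_survival:
        Survival probabilities at the knots; ``knot_survival[0]`` must be 1,
        values lie in [0, 1] and are non-increasing.
    interpolation:
        ``"step"`` (right-continuous) or ``"linear"``.
    """

    knot_times: np.ndarray
    knot_survival: np.ndarray
    interpolation: str = "step"

    def __post_init__(self) -> None:
        t = np.asarray(self.knot_times, dtype=float)
        s = np.asarray(self.knot_survival, dtype=float)
        if t.ndim != 1 or s.ndim != 1 or t.shape != s.shape or t.size == 0:
            raise ValueError("knot_times and knot_survival must be equal-length 1-D arrays")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(s)):
            raise ValueError("curve knots must be finite")
        if t[0] != 0.0:
            raise ValueError("first knot time must be 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if abs(s[0] - 1.0) > _MONO_TOL:
            raise ValueError("survival at time 0 must be 1")
        if np.any(np.diff(s) > _MONO_TOL):
            raise ValueError("survival values must be non-increasing")
        if np.any(s < -_MONO_TOL) or np.any(s > 1.0 + _MONO_TOL):
            raise ValueError("survival values must lie in [0, 1]")
        if self.interpolation not in ("step", "linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
        object.__setattr__(self, "knot_times", t)
        object.__setattr__(self, "knot_survival", s)

    # Convenience wrappers so curves read naturally at call sites.
    def __call__(self, t) -> float:
        return survival_at(self, t)

    def median(self) -> float:
        return median_survival_time(self)


@dataclass(frozen=True)
class CensoredSample:
    """Right-censored observations: times t_i > 0 and event flags (1 = event)."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.ndim != 1 or e.ndim != 1 or t.shape != e.shape:
            raise ValueError("times and events must be equal-length 1-D arrays")
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("observed times must be positive and finite")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


def km_fit(sample: CensoredSample) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate of a censored sample.

    Ties between events and censorings at the same timestamp follow the
    standard convention: events are processed before censorings, so a
    patient censored at an event time is still in the risk set for that
    event.  The returned curve is a right-continuous step function with
    drops only at event times.
    """
    if len(sample) == 0:
        raise ValueError("cannot fit Kaplan-Meier on an empty sample")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(sample.times, event_observed=sample.events)
    sf = kmf.survival_function_.iloc[:, 0]
    times = np.asarray(sf.index, dtype=float)
    surv = np.asarray(sf.values, dtype=float)
    # keep t=0, every knot where the curve drops, and the last observed time
    # (the latter pins the flat stretch after the final event/censoring)
    keep = np.concatenate(([True], np.diff(surv) < 0))
    keep[0] = True
    keep[-1] = True
    if times[0] != 0.0:
        times = np.concatenate(([0.0], times))
        surv = np.concatenate(([1.0], surv))
        keep = np.concatenate(([True], keep))
    return SurvivalCurve(times[keep], surv[keep], interpolation="step")


def tail_extension(curve: SurvivalCurve) -> tuple[float, float]:
    """Parameters of the linear tail used beyond the last knot.

    Returns ``(slope, t_end)``: for ``t_last < t < t_end`` the extended
    curve is ``s_last + slope * (t - t_last)``; at and beyond ``t_end`` it
    is 0.  The slope comes from the last two knots, or from the line through
    (0, 1) and the last knot when the former is flat or rising; the
    extension is capped at three times the last knot time, where the curve
    drops to 0.
    """
    t = curve.knot_times
    s = curve.knot_survival
    t_last, s_last = float(t[-1]), float(s[-1])
    if s_last <= 0.0:
        return 0.0, t_last
    if t_last == 0.0:
        return 0.0, 0.0  # degenerate single-knot curve: S = 0 for all t > 0
    slope = 0.0
    if t.size >= 2:
        slope = (s[-1] - s[-2]) / (t[-1] - t[-2])
    if t.size < 2 or slope >= 0.0:
        slope = (s_last - 1.0) / t_last
    t_cap = 3.0 * t_last
    if slope < 0.0:
        t_zero = t_last + s_last / (-slope)
        return float(slope), float(min(t_zero, t_cap))
    return 0.0, float(t_cap)


def survival_at(curve: SurvivalCurve, t) -> float:
    """S(t) under the curve's interpolation convention, tail-extended beyond the last knot."""
    t = float(t)
    if t < 0:
        raise ValueError("time must be non-negative")
    kt, ks = curve.knot_times, curve.knot_survival
    if t <= kt[-1]:
        if curve.interpolation == "linear":
            return float(np.interp(t, kt, ks))
        idx = int(np.searchsorted(kt, t, side="right")) - 1
        return float(ks[idx])
    slope, t_end = tail_extension(curve)
    if t >= t_end:
        return 0.0
    return float(max(ks[-1] + slope * (t - kt[-1]), 0.0))


def _extended_breakpoints(curve: SurvivalCurve) -> tuple[np.ndarray, np.ndarray]:
    """Knots of the tail-extended curve, ending at the time it reaches (or is dropped to) 0."""
    kt, ks = curve.knot_times, curve.knot_survival
    if ks[-1] <= 0.0:
        return kt, ks
    slope, t_end = tail_extension(curve)
    s_end_minus = max(ks[-1] + slope * (t_end - kt[-1]), 0.0) if t_end > kt[-1] else ks[-1]
    # value immediately before t_end on the extension line (the curve drops to 0 at t_end)
    if t_end <= kt[-1]:
        return kt, ks
    return np.append(kt, t_end), np.append(ks, s_end_minus)


def median_survival_time(curve: SurvivalCurve) -> float:
    """Smallest t with S(t) <= 0.5; solved on the tail extension when needed."""
    kt, ks = _extended_breakpoints(curve)
    below = ks <= 0.5
    if not below.any():
        return float(kt[-1])  # drops to 0 (past the cap) only at the final breakpoint
    j = int(np.argmax(below))
    if j == 0:
        return float(kt[0])
    step_like = curve.interpolation == "step" and j < curve.knot_times.size
    if step_like:
        return float(kt[j])
    t0, t1 = kt[j - 1], kt[j]
    s0, s1 = ks[j - 1], ks[j]
    if s1 == s0:
        return float(t1)
    return float(t0 + (s0 - 0.5) * (t1 - t0) / (s0 - s1))


def _integral_from(curve: SurvivalCurve, c: float) -> float:
    """Exact integral of the tail-extended curve over [c, time-of-zero]."""
    kt, ks = _extended_breakpoints(curve)
    n_orig = curve.knot_times.size
    total = 0.0
    for j in range(kt.size - 1):
        a, b = float(kt[j]), float(kt[j + 1])
        if b <= c:
            continue
        lo = max(a, c)
        seg_step = curve.interpolation == "step" and (j + 1) < n_orig
        if seg_step:
            total += ks[j] * (b - lo)
        else:
            # linear segment (model curves, or the tail extension of any curve)
            sa = ks[j] + (ks[j + 1] - ks[j]) * (lo - a) / (b - a)
            total += 0.5 * (sa + ks[j + 1]) * (b - lo)
    return total


def conditional_mean_beyond(curve: SurvivalCurve, c) -> float:
    """Mean survival time conditional on surviving to time ``c``.

    Computes ``c + (integral of S from c to T) / S(c)`` where T is where the
    tail-extended curve reaches 0.  With ``c = 0`` this is the unconditional
    mean of the distribution the curve encodes.
    """
    c = float(c)
    if c < 0:
        raise ValueError("conditioning time must be non-negative")
    s_c = survival_at(curve, c)
    if s_c <= 0.0:
        raise ZeroSurvivalError(f"S({c}) = 0: cannot condition on surviving past {c}")
    return c + _integral_from(curve, c) / s_c


# ---------------------------------------------------------------------------
# CSV serialization: long format (patient_id, time, survival)


def curves_to_csv(curves: Mapping[str, SurvivalCurve], path) -> None:
    rows = []
    for pid, curve in curves.items():
        for t, s in zip(curve.knot_times, curve.knot_survival):
            rows.append((pid, t, s, curve.interpolation))
    pd.DataFrame(rows, columns=["patient_id", "time", "survival", "interpolation"]).to_csv(
        path, index=False
    )


def curves_from_csv(path) -> dict[str, SurvivalCurve]:
    df = pd.read_csv(path)
    out: dict[str, SurvivalCurve] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("time")
        interp = grp["interpolation"].iloc[0] if "interpolation" in grp else "step"
        out[str(pid)] = SurvivalCurve(
            grp["time"].to_numpy(), grp["survival"].to_numpy(), interpolation=interp
        )
    return out
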