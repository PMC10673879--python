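"""Censoring-aware evaluation of individual survival distribution predictions.

The headline statistic is the MAE-margin: a mean absolute error between
predicted and "true" event times in which each censored patient's true
time is imputed as the mean of the training Kaplan-Meier curve conditioned
on surviving past that patient's censoring time (the *margin time*).  The
predicted event time of a patient is the median of their predicted survival
curve.  Discrimination is summarised by Harrell's concordance index over
predicted times, and single-horizon classification accuracy excludes
patients censored before the horizon, since their status there is unknown.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import (
    CensoredSample,
    SurvivalCurve,
    ZeroSurvivalError,
    conditional_mean_beyond,
    median_survival_time,
    survival_at,
)

__all__ = [
    "Prediction",
    "EvaluationReport",
    "margin_time",
    "mae_margin",
    "c_index",
    "horizon_accuracy",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class Prediction:
    """One patient's predicted survival curve and the derived point prediction."""

    patient_id: str
    curve: SurvivalCurve
    predicted_time: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.predicted_time is None:
            object.__setattr__(self, "predicted_time", median_survival_time(self.curve))


@dataclass
class EvaluationReport:
    mae_margin: float
    c_index: float
    horizon_accuracies: dict[float, float]
    n_used: dict[str, int]
    ci_halfwidth: float
    km_baseline_mae_margin: float | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "mae_margin": self.mae_margin,
            "c_index": self.c_index,
            "horizon_accuracies": {str(k): v for k, v in self.horizon_accuracies.items()},
            "n_used": self.n_used,
            "ci_halfwidth": self.ci_halfwidth,
            "km_baseline_mae_margin": self.km_baseline_mae_margin,
            "extra": self.extra,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def margin_time(train_km: SurvivalCurve, c: float) -> float:
    """Imputed event time for a patient censored at ``c``.

    The conditional mean of the training Kaplan-Meier curve beyond ``c``;
    always >= c.  If the curve assigns zero survival to ``c`` the margin
    time is undefined and we fall back to ``c`` itself (the censoring time
    is still a valid lower bound).
    """
    try:
        return conditional_mean_beyond(train_km, c)
    except ZeroSurvivalError:
        return float(c)


def _check_alignment(preds: list[Prediction], y: CensoredSample) -> None:
    if len(preds) != len(y):
        raise ValueError(f"{len(preds)} predictions but {len(y)} observations")


def best_guess_times(y: CensoredSample, train_km: SurvivalCurve) -> np.ndarray:
    """Observed time for events; margin time for censored patients."""
    out = y.times.astype(float).copy()
    for i in np.nonzero(y.events == 0)[0]:
        out[i] = margin_time(train_km, y.times[i])
    return out


def mae_margin(preds: list[Prediction], y: CensoredSample, train_km: SurvivalCurve) -> float:
    """Unweighted mean of |predicted time - (event or margin) time| in months.

    ``train_km`` must be fit on training data only: the margin time is part
    of the ground truth being compared against and must not see test
    outcomes.  With no censored patients this reduces exactly to plain MAE.
    """
    _check_alignment(preds, y)
    truth = best_guess_times(y, train_km)
    pred = np.array([p.predicted_time for p in preds], dtype=float)
    return float(np.mean(np.abs(pred - truth)))


def per_patient_abs_errors(
    preds: list[Prediction], y: CensoredSample, train_km: SurvivalCurve
) -> np.ndarray:
    _check_alignment(preds, y)
    truth = best_guess_times(y, train_km)
    pred = np.array([p.predicted_time for p in preds], dtype=float)
    return np.abs(pred - truth)


def c_index(preds: list[Prediction], y: CensoredSample) -> float:
    """Harrell's concordance index over predicted event times.

    A pair (i, j) is comparable when patient i's event was observed and
    t_i < t_j; it is concordant when the model predicts an earlier time for
    i.  Ties in predicted time count 1/2.
    """
    _check_alignment(preds, y)
    pred = np.array([p.predicted_time for p in preds], dtype=float)
    t, e = y.times, y.events
    concordant = 0.0
    comparable = 0
    for i in np.nonzero(e == 1)[0]:
        mask = t > t[i]
        comparable += int(mask.sum())
        concordant += float(np.sum(pred[i] < pred[mask])) + 0.5 * float(
            np.sum(pred[i] == pred[mask])
        )
    if comparable == 0:
        raise ValueError("no comparable pairs: cannot compute concordance")
    return concordant / comparable


def horizon_accuracy(preds: list[Prediction], y: CensoredSample, horizon: float) -> float:
    """Accuracy of 'survives past the horizon' classification.

    Patients censored before the horizon are excluded (their status at the
    horizon is unknown).  The model predicts survival when the predicted
    curve gives S(horizon) >= 0.5, consistent with the median-based point
    prediction.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    _check_alignment(preds, y)
    keep = ~((y.events == 0) & (y.times < horizon))
    if not keep.any():
        raise ValueError("all patients censored before the horizon")
    observed = y.times >= horizon
    predicted = np.array(
        [survival_at(p.curve, horizon) >= 0.5 for p in preds], dtype=bool
    )
    return float(np.mean(observed[keep] == predicted[keep]))


def horizon_n_used(y: CensoredSample, horizon: float) -> int:
    return int(np.sum(~((y.events == 0) & (y.times < horizon))))


def bootstrap_ci(
    per_patient_abs_errors: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> float:
    """Half-width of the percentile 95% bootstrap interval for the mean error."""
    errors = np.asarray(per_patient_abs_errors, dtype=float)
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if errors.size < 2:
        raise ValueError("need at least 2 errors to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, errors.size, size=(n_boot, errors.size))
    means = errors[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float((hi - lo) / 2.0)


def errors_to_csv(preds: list[Prediction], y: CensoredSample, train_km: SurvivalCurve, path) -> None:
    truth = best_guess_times(y, train_km)
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in preds],
            "observed_time": y.times,
            "event": y.events,
            "best_guess_time": truth,
            "predicted_time": [p.predicted_time for p in preds],
        }
    )
    df["abs_error"] = (df["predicted_time"] - df["best_guess_time"]).abs()
    df.to_csv(path, index=False)
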