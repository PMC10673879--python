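"""Cox proportional hazards with a Kalbfleisch-Prentice baseline.

Coefficients maximize the Breslow-tie partial likelihood by damped Newton
iterations; the baseline survival S0 is then the Kalbfleisch-Prentice
product estimator: at each distinct event time the survival factor alpha
solves sum_{i in D} w_i / (1 - alpha^{w_i}) = sum_{j in R} w_j with
w = exp(eta) (closed form for an untied event).  With all coefficients at
zero this reduces exactly to the Kaplan-Meier product-limit estimator.

Predictions are S(t | x) = S0(t)^{exp(beta . z)} where z is the feature
vector standardized with training statistics, so the baseline corresponds
to a patient at the training mean.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from ..curves import CensoredSample, SurvivalCurve
from .base import ConvergenceError, FeatureMatrix, ISDModel, Standardizer, _as_matrix

__all__ = ["CoxKPModel", "cox_newton"]

_BETA_BOUND = 20.0  # |beta|_inf beyond this on z-scored features indicates separation


def _partial_loglik_parts(X: np.ndarray, times: np.ndarray, events: np.ndarray, beta: np.ndarray):
    """Breslow log partial likelihood, gradient and Hessian (unpenalized)."""
    order = np.argsort(times, kind="stable")
    X = X[order]
    t = times[order]
    e = events[order]
    n, d = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    # suffix sums over the risk sets (risk set at time t = all with t_i >= t)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(d)
    hess = np.zeros((d, d))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dk = int(e[i:j].sum())
        if dk > 0:
            ev = np.arange(i, j)[e[i:j] == 1]
            xbar = s1[i] / s0[i]
            ll += float(eta[ev].sum()) - dk * np.log(s0[i])
            grad += X[ev].sum(axis=0) - dk * xbar
            hess -= dk * (s2[i] / s0[i] - np.outer(xbar, xbar))
        i = j
    return ll, grad, hess


def cox_newton(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-10,
):
    """Maximize the (optionally ridge-penalized) Breslow partial likelihood.

    Returns ``(beta, hessian_penalized, n_iter)``.  Raises
    :class:`ConvergenceError` on non-convergence or apparent separation.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    beta = np.zeros(d)
    if d == 0:
        return beta, np.zeros((0, 0)), 0
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        ll, grad, hess = _partial_loglik_parts(X, times, events, beta)
        ll_pen = ll - 0.5 * ridge * beta @ beta
        grad_pen = grad - ridge * beta
        hess_pen = hess - ridge * np.eye(d)
        try:
            step = np.linalg.solve(-hess_pen, grad_pen)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(-hess_pen) @ grad_pen
        # damped Newton: halve until the penalized objective does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_c, _, _ = _partial_loglik_parts(X, times, events, cand)
            if ll_c - 0.5 * ridge * cand @ cand >= ll_pen - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(beta)) > _BETA_BOUND:
            raise ConvergenceError("coefficients diverging: likely separation")
        if np.linalg.norm(scale * step) < tol or abs(ll_pen - ll_old) < 1e-12:
            _, _, hess = _partial_loglik_parts(X, times, events, beta)
            return beta, hess - ridge * np.eye(d), it
        ll_old = ll_pen
    raise ConvergenceError(f"Cox Newton did not converge in {max_iter} iterations")


def _kp_baseline(times: np.ndarray, events: np.ndarray, eta: np.ndarray) -> SurvivalCurve:
    """Kalbfleisch-Prentice baseline survival given linear predictors eta."""
    w = np.exp(np.clip(eta, -500, 500))
    event_times = np.unique(times[events == 1])
    alphas = []
    for tk in event_times:
        at_risk = times >= tk
        dead = (times == tk) & (events == 1)
        s0 = float(w[at_risk].sum())
        wd = w[dead]
        if wd.size == 1:
            frac = 1.0 - float(wd[0]) / s0
            alpha = frac ** (1.0 / float(wd[0])) if frac > 0 else 0.0
        else:
            rest = s0
            if float(wd.sum()) >= rest - 1e-12 and np.count_nonzero(at_risk) == wd.size:
                alpha = 0.0
            else:
                def f(a):
                    return float(np.sum(wd / (1.0 - a ** wd))) - rest

                lo, hi = 1e-12, 1.0 - 1e-12
                if f(hi) < 0:  # numerically everyone dies
                    alpha = 0.0
                else:
                    alpha = brentq(f, lo, hi, xtol=1e-12)
        alphas.append(alpha)
    surv = np.cumprod(alphas)
    knots = np.concatenate(([0.0], event_times))
    vals = np.concatenate(([1.0], surv))
    t_max = float(times.max())
    if event_times.size == 0 or t_max > event_times[-1]:
        # pin the flat stretch out to the last observation (censoring past
        # the final event), matching the Kaplan-Meier knot convention
        knots = np.append(knots, t_max)
        vals = np.append(vals, vals[-1])
    return SurvivalCurve(knots, vals, interpolation="step")


class CoxKPModel(ISDModel):
    """Cox regression paired with the Kalbfleisch-Prentice baseline estimator."""

    def __init__(self, ridge: float = 0.0, standardize: bool = True):
        self.ridge = ridge
        self.standardize = standardize
        self.beta_: np.ndarray | None = None
        self.baseline_: SurvivalCurve | None = None
        self.scaler_: Standardizer | None = None
        self.n_iter_: int | None = None

    def fit(self, X: FeatureMatrix, y: CensoredSample) -> "CoxKPModel":
        if y.n_events == 0:
            raise ValueError("need at least one event to fit a Cox model")
        Xv = _as_matrix(X)
        self.scaler_ = Standardizer().fit(Xv if self.standardize else np.zeros_like(Xv))
        Z = self.scaler_.transform(Xv) if self.standardize else Xv
        if not self.standardize:
            self.scaler_ = None
        self.beta_, _, self.n_iter_ = cox_newton(Z, y.times, y.events, ridge=self.ridge)
        eta = Z @ self.beta_
        self.baseline_ = _kp_baseline(y.times, y.events, eta)
        return self

    def predict_curves(self, X) -> list[SurvivalCurve]:
        if self.beta_ is None:
            raise RuntimeError("model not fitted")
        Xv = _as_matrix(X)
        if Xv.shape[1] != self.beta_.size:
            raise ValueError(f"expected {self.beta_.size} features, got {Xv.shape[1]}")
        Z = self.scaler_.transform(Xv) if self.scaler_ is not None else Xv
        risks = np.exp(np.clip(Z @ self.beta_, -500, 500))
        kt, ks = self.baseline_.knot_times, self.baseline_.knot_survival
        return [
            SurvivalCurve(kt, np.power(ks, r), interpolation="step") for r in risks
        ]

    def to_dict(self) -> dict:
        return {
            "ridge": self.ridge,
            "standardize": self.standardize,
            "beta": self.beta_.tolist(),
            "baseline_times": self.baseline_.knot_times.tolist(),
            "baseline_survival": self.baseline_.knot_survival.tolist(),
            "scaler": self.scaler_.to_dict() if self.scaler_ is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoxKPModel":
        m = cls(ridge=d["ridge"], standardize=d["standardize"])
        m.beta_ = np.asarray(d["beta"], dtype=float)
        m.baseline_ = SurvivalCurve(
            np.asarray(d["baseline_times"]), np.asarray(d["baseline_survival"]), "step"
        )
        m.scaler_ = Standardizer.from_dict(d["scaler"]) if d["scaler"] else None
        return m
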