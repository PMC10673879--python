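"""Multi-task logistic regression (MTLR) for individual survival distributions.

MTLR discretizes time into m+1 intervals by edges t_1 < ... < t_m and
models a distribution over the m+1 monotone binary label sequences
(y_1, ..., y_m), y_j = 1 meaning the event has occurred by t_j.  The
sequence with the event in interval k (intervals are (t_{k-1}, t_k], with
t_0 = 0 and t_{m+1} = inf) has unnormalized log-score

    s_k(x) = sum_{j >= k} (theta_j . x + b_j),      s_{m+1}(x) = 0,

and probability softmax(s)(k).  An uncensored patient contributes the
log-probability of their event interval; a patient censored at c
contributes the log of the summed probabilities of every sequence whose
event interval starts at or after the last grid edge <= c (the sequences
consistent with survival past c).  The objective -- log-likelihood minus
(C/2)||theta||^2 -- is smooth and concave; we minimize its negation with
L-BFGS using an analytic gradient.

The predicted survival curve evaluates S(t_j | x) = P(event interval > j)
at the grid edges and interpolates linearly between them, which keeps the
median well defined on coarse grids.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from ..curves import CensoredSample, SurvivalCurve
from .base import ConvergenceError, FeatureMatrix, ISDModel, Standardizer, TimeGrid, _as_matrix

__all__ = ["MTLRModel"]


def _sequence_scores(G: np.ndarray) -> np.ndarray:
    """(n, m+1) log-scores: s_k = sum_{j>=k} g_j for k=1..m, plus s_{m+1}=0."""
    rev = np.cumsum(G[:, ::-1], axis=1)[:, ::-1]
    return np.concatenate([rev, np.zeros((G.shape[0], 1))], axis=1)


def _event_interval(times: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """0-based interval index k such that t in (edge_{k-1}, edge_k]; m for t > edge_m."""
    return np.searchsorted(edges, times, side="left")


def _censor_first_interval(times: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """0-based first sequence index consistent with survival past a censoring time."""
    return np.searchsorted(edges, times, side="right")


def _neg_log_posterior(params, X, kidx, cmask, l2_const, m, d):
    theta = params[: m * d].reshape(m, d)
    bias = params[m * d :]
    G = X @ theta.T + bias  # (n, m)
    S = _sequence_scores(G)  # (n, m+1)
    logZ = logsumexp(S, axis=1)
    n = X.shape[0]
    ll_num = np.empty(n)
    post = np.zeros((n, m + 1))  # posterior over sequences given the observation
    unc = ~cmask
    if unc.any():
        ll_num[unc] = S[unc, kidx[unc]]
        post[unc, kidx[unc]] = 1.0
    if cmask.any():
        # masked logsumexp/softmax over the sequences consistent with censoring
        allowed = np.arange(m + 1)[None, :] >= kidx[cmask, None]
        Sc = np.where(allowed, S[cmask], -np.inf)
        lse = logsumexp(Sc, axis=1)
        ll_num[cmask] = lse
        post[cmask] = np.exp(Sc - lse[:, None])
    prior = softmax(S, axis=1)
    nll = -float(np.sum(ll_num - logZ))
    # d nll / d g_j = -(sum_{k<=j} post_k - sum_{k<=j} prior_k)  [k, j 0-based: k <= j]
    diff = np.cumsum(post - prior, axis=1)[:, :m]
    grad_G = -diff
    # ridge covers the biases as well: the quantile-placed grid makes the
    # uniform sequence distribution the natural fully-regularized limit
    grad_theta = grad_G.T @ X + l2_const * theta
    grad_b = grad_G.sum(axis=0) + l2_const * bias
    obj = nll + 0.5 * l2_const * (float(np.sum(theta * theta)) + float(bias @ bias))
    return obj, np.concatenate([grad_theta.ravel(), grad_b])


class MTLRModel(ISDModel):
    """MTLR with an L2 (ridge) penalty on the coefficient matrix.

    Parameters
    ----------
    l2_const:
        Ridge strength C >= 0 on all parameters (coefficients and biases);
        the single constant the SuperLearner tunes.  At very large C the
        model collapses to the uniform distribution over the m+1 monotone
        sequences.
    grid:
        Optional fixed :class:`TimeGrid`; by default m = ceil(sqrt(#events))
        edges at empirical quantiles of the uncensored event times.
    """

    def __init__(
        self,
        l2_const: float = 1.0,
        grid: TimeGrid | None = None,
        standardize: bool = True,
        max_iter: int = 500,
        tol: float = 1e-8,
    ):
        if l2_const < 0:
            raise ValueError("l2_const must be non-negative")
        self.l2_const = l2_const
        self.grid = grid
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol
        self.theta_: np.ndarray | None = None
        self.bias_: np.ndarray | None = None
        self.scaler_: Standardizer | None = None
        self.objective_path_: list[float] = []

    def fit(self, X: FeatureMatrix, y: CensoredSample) -> "MTLRModel":
        Xv = _as_matrix(X)
        if self.standardize:
            self.scaler_ = Standardizer().fit(Xv)
            Z = self.scaler_.transform(Xv)
        else:
            self.scaler_ = None
            Z = Xv
        grid = self.grid if self.grid is not None else TimeGrid.from_sample(y)
        edges = grid.bin_edges
        m, d = edges.size, Z.shape[1]
        kidx = np.where(
            y.events == 1,
            _event_interval(y.times, edges),
            _censor_first_interval(y.times, edges),
        )
        cmask = y.events == 0
        x0 = np.zeros(m * d + m)
        self.objective_path_ = []

        def fun(p):
            obj, g = _neg_log_posterior(p, Z, kidx, cmask, self.l2_const, m, d)
            return obj, g

        def cb(p):
            self.objective_path_.append(
                _neg_log_posterior(p, Z, kidx, cmask, self.l2_const, m, d)[0]
            )

        res = minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-8},
        )
        if not np.isfinite(res.fun):
            raise ConvergenceError("MTLR objective is non-finite")
        if not res.success and res.status != 1:  # status 1 = maxiter (tolerated below)
            raise ConvergenceError(f"MTLR optimizer failed: {res.message} (nit={res.nit})")
        if res.status == 1:
            raise ConvergenceError(
                f"MTLR did not converge within {self.max_iter} iterations "
                f"(final objective {res.fun:.6g})"
            )
        self.theta_ = res.x[: m * d].reshape(m, d)
        self.bias_ = res.x[m * d :]
        self.fitted_grid_ = grid
        return self

    def predict_curves(self, X) -> list[SurvivalCurve]:
        if self.theta_ is None:
            raise RuntimeError("model not fitted")
        Xv = _as_matrix(X)
        if Xv.shape[1] != self.theta_.shape[1]:
            raise ValueError(
                f"expected {self.theta_.shape[1]} features, got {Xv.shape[1]}"
            )
        Z = self.scaler_.transform(Xv) if self.scaler_ is not None else Xv
        probs = self.predict_sequence_probs(Z, raw=True)
        edges = self.fitted_grid_.bin_edges
        # S(t_j) = P(event interval index > j) for edges j = 1..m (1-based)
        surv = 1.0 - np.cumsum(probs[:, :-1], axis=1)
        knots = np.concatenate(([0.0], edges))
        out = []
        for row in surv:
            vals = np.concatenate(([1.0], np.clip(row, 0.0, 1.0)))
            vals = np.minimum.accumulate(vals)
            out.append(SurvivalCurve(knots, vals, interpolation="linear"))
        return out

    def predict_sequence_probs(self, X, raw: bool = False) -> np.ndarray:
        """(n, m+1) probabilities over the monotone label sequences."""
        Z = X if raw else (self.scaler_.transform(_as_matrix(X)) if self.scaler_ else _as_matrix(X))
        G = Z @ self.theta_.T + self.bias_
        return softmax(_sequence_scores(G), axis=1)

    def to_dict(self) -> dict:
        return {
            "l2_const": self.l2_const,
            "standardize": self.standardize,
            "theta": self.theta_.tolist(),
            "bias": self.bias_.tolist(),
            "edges": self.fitted_grid_.bin_edges.tolist(),
            "scaler": self.scaler_.to_dict() if self.scaler_ else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MTLRModel":
        m = cls(l2_const=d["l2_const"], standardize=d["standardize"])
        m.theta_ = np.asarray(d["theta"], dtype=float)
        m.bias_ = np.asarray(d["bias"], dtype=float)
        m.fitted_grid_ = TimeGrid(np.asarray(d["edges"], dtype=float))
        m.scaler_ = Standardizer.from_dict(d["scaler"]) if d["scaler"] else None
        return m
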