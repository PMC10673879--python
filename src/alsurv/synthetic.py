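"""Synthetic ALS-like cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a cohort of 172 patients carrying 114 clinical and 68
cortical-thickness features, event times from an accelerated failure time
model, and ~45% independent right-censoring that includes a MAID-like
component (a random subset of censored patients whose follow-up ends at a
MAID date).  By default the prognostic signal lives entirely in the
clinical block and the image block is pure correlated noise, matching the
regime in which model selection should prefer clinical-only feature sets.

Features have a single-factor correlation structure per block (loading
0.4), giving pairwise correlation 0.16 -- a one-parameter stand-in for the
strong inter-regional correlation of cortical thickness measurements.
Censoring times are drawn from an administrative uniform window whose
width is calibrated so the expected realized censoring fraction matches
the target; they are independent of the event times by construction.
Missingness is injected completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .preprocessing import DAYS_PER_MONTH, CohortTable
from .models.base import CLINICAL, IMAGE

__all__ = ["SimConfig", "SimulatedCohort", "simulate_cohort"]


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 172
    n_clinical: int = 114
    n_image: int = 68
    n_informative_clinical: int = 10
    n_informative_image: int = 0
    coef_value: float = 0.2  # alternating-sign AFT log-time coefficients
    family: str = "lognormal_aft"  # or "weibull_aft"
    baseline_log_time: float = float(np.log(30.0))  # median ~30 months
    sigma: float = 0.6
    block_loading: float = 0.4
    target_censor_rate: float = 0.45
    maid_fraction: float = 0.10  # of censored patients
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_censor_rate", "maid_fraction", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_informative_clinical > self.n_clinical:
            raise ValueError("n_informative_clinical exceeds n_clinical")
        if self.n_informative_image > self.n_image:
            raise ValueError("n_informative_image exceeds n_image")
        if self.family not in ("lognormal_aft", "weibull_aft"):
            raise ValueError("family must be 'lognormal_aft' or 'weibull_aft'")


@dataclass(frozen=True)
class SimulatedCohort:
    raw: pd.DataFrame  # the visit-level CSV dialect preprocessing reads
    cohort: CohortTable  # exact times, bypassing date rounding
    truth: dict

    def write(self, raw_path, truth_path=None) -> None:
        self.raw.to_csv(raw_path, index=False)
        if truth_path is not None:
            import json

            with open(truth_path, "w") as fh:
                json.dump(
                    {
                        k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in self.truth.items()
                    },
                    fh,
                    indent=2,
                )


def _block(rng, n, d, loading) -> np.ndarray:
    f = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, d))
    return loading * f + np.sqrt(1.0 - loading**2) * eps


def _alternating_coefs(d, n_informative, value) -> np.ndarray:
    beta = np.zeros(d)
    signs = np.where(np.arange(n_informative) % 2 == 0, 1.0, -1.0)
    beta[:n_informative] = value * signs
    return beta


def _calibrate_window(latent_times: np.ndarray, target: float) -> float:
    """Width tau of the U(0, tau) censoring window matching the target rate.

    With C ~ U(0, tau) independent of T, P(censored | T) = min(T, tau)/tau;
    the expectation over the drawn latent times is monotone decreasing in
    tau, so the calibration is a scalar root-find.
    """
    if not (0.0 < target < 1.0):
        raise ValueError(f"target censor rate {target} is infeasible for a uniform window")

    def realized(tau):
        return float(np.mean(np.minimum(latent_times, tau) / tau)) - target

    lo, hi = 1e-9, 50.0 * float(latent_times.max())
    if realized(hi) > 0:
        raise ValueError("target censor rate infeasible: even the widest window censors more")
    return brentq(realized, lo, hi, xtol=1e-9)


def simulate_cohort(config: SimConfig = SimConfig()) -> SimulatedCohort:
    """Draw one cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    Xc = _block(rng, n, config.n_clinical, config.block_loading)
    Xi = _block(rng, n, config.n_image, config.block_loading)
    beta_c = _alternating_coefs(config.n_clinical, config.n_informative_clinical, config.coef_value)
    beta_i = _alternating_coefs(config.n_image, config.n_informative_image, config.coef_value)
    lin = config.baseline_log_time + Xc @ beta_c + Xi @ beta_i
    if config.family == "lognormal_aft":
        log_t = lin + config.sigma * rng.standard_normal(n)
    else:
        log_t = lin + config.sigma * np.log(rng.exponential(size=n))
    latent_event = np.exp(log_t)
    tau = _calibrate_window(latent_event, config.target_censor_rate)
    latent_censor = rng.uniform(0.0, tau, size=n)
    events = (latent_event <= latent_censor).astype(int)
    times = np.minimum(latent_event, latent_censor)
    censored_idx = np.nonzero(events == 0)[0]
    n_maid = int(round(config.maid_fraction * censored_idx.size))
    maid_idx = rng.choice(censored_idx, size=n_maid, replace=False) if n_maid else np.array([], int)
    maid_mask = np.zeros(n, dtype=bool)
    maid_mask[maid_idx] = True

    clin_names = [f"clin_{j:03d}" for j in range(config.n_clinical)]
    img_names = [f"img_{j:03d}" for j in range(config.n_image)]
    feats = pd.DataFrame(np.hstack([Xc, Xi]), columns=clin_names + img_names)
    if config.missing_rate > 0:
        mask = rng.uniform(size=feats.shape) < config.missing_rate
        feats = feats.mask(pd.DataFrame(mask, columns=feats.columns))

    recruitment = pd.Timestamp("2018-01-01") + pd.to_timedelta(
        rng.integers(0, 365, size=n), unit="D"
    )
    offset = pd.to_timedelta(np.round(times * DAYS_PER_MONTH).astype(int), unit="D")
    raw = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "recruitment_date": recruitment.strftime("%Y-%m-%d"),
            "last_contact_date": (recruitment + offset).strftime("%Y-%m-%d"),
            "event_date": pd.Series(
                np.where(events == 1, (recruitment + offset).strftime("%Y-%m-%d"), None)
            ),
            "maid_date": pd.Series(
                np.where(maid_mask, (recruitment + offset).strftime("%Y-%m-%d"), None)
            ),
        }
    )
    raw = pd.concat([raw, feats], axis=1)

    blocks = {c: CLINICAL for c in clin_names} | {c: IMAGE for c in img_names}
    cohort = CohortTable(
        tuple(raw["patient_id"]),
        times,
        events,
        feats,
        blocks,
    )
    truth = {
        "beta_clinical": beta_c,
        "beta_image": beta_i,
        "intercept": config.baseline_log_time,
        "sigma": config.sigma,
        "family": config.family,
        "censor_window": tau,
        "latent_event_times": latent_event,
        "latent_censor_times": latent_censor,
        "maid_ids": [f"P{i:04d}" for i in maid_idx],
        "realized_censor_rate": float(1.0 - events.mean()),
        "seed": config.seed,
    }
    return SimulatedCohort(raw=raw, cohort=cohort, truth=truth)
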