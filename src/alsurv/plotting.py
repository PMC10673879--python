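"""Survival-curve figures: per-patient ISDs with a cohort Kaplan-Meier overlay."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .curves import SurvivalCurve, survival_at

__all__ = ["plot_survival_curves"]


def _dense(curve: SurvivalCurve, t_max: float, n: int = 400):
    ts = np.linspace(0.0, t_max, n)
    return ts, np.array([survival_at(curve, t) for t in ts])


def plot_survival_curves(
    curves: dict[str, SurvivalCurve],
    km: SurvivalCurve | None = None,
    path=None,
    title: str = "Predicted individual survival distributions",
):
    """Plot patient ISDs (and optionally the cohort KM) and save to ``path``."""
    t_max = max(float(c.knot_times[-1]) for c in curves.values())
    if km is not None:
        t_max = max(t_max, float(km.knot_times[-1]))
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for pid, curve in curves.items():
        ts, ss = _dense(curve, t_max)
        ax.plot(ts, ss, label=str(pid), lw=1.5)
    if km is not None:
        ts, ss = _dense(km, t_max)
        ax.plot(ts, ss, color="black", ls="--", lw=2, label="Kaplan-Meier (cohort)")
    ax.axhline(0.5, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("months since recruitment")
    ax.set_ylabel("survival probability S(t)")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
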