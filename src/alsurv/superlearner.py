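"""Model selection over (algorithm x feature-selection x feature-set) pipelines.

The SuperLearner enumerates a 4 x 2 x 3 = 24-cell grid -- four base ISD
algorithms (AFT, Cox-KP, MTLR, RSF), Cox feature selection on or off, and
three feature sets (clinical, image, both) -- scores every cell by mean
MAE-margin under internal stratified 5-fold cross-validation of the
training data, tunes MTLR's L2 constant in the same inner loop, and refits
the single winning pipeline on the full training set.  It selects one
winner; it does not blend.

External (nested) stratified 5-fold cross-validation wraps the whole
procedure for honest performance reporting: every training-side statistic
-- imputation means, feature scaling, selected features, and the
Kaplan-Meier curve used for margin times -- is a function of the training
side of its split only.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .curves import CensoredSample, SurvivalCurve, km_fit, median_survival_time
from .evaluation import (
    EvaluationReport,
    Prediction,
    bootstrap_ci,
    c_index,
    horizon_accuracy,
    mae_margin,
    per_patient_abs_errors,
)
from .feature_selection import cox_select
from .models import AFTModel, ConvergenceError, CoxKPModel, MTLRModel, RSFModel
from .preprocessing import CohortTable

logger = logging.getLogger("alsurv.superlearner")

__all__ = [
    "HyperCombo",
    "SelectionReport",
    "FinalModel",
    "enumerate_grid",
    "stratified_folds",
    "internal_select",
    "fit_final",
    "external_cv_evaluate",
]

ALGORITHMS = ("aft", "cox_kp", "mtlr", "rsf")
FEATURE_SELECTIONS = ("cox", "none")
FEATURE_SETS = ("clinical", "image", "both")
DEFAULT_MTLR_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_HORIZONS = (12.0, 24.0, 36.0)

# fixed tie-break precedence: simpler pipelines first
_ALG_ORDER = {"cox_kp": 0, "aft": 1, "mtlr": 2, "rsf": 3}
_FS_ORDER = {"none": 0, "cox": 1}
_SET_ORDER = {"clinical": 0, "image": 1, "both": 2}


@dataclass(frozen=True)
class HyperCombo:
    algorithm: str
    feature_selection: str
    feature_set: str
    params: tuple = ()  # sorted (key, value) pairs; hashable

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.feature_selection not in FEATURE_SELECTIONS:
            raise ValueError(f"unknown feature_selection {self.feature_selection!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        object.__setattr__(self, "params", tuple(sorted(self.params)))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def with_params(self, **kw) -> "HyperCombo":
        merged = {**self.param_dict, **kw}
        return replace(self, params=tuple(sorted(merged.items())))

    def label(self) -> str:
        return f"{self.algorithm}/{self.feature_selection}/{self.feature_set}"

    def sort_key(self):
        return (
            _ALG_ORDER[self.algorithm],
            _FS_ORDER[self.feature_selection],
            _SET_ORDER[self.feature_set],
        )


def enumerate_grid(
    mtlr_c_grid=DEFAULT_MTLR_C_GRID,
    algorithms=ALGORITHMS,
    feature_selections=FEATURE_SELECTIONS,
    feature_sets=FEATURE_SETS,
    algorithm_params: dict | None = None,
) -> list[HyperCombo]:
    """The Cartesian hyperparameter grid; 24 cells with the default axes."""
    algorithm_params = algorithm_params or {}
    grid = []
    for alg in algorithms:
        params = dict(algorithm_params.get(alg, {}))
        if alg == "mtlr":
            params.setdefault("c_grid", tuple(mtlr_c_grid))
        for fs in feature_selections:
            for fset in feature_sets:
                grid.append(
                    HyperCombo(alg, fs, fset, params=tuple(params.items()))
                )
    return grid


def stratified_folds(y: CensoredSample, k: int, seed: int) -> np.ndarray:
    """Fold labels stratified by the event indicator; sizes differ by <= 1 per stratum."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y.events, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each stratum needs >= {k} members, got events={counts[1]}, censored={counts[0]}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y.events)):
        folds[test_idx] = f
    return folds


def _derive_seed(seed: int, *salts: int) -> int:
    out = int(seed) & 0x7FFFFFFF
    for s in salts:
        out = (out * 1_000_003 + int(s) + 1) & 0x7FFFFFFF
    return out


def _make_model(combo: HyperCombo, seed: int):
    p = combo.param_dict
    if combo.algorithm == "aft":
        return AFTModel(family=p.get("family", "lognormal"), penalizer=p.get("penalizer", 0.0))
    if combo.algorithm == "cox_kp":
        return CoxKPModel(ridge=p.get("ridge", 0.0))
    if combo.algorithm == "mtlr":
        return MTLRModel(l2_const=p.get("l2_const", 1.0))
    if combo.algorithm == "rsf":
        return RSFModel(
            n_trees=p.get("n_trees", 100),
            mtry=p.get("mtry"),
            min_leaf_events=p.get("min_leaf_events", 3),
            seed=seed,
        )
    raise ValueError(combo.algorithm)


@dataclass
class FittedPipeline:
    """One fitted (feature-set, imputer, selection, model) chain."""

    combo: HyperCombo
    feature_names: list[str]  # after block restriction, order fixed at fit time
    impute_means: pd.Series
    selected_names: list[str]
    model: object

    def _prepare(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].copy()
        X = X.fillna(self.impute_means)
        return X[self.selected_names].to_numpy(dtype=float)

    def predict_curves(self, features: pd.DataFrame) -> list[SurvivalCurve]:
        return self.model.predict_curves(self._prepare(features))

    def predictions(self, cohort: CohortTable) -> list[Prediction]:
        curves = self.predict_curves(cohort.features)
        return [Prediction(pid, c) for pid, c in zip(cohort.patient_ids, curves)]


def _fit_pipeline(
    train: CohortTable, combo: HyperCombo, seed: int, alpha: float = 0.05
) -> FittedPipeline:
    sub = train.restrict_block(combo.feature_set)
    feature_names = list(sub.features.columns)
    impute_means = sub.features.mean()
    feats = sub.features.fillna(impute_means)
    imputed = CohortTable(sub.patient_ids, sub.times, sub.events, feats, sub.blocks)
    if combo.feature_selection == "cox":
        subset = cox_select(imputed.feature_matrix(), imputed.sample, alpha=alpha)
        selected = list(subset.selected_names)
    else:
        selected = feature_names
    model = _make_model(combo, seed)
    model.fit(
        imputed.restrict_features(selected).feature_matrix(), imputed.sample
    )
    return FittedPipeline(combo, feature_names, impute_means, selected, model)


@dataclass
class SelectionReport:
    results: pd.DataFrame  # combo label, mean/sd MAE-margin, chosen params
    winner: HyperCombo
    fold_assignments: np.ndarray
    seed: int
    failed: list[tuple[str, str]] = field(default_factory=list)


class _FoldPrep:
    """Cache of per-(fold, feature-set, selection) prepared data.

    Imputation means, Cox feature selection and the training Kaplan-Meier
    curve do not depend on the algorithm axis of the grid, so they are
    computed once per inner fold and shared across the four algorithms.
    All cached statistics are functions of the inner-training rows only.
    """

    def __init__(self, train: CohortTable, folds: np.ndarray, k: int, alpha: float):
        self.train = train
        self.folds = folds
        self.k = k
        self.alpha = alpha
        self._cache: dict[tuple, tuple] = {}

    def get(self, f: int, feature_set: str, feature_selection: str):
        key = (f, feature_set, feature_selection)
        if key not in self._cache:
            tr = self.train.subset_rows(self.folds != f)
            te = self.train.subset_rows(self.folds == f)
            sub = tr.restrict_block(feature_set)
            means = sub.features.mean()
            imputed = CohortTable(
                sub.patient_ids, sub.times, sub.events,
                sub.features.fillna(means), sub.blocks,
            )
            if feature_selection == "cox":
                subset = cox_select(imputed.feature_matrix(), imputed.sample, alpha=self.alpha)
                selected = list(subset.selected_names)
            else:
                selected = list(sub.features.columns)
            X_tr = imputed.restrict_features(selected).feature_matrix()
            X_te = (
                te.features[list(sub.features.columns)]
                .fillna(means)[selected]
                .to_numpy(dtype=float)
            )
            self._cache[key] = (X_tr, imputed.sample, X_te, te, km_fit(tr.sample))
        return self._cache[key]


def _score_combo_folds(prep: _FoldPrep, combo: HyperCombo, seed: int):
    """Mean/sd internal MAE-margin of one fully specified combo."""
    maes = []
    for f in range(prep.k):
        X_tr, y_tr, X_te, te, train_km = prep.get(f, combo.feature_set, combo.feature_selection)
        fit_seed = _derive_seed(seed, zlib.crc32(combo.label().encode()) & 0xFFFF, f)
        model = _make_model(combo, fit_seed)
        model.fit(X_tr, y_tr)
        curves = model.predict_curves(X_te)
        preds = [Prediction(pid, c) for pid, c in zip(te.patient_ids, curves)]
        maes.append(mae_margin(preds, te.sample, train_km))
    return float(np.mean(maes)), float(np.std(maes))


def internal_select(
    train: CohortTable,
    grid: list[HyperCombo],
    k: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
) -> SelectionReport:
    """Score every grid cell by internal k-fold CV MAE-margin and pick the minimum.

    MTLR cells are scored once per value of their L2-constant grid and
    keep the best (largest on ties, i.e. the most regularized).  Cells
    whose pipeline raises a model error on any fold are excluded from the
    competition and logged.
    """
    folds = stratified_folds(train.sample, k, seed)
    prep = _FoldPrep(train, folds, k, alpha)
    rows = []
    failed: list[tuple[str, str]] = []
    for combo in grid:
        candidates: list[HyperCombo]
        if combo.algorithm == "mtlr":
            c_grid = combo.param_dict.get("c_grid", DEFAULT_MTLR_C_GRID)
            candidates = [
                combo.with_params(l2_const=float(c), c_grid=None) for c in c_grid
            ]
        else:
            candidates = [combo]
        best = None
        err_msg = None
        for cand in candidates:
            try:
                mean, sd = _score_combo_folds(prep, cand, seed)
            except (ConvergenceError, ValueError, np.linalg.LinAlgError) as err:
                err_msg = str(err)
                continue
            key = (mean, -cand.param_dict.get("l2_const", 0.0))
            if best is None or key < best[0]:
                best = (key, cand, mean, sd)
        if best is None:
            failed.append((combo.label(), err_msg or "unknown"))
            logger.warning("combo %s failed on all candidates: %s", combo.label(), err_msg)
            continue
        _, cand, mean, sd = best
        rows.append(
            {
                "combo": combo.label(),
                "algorithm": combo.algorithm,
                "feature_selection": combo.feature_selection,
                "feature_set": combo.feature_set,
                "mean_mae_margin": mean,
                "sd_mae_margin": sd,
                "chosen": cand,
            }
        )
    if not rows:
        raise ConvergenceError("every grid combination failed internal cross-validation")
    results = pd.DataFrame(rows).sort_values("mean_mae_margin", kind="stable")
    best_mean = results["mean_mae_margin"].min()
    contenders = [
        r["chosen"] for _, r in results.iterrows() if r["mean_mae_margin"] == best_mean
    ]
    winner = min(contenders, key=lambda c: c.sort_key())
    results = results.drop(columns=["chosen"]).reset_index(drop=True)
    return SelectionReport(results, winner, folds, seed, failed)


@dataclass
class FinalModel:
    pipeline: FittedPipeline
    selection: SelectionReport
    train_km: SurvivalCurve

    def predict_curves(self, features: pd.DataFrame) -> list[SurvivalCurve]:
        return self.pipeline.predict_curves(features)

    def predictions(self, cohort: CohortTable) -> list[Prediction]:
        return self.pipeline.predictions(cohort)


def fit_final(train: CohortTable, winner: HyperCombo, seed: int = 0, alpha: float = 0.05,
              selection: SelectionReport | None = None) -> FinalModel:
    """Refit the winning pipeline on the full training set."""
    pipe = _fit_pipeline(train, winner, _derive_seed(seed, 0xF1A), alpha)
    return FinalModel(pipe, selection, km_fit(train.sample))


def external_cv_evaluate(
    cohort: CohortTable,
    grid: list[HyperCombo],
    k: int = 5,
    seed: int = 0,
    horizons=DEFAULT_HORIZONS,
    n_boot: int = 1000,
    alpha: float = 0.05,
    inner_k: int | None = None,
) -> EvaluationReport:
    """Nested cross-validation: internal selection + final refit per external fold.

    Pools per-patient predictions across test folds and reports MAE-margin
    (with a bootstrap 95% half-width), C-index, per-horizon accuracies and
    the Kaplan-Meier baseline MAE-margin computed on identical folds and
    margin times (the baseline predicts the training KM curve for every
    patient).
    """
    inner_k = inner_k or k
    folds = stratified_folds(cohort.sample, k, seed)
    pooled_preds: list[Prediction] = []
    pooled_base: list[Prediction] = []
    pooled_errors: list[np.ndarray] = []
    base_errors: list[np.ndarray] = []
    pooled_idx: list[np.ndarray] = []
    winners = []
    for f in range(k):
        tr = cohort.subset_rows(folds != f)
        te = cohort.subset_rows(folds == f)
        fold_seed = _derive_seed(seed, 0xE0, f)
        sel = internal_select(tr, grid, k=inner_k, seed=fold_seed, alpha=alpha)
        final = fit_final(tr, sel.winner, seed=fold_seed, alpha=alpha, selection=sel)
        preds = final.predictions(te)
        km = final.train_km
        km_median = median_survival_time(km)
        base = [Prediction(pid, km, predicted_time=km_median) for pid in te.patient_ids]
        pooled_preds.extend(preds)
        pooled_base.extend(base)
        pooled_errors.append(per_patient_abs_errors(preds, te.sample, km))
        base_errors.append(per_patient_abs_errors(base, te.sample, km))
        pooled_idx.append(np.nonzero(folds == f)[0])
        winners.append(sel.winner.label())

    order = np.concatenate(pooled_idx)
    y_pooled = CensoredSample(cohort.times[order], cohort.events[order])
    errors = np.concatenate(pooled_errors)
    berrors = np.concatenate(base_errors)
    accs = {}
    n_used = {"mae_margin": len(cohort), "c_index": len(cohort)}
    for h in horizons:
        try:
            accs[h] = horizon_accuracy(pooled_preds, y_pooled, h)
            n_used[f"accuracy_{h}"] = int(
                np.sum(~((y_pooled.events == 0) & (y_pooled.times < h)))
            )
        except ValueError:
            accs[h] = float("nan")
    report = EvaluationReport(
        mae_margin=float(errors.mean()),
        c_index=c_index(pooled_preds, y_pooled),
        horizon_accuracies=accs,
        n_used=n_used,
        ci_halfwidth=bootstrap_ci(errors, n_boot=n_boot, seed=_derive_seed(seed, 0xB0)),
        km_baseline_mae_margin=float(berrors.mean()),
        extra={
            "fold_winners": winners,
            "seed": seed,
            "k": k,
            "km_baseline_c_index": None,
        },
    )
    return report
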