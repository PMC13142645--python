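"""Brain-age regression: nested-CV benchmarking, refit, bias correction.

A panel of regressor families (kernel SVR, penalized linear models,
random forest, gradient-boosting ensembles) is tuned inside a nested
cross-validation — outer folds stratified by age decade with repeats,
inner folds for hyperparameter search — and summarized with MAE, RMSE,
R2 and Pearson's r (t-based and Fisher-z 95% CIs).  The winner by mean
outer MAE is refit on all reference controls, and its raw predictions
are bias-corrected for regression toward the mean age:

    corrected = (raw - a) / b,   with  raw ~ a + b * age

fitted on pooled out-of-fold predictions.  BAG = corrected - age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold, ParameterSampler, RepeatedStratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, LinearSVR

__all__ = [
    "CVSpec",
    "ModelPerformance",
    "BiasCorrection",
    "BrainAgeModel",
    "BenchmarkResult",
    "FAMILY_REGISTRY",
    "age_decade_strata",
    "nested_cv_benchmark",
    "summarize_metrics",
    "fit_bias_correction",
    "refit_final",
    "predict_brainage",
    "compute_bag",
]


@dataclass
class CVSpec:
    """Nested cross-validation layout: outer folds/repeats stratified by
    age decade, inner folds for the hyperparameter search."""

    outer_folds: int = 5
    outer_repeats: int = 5
    inner_folds: int = 3
    search_budget: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.outer_repeats < 1 or self.search_budget < 1:
            raise ValueError("repeats and search budget must be >= 1")


@dataclass
class ModelPerformance:
    model_family: str
    mae: float
    rmse: float
    r2: float
    pearson_r: float
    ci_mae: tuple[float, float]
    ci_rmse: tuple[float, float]
    ci_r2: tuple[float, float]
    ci_r: tuple[float, float]
    per_fold: pd.DataFrame = field(repr=False)


@dataclass
class BiasCorrection:
    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if abs(self.slope) < 1e-6:
            raise ValueError("bias-correction slope is numerically zero")


@dataclass
class BrainAgeModel:
    estimator: object
    family: str
    hyperparameters: dict
    bias: BiasCorrection
    feature_labels: list[str]
    training_summary: dict = field(default_factory=dict)


@dataclass
class BenchmarkResult:
    table: pd.DataFrame
    performances: dict[str, ModelPerformance]
    winner: str
    winner_params: dict
    oof: pd.DataFrame  # pooled outer-fold predictions of the winner
    fold_assignments: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)


@dataclass
class _Family:
    name: str
    factory: object
    space: dict
    scale_sensitive: bool = True


def _loguniform(lo, hi):
    return sps.loguniform(lo, hi)


def _registry() -> dict[str, _Family]:
    reg = {
        "ridge": _Family("ridge", lambda p, seed: Ridge(**p), {"alpha": _loguniform(1e-3, 1e4)}),
        "lasso": _Family("lasso", lambda p, seed: Lasso(max_iter=5000, **p),
                         {"alpha": _loguniform(1e-3, 1e2)}),
        "elastic_net": _Family(
            "elastic_net", lambda p, seed: ElasticNet(max_iter=5000, **p),
            {"alpha": _loguniform(1e-3, 1e2), "l1_ratio": sps.uniform(0.05, 0.9)},
        ),
        "svr_rbf": _Family(
            "svr_rbf", lambda p, seed: SVR(kernel="rbf", **p),
            {"C": _loguniform(1e-1, 1e3), "gamma": _loguniform(1e-4, 1e-1),
             "epsilon": sps.uniform(0.05, 2.0)},
        ),
        "linear_svr": _Family(
            "linear_svr", lambda p, seed: LinearSVR(max_iter=5000, dual="auto", **p),
            {"C": _loguniform(1e-3, 1e2), "epsilon": sps.uniform(0.05, 2.0)},
        ),
        "random_forest": _Family(
            "random_forest",
            lambda p, seed: RandomForestRegressor(random_state=seed, n_jobs=1, **p),
            {"n_estimators": sps.randint(100, 301), "max_depth": sps.randint(3, 15),
             "min_samples_leaf": sps.randint(1, 10)},
            scale_sensitive=False,
        ),
        "linear": _Family("linear", lambda p, seed: LinearRegression(), {}),
    }
    try:  # gradient-boosting ensembles, optional at import time
        from lightgbm import LGBMRegressor

        reg["lightgbm"] = _Family(
            "lightgbm",
            lambda p, seed: LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **p),
            {"n_estimators": sps.randint(100, 500), "learning_rate": _loguniform(1e-2, 0.3),
             "num_leaves": sps.randint(7, 63)},
            scale_sensitive=False,
        )
    except ImportError:
        pass
    try:
        from xgboost import XGBRegressor

        reg["xgboost"] = _Family(
            "xgboost",
            lambda p, seed: XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **p),
            {"n_estimators": sps.randint(100, 500), "learning_rate": _loguniform(1e-2, 0.3),
             "max_depth": sps.randint(2, 8)},
            scale_sensitive=False,
        )
    except ImportError:
        pass
    return reg


FAMILY_REGISTRY: dict[str, _Family] = _registry()

DEFAULT_FAMILIES = [
    "svr_rbf", "elastic_net", "ridge", "lasso", "random_forest",
    "linear_svr", "lightgbm", "xgboost",
]


def age_decade_strata(age: np.ndarray, min_per_stratum: int) -> np.ndarray:
    """floor(age/10) strata; strata smaller than ``min_per_stratum`` are
    merged with the nearest neighbouring decade until all are viable."""
    strata = np.floor(np.asarray(age, dtype=float) / 10.0).astype(int)
    while True:
        labels, counts = np.unique(strata, return_counts=True)
        small = labels[counts < min_per_stratum]
        if small.size == 0 or labels.size == 1:
            break
        s = small[0]
        others = labels[labels != s]
        nearest = others[np.argmin(np.abs(others - s))]
        strata[strata == s] = nearest
    labels, counts = np.unique(strata, return_counts=True)
    if np.any(counts < min_per_stratum):
        raise ValueError(
            f"stratum sizes {dict(zip(labels.tolist(), counts.tolist()))} remain "
            f"below {min_per_stratum} after merging"
        )
    return strata


def _build(family: _Family, params: dict, seed: int):
    est = family.factory(params, seed)
    if family.scale_sensitive:
        return make_pipeline(StandardScaler(), est)
    return est


def _tune(
    family: _Family, x: np.ndarray, age: np.ndarray, spec: CVSpec, rng_seed: int
) -> dict:
    """Seeded random hyperparameter search on the inner folds; returns the
    parameter set with lowest mean inner MAE."""
    if not family.space:
        return {}
    candidates = list(ParameterSampler(family.space, n_iter=spec.search_budget,
                                       random_state=rng_seed))
    inner = KFold(n_splits=spec.inner_folds, shuffle=True, random_state=rng_seed)
    splits = list(inner.split(x))
    best_params, best_mae = candidates[0], np.inf
    for params in candidates:
        errs = []
        for tr, te in splits:
            est = _build(family, params, rng_seed)
            est.fit(x[tr], age[tr])
            errs.append(np.mean(np.abs(est.predict(x[te]) - age[te])))
        mae = float(np.mean(errs))
        if mae < best_mae:
            best_mae, best_params = mae, params
    return best_params


def summarize_metrics(
    pred: np.ndarray, truth: np.ndarray, fold_ids: np.ndarray, family: str = ""
) -> ModelPerformance:
    """Per-fold MAE/RMSE/R2/r aggregated with t-based 95% CIs over folds
    and a Fisher-z interval for the pooled Pearson r."""
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    fold_ids = np.asarray(fold_ids)
    folds = np.unique(fold_ids)
    if folds.size < 2:
        raise ValueError("need >= 2 folds for confidence intervals")
    rows = []
    for f in folds:
        m = fold_ids == f
        e = pred[m] - truth[m]
        mae = float(np.mean(np.abs(e)))
        rmse = float(np.sqrt(np.mean(e**2)))
        ss_res = float(np.sum(e**2))
        ss_tot = float(np.sum((truth[m] - truth[m].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        if np.std(pred[m]) == 0 or np.std(truth[m]) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(pred[m], truth[m])[0, 1])
        rows.append({"fold": f, "mae": mae, "rmse": rmse, "r2": r2, "r": r})
    per_fold = pd.DataFrame(rows)

    def t_ci(vals: np.ndarray) -> tuple[float, float]:
        k = len(vals)
        half = sps.t.ppf(0.975, k - 1) * np.std(vals, ddof=1) / np.sqrt(k)
        return (float(np.mean(vals) - half), float(np.mean(vals) + half))

    if np.std(pred) == 0:
        warnings.warn("constant predictions: Pearson r undefined", stacklevel=2)
        r_pooled, ci_r = np.nan, (np.nan, np.nan)
    else:
        r_pooled = float(np.corrcoef(pred, truth)[0, 1])
        zr = np.arctanh(np.clip(r_pooled, -1 + 1e-12, 1 - 1e-12))
        hw = 1.96 / np.sqrt(len(pred) - 3)
        ci_r = (float(np.tanh(zr - hw)), float(np.tanh(zr + hw)))

    return ModelPerformance(
        model_family=family,
        mae=float(per_fold["mae"].mean()),
        rmse=float(per_fold["rmse"].mean()),
        r2=float(per_fold["r2"].mean()),
        pearson_r=r_pooled,
        ci_mae=t_ci(per_fold["mae"].to_numpy()),
        ci_rmse=t_ci(per_fold["rmse"].to_numpy()),
        ci_r2=t_ci(per_fold["r2"].to_numpy()),
        ci_r=ci_r,
        per_fold=per_fold,
    )


def nested_cv_benchmark(
    x: pd.DataFrame | np.ndarray,
    age: np.ndarray,
    families: list[str] | None = None,
    spec: CVSpec | None = None,
) -> BenchmarkResult:
    """Benchmark regressor families under nested CV; winner = lowest mean
    outer-fold MAE.  Hyperparameters are tuned on inner folds only, so no
    outer-fold test subject ever influences model selection."""
    spec = spec or CVSpec()
    spec.validate()
    if families is None:
        families = [f for f in DEFAULT_FAMILIES if f in FAMILY_REGISTRY]
    unknown = [f for f in families if f not in FAMILY_REGISTRY]
    if unknown:
        raise ValueError(f"unknown model families: {unknown}")
    xv = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, float)
    age = np.asarray(age, dtype=float)
    if len(xv) < 50:
        raise ValueError("need at least 50 subjects for the benchmark")

    strata = age_decade_strata(age, min_per_stratum=spec.outer_folds)
    outer = RepeatedStratifiedKFold(
        n_splits=spec.outer_folds, n_repeats=spec.outer_repeats, random_state=spec.seed
    )
    splits = list(outer.split(xv, strata))

    performances: dict[str, ModelPerformance] = {}
    oof_store: dict[str, pd.DataFrame] = {}
    fold_params: dict[str, list[dict]] = {}
    for fam_name in families:
        family = FAMILY_REGISTRY[fam_name]
        preds = np.empty(0)
        truths = np.empty(0)
        fold_ids = np.empty(0, dtype=int)
        subject_rows = np.empty(0, dtype=int)
        params_per_fold = []
        for fold_i, (tr, te) in enumerate(splits):
            params = _tune(family, xv[tr], age[tr], spec,
                           rng_seed=spec.seed + 1000 * fold_i)
            est = _build(family, params, spec.seed)
            est.fit(xv[tr], age[tr])
            p = est.predict(xv[te])
            preds = np.concatenate([preds, p])
            truths = np.concatenate([truths, age[te]])
            fold_ids = np.concatenate([fold_ids, np.full(len(te), fold_i)])
            subject_rows = np.concatenate([subject_rows, te])
            params_per_fold.append(params)
        performances[fam_name] = summarize_metrics(preds, truths, fold_ids, fam_name)
        oof_store[fam_name] = pd.DataFrame(
            {"row": subject_rows, "fold": fold_ids, "age": truths, "pred": preds}
        )
        fold_params[fam_name] = params_per_fold

    table = pd.DataFrame(
        [
            {
                "model_family": p.model_family,
                "mae": p.mae, "rmse": p.rmse, "r2": p.r2, "pearson_r": p.pearson_r,
                "ci_mae_low": p.ci_mae[0], "ci_mae_high": p.ci_mae[1],
                "ci_r_low": p.ci_r[0], "ci_r_high": p.ci_r[1],
            }
            for p in performances.values()
        ]
    ).sort_values("mae").reset_index(drop=True)
    winner = table.loc[0, "model_family"]
    best_fold = int(
        performances[winner].per_fold.sort_values("mae").iloc[0]["fold"]
    )
    return BenchmarkResult(
        table=table,
        performances=performances,
        winner=winner,
        winner_params=fold_params[winner][best_fold],
        oof=oof_store[winner],
        fold_assignments=splits,
    )


def fit_bias_correction(pred_oof: np.ndarray, age: np.ndarray) -> BiasCorrection:
    """Least-squares fit pred = a + b*age on out-of-fold predictions."""
    res = sps.linregress(np.asarray(age, float), np.asarray(pred_oof, float))
    return BiasCorrection(intercept=float(res.intercept), slope=float(res.slope))


def refit_final(
    x: pd.DataFrame,
    age: np.ndarray,
    family: str,
    hyperparameters: dict,
    bias: BiasCorrection,
    seed: int = 0,
) -> BrainAgeModel:
    """Refit the winning family on the full reference pool."""
    if family not in FAMILY_REGISTRY:
        raise ValueError(f"unknown family {family!r}")
    if hyperparameters is None:
        raise ValueError("hyperparameters are required")
    if x.shape[1] == 0:
        raise ValueError("empty feature set")
    est = _build(FAMILY_REGISTRY[family], hyperparameters, seed)
    est.fit(x.to_numpy(dtype=float), np.asarray(age, float))
    return BrainAgeModel(
        estimator=est,
        family=family,
        hyperparameters=dict(hyperparameters),
        bias=bias,
        feature_labels=list(x.columns),
        training_summary={"n_train": int(len(x))},
    )


def predict_brainage(model: BrainAgeModel, x: pd.DataFrame) -> np.ndarray:
    """Bias-corrected brain age: (raw prediction - a) / b."""
    if list(x.columns) != model.feature_labels:
        missing = set(model.feature_labels) - set(x.columns)
        extra = set(x.columns) - set(model.feature_labels)
        raise ValueError(f"feature label mismatch; missing={sorted(missing)[:3]} "
                         f"extra={sorted(extra)[:3]}")
    raw = model.estimator.predict(x.to_numpy(dtype=float))
    return (raw - model.bias.intercept) / model.bias.slope


def compute_bag(corrected_brainage: np.ndarray, age: np.ndarray) -> np.ndarray:
    """BAG = corrected brain age - chronological age (years)."""
    corrected_brainage = np.asarray(corrected_brainage, float)
    age = np.asarray(age, float)
    if corrected_brainage.shape != age.shape:
        raise ValueError("length mismatch between predictions and ages")
    return corrected_brainage - age
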