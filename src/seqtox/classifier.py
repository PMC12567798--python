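"""Binary toxin classifier: training, nested cross-validation, tuning.

Four algorithm families sit behind one interface — the two
gradient-boosting implementations (XGBoost, the default and best
performer, and LightGBM) plus random forest and a support-vector
machine.  Nested cross-validation refits every label-dependent step
(minimotif mining, ensemble feature selection, RFECV) inside each
training fold and records which sample ids each such step saw, so
information-leakage checks are mechanical.

Hyperparameter search is sequential model-based optimization: a
Gaussian-process surrogate over the (log-)scaled search space with an
expected-improvement acquisition, maximizing mean cross-validated MCC.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .evaluation import (
    ConfusionCounts,
    MetricsReport,
    auc_from_scores,
    counts_from_predictions,
    metrics_from_counts,
)
from .feature_selection import gefs_top_features, rfecv_select, correlation_filter, drop_zero_variance
from .motif_mining import discover_motifs, encode_motifs
from .sequence_io import Dataset

__all__ = [
    "ALGORITHMS",
    "CVScheme",
    "TrainedModel",
    "train",
    "predict",
    "cross_validate",
    "run_nested_cv",
    "tune_hyperparameters",
    "smbo_maximize",
    "save_model",
    "load_model",
]

ALGORITHMS = ("xgboost", "lightgbm", "random-forest", "svm")


def _make_estimator(algorithm: str, params: dict | None, seed: int):
    params = dict(params or {})
    if algorithm == "xgboost":
        base = dict(n_estimators=100, tree_method="hist", eval_metric="logloss",
                    random_state=seed, n_jobs=1)
        base.update(params)
        return XGBClassifier(**base)
    if algorithm == "lightgbm":
        base = dict(n_estimators=100, random_state=seed, n_jobs=1, verbose=-1,
                    deterministic=True, force_row_wise=True)
        base.update(params)
        return LGBMClassifier(**base)
    if algorithm == "random-forest":
        base = dict(n_estimators=100, random_state=seed, n_jobs=1)
        base.update(params)
        return RandomForestClassifier(**base)
    if algorithm == "svm":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        base = dict(probability=True, random_state=seed)
        base.update(params)
        # SVMs need comparable feature scales; the boosted trees do not
        return make_pipeline(StandardScaler(), SVC(**base))
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclasses.dataclass
class CVScheme:
    """Stratified k-fold plan: 20 folds means 95% train / 5% validation."""

    n_folds: int = 20
    seed: int = 0

    def splitter(self) -> StratifiedKFold:
        return StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)


@dataclasses.dataclass
class TrainedModel:
    """A fitted classifier bound to an ordered feature-name list.

    Prediction matches columns by name, never by position; the decision
    threshold converts the toxin-class probability into a label
    (``probability >= threshold``).
    """

    algorithm: str
    estimator: object
    feature_names: list[str]
    threshold: float = 0.5
    seed: int = 0
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


def _config_hash(algorithm: str, params: dict | None, seed: int) -> str:
    payload = json.dumps({"algorithm": algorithm, "params": params or {}, "seed": seed},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def train(
    fm: pd.DataFrame,
    labels: Sequence[int],
    algorithm: str = "xgboost",
    params: dict | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> TrainedModel:
    """Fit one classifier; deterministic for a fixed seed (single thread)."""
    y = np.asarray(labels)
    if len(y) != len(fm):
        raise ValueError(f"{len(fm)} rows but {len(y)} labels")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    est = _make_estimator(algorithm, params, seed)
    est.fit(fm.to_numpy(dtype=float), y)
    return TrainedModel(
        algorithm=algorithm,
        estimator=est,
        feature_names=list(fm.columns),
        threshold=threshold,
        seed=seed,
        config_hash=_config_hash(algorithm, params, seed),
    )


def predict(model: TrainedModel, fm: pd.DataFrame) -> pd.DataFrame:
    """Per-row toxin probability and thresholded label.

    ``fm`` may carry extra columns and any column order; missing model
    features are an error listing the absent names.
    """
    missing = [f for f in model.feature_names if f not in fm.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    x = fm[model.feature_names].to_numpy(dtype=float)
    proba = model.estimator.predict_proba(x)[:, 1]
    return pd.DataFrame(
        {"probability": proba, "label": (proba >= model.threshold).astype(int)},
        index=fm.index,
    )


def cross_validate(
    fm: pd.DataFrame,
    labels: Sequence[int],
    algorithm: str = "xgboost",
    scheme: CVScheme | None = None,
    params: dict | None = None,
    preprocess: Callable | None = None,
    threshold: float = 0.5,
) -> dict:
    """Stratified k-fold cross-validation with in-fold preprocessing.

    ``preprocess(X_train, y_train, fold, audit)`` may return a feature-name
    list (fit on the training portion only) that both halves of the fold
    are then restricted to; it can append to ``audit`` whatever ids it
    consumed.  Returns per-fold confusion counts and metrics, their
    means ("metrics", matching fold-averaged table semantics), metrics
    of the mean counts ("metrics_of_mean_counts"), and the audit log.
    """
    scheme = scheme or CVScheme()
    y = np.asarray(labels)
    audit: list[dict] = []
    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[MetricsReport] = []
    aucs: list[float] = []
    folds: list[dict] = []
    for fold, (tr, va) in enumerate(scheme.splitter().split(fm, y)):
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold} has a single class after splitting")
        x_tr, x_va = fm.iloc[tr], fm.iloc[va]
        if preprocess is not None:
            features = preprocess(x_tr, y[tr], fold, audit)
            x_tr, x_va = x_tr[features], x_va[features]
        model = train(x_tr, y[tr], algorithm, params=params,
                      seed=scheme.seed + fold, threshold=threshold)
        pred = predict(model, x_va)
        counts = counts_from_predictions(y[va], pred["label"].to_numpy())
        report = metrics_from_counts(counts)
        report.AUC = auc_from_scores(pred["probability"].to_numpy(), y[va])
        fold_counts.append(counts)
        fold_metrics.append(report)
        aucs.append(report.AUC)
        folds.append({
            "fold": fold,
            "train_ids": list(fm.index[tr]),
            "validation_ids": list(fm.index[va]),
            "counts": dataclasses.asdict(counts),
            "metrics": report.to_dict(),
        })
    mean_counts = ConfusionCounts(
        tp=float(np.mean([c.tp for c in fold_counts])),
        tn=float(np.mean([c.tn for c in fold_counts])),
        fp=float(np.mean([c.fp for c in fold_counts])),
        fn=float(np.mean([c.fn for c in fold_counts])),
    )
    mean_metrics = {
        name: float(np.mean([m.to_dict()[name] for m in fold_metrics]))
        for name in fold_metrics[0].to_dict()
    }
    return {
        "folds": folds,
        "mean_counts": dataclasses.asdict(mean_counts),
        "metrics": mean_metrics,
        "metrics_of_mean_counts": metrics_from_counts(mean_counts).to_dict(),
        "audit": audit,
    }


def run_nested_cv(
    records: Dataset,
    labels: Sequence[int],
    base_fm: pd.DataFrame,
    algorithm: str = "xgboost",
    scheme: CVScheme | None = None,
    motif_params: dict | None = None,
    selection_params: dict | None = None,
    params: dict | None = None,
) -> dict:
    """Fully nested pipeline CV: motif mining, correlation filtering,
    GEFS and RFECV are refit on every training fold.

    ``base_fm`` holds the label-free descriptor columns for all records
    (motif flags are added per fold from fold-mined motifs).  The audit
    log records, for each fold and label-using stage, exactly the sample
    ids whose labels the stage received.
    """
    scheme = scheme or CVScheme()
    motif_params = motif_params or {}
    selection_params = dict(selection_params or {})
    y = np.asarray(labels)
    by_id = {rec.id: rec for rec in records}

    def preprocess(x_tr: pd.DataFrame, y_tr: np.ndarray, fold: int, audit: list) -> list[str]:
        tr_ids = list(x_tr.index)
        pos = Dataset([by_id[i] for i, lab in zip(tr_ids, y_tr) if lab == 1], label="toxin")
        neg = Dataset([by_id[i] for i, lab in zip(tr_ids, y_tr) if lab == 0], label="non-toxin")
        audit.append({"fold": fold, "stage": "motif_mining",
                      "ids": pos.ids() + neg.ids()})
        ms = discover_motifs(pos, neg, **motif_params)
        if len(ms):
            motif_tr = pd.DataFrame(
                [encode_motifs(by_id[i].sequence, ms) for i in tr_ids], index=tr_ids
            )
            x_tr = pd.concat([x_tr, motif_tr], axis=1)
            # make fold motifs visible to the validation transform
            fold_motifs[fold] = ms
        x_tr, report = drop_zero_variance(x_tr)
        x_tr, report = correlation_filter(
            x_tr, threshold=selection_params.get("corr_threshold", 0.8), report=report
        )
        gefs_kwargs = {k: selection_params[k] for k in
                       ("n_members", "member_top", "top_k", "n_estimators")
                       if k in selection_params}
        audit.append({"fold": fold, "stage": "gefs", "ids": list(x_tr.index)})
        top, _, report = gefs_top_features(
            x_tr, y_tr, seed=scheme.seed + fold, report=report, **gefs_kwargs
        )
        rfecv_kwargs = {k: selection_params[k] for k in ("cv_folds", "n_estimators")
                        if k in selection_params}
        audit.append({"fold": fold, "stage": "rfecv", "ids": list(x_tr.index)})
        final, report = rfecv_select(
            x_tr[top], y_tr, seed=scheme.seed + fold, report=report, **rfecv_kwargs
        )
        return final

    fold_motifs: dict[int, object] = {}

    # motif columns must exist on validation rows too: wrap cross_validate
    # with a matrix that gains fold-specific motif columns lazily.
    scheme_local = scheme
    y_all = y
    audit: list[dict] = []
    fold_counts: list[ConfusionCounts] = []
    folds_out: list[dict] = []
    for fold, (tr, va) in enumerate(scheme_local.splitter().split(base_fm, y_all)):
        x_tr, x_va = base_fm.iloc[tr], base_fm.iloc[va]
        features = preprocess(x_tr, y_all[tr], fold, audit)
        ms = fold_motifs.get(fold)
        if ms is not None and len(ms):
            motif_all = pd.DataFrame(
                [encode_motifs(by_id[i].sequence, ms) for i in base_fm.index],
                index=base_fm.index,
            )
            x_tr = pd.concat([x_tr, motif_all.iloc[tr]], axis=1)
            x_va = pd.concat([x_va, motif_all.iloc[va]], axis=1)
        model = train(x_tr[features], y_all[tr], algorithm, params=params,
                      seed=scheme_local.seed + fold)
        pred = predict(model, x_va)
        counts = counts_from_predictions(y_all[va], pred["label"].to_numpy())
        report = metrics_from_counts(counts)
        report.AUC = auc_from_scores(pred["probability"].to_numpy(), y_all[va])
        fold_counts.append(counts)
        folds_out.append({
            "fold": fold,
            "train_ids": list(base_fm.index[tr]),
            "validation_ids": list(base_fm.index[va]),
            "n_features": len(features),
            "counts": dataclasses.asdict(counts),
            "metrics": report.to_dict(),
        })
    mean_metrics = {
        name: float(np.mean([f["metrics"][name] for f in folds_out]))
        for name in folds_out[0]["metrics"]
    }
    return {"folds": folds_out, "metrics": mean_metrics, "audit": audit}


# ---------------------------------------------------------------------------
# Sequential model-based optimization
# ---------------------------------------------------------------------------


def _space_to_unit(space: dict, params: dict) -> np.ndarray:
    u = []
    for name, (low, high, kind) in space.items():
        v = params[name]
        if kind == "log":
            u.append((np.log(v) - np.log(low)) / (np.log(high) - np.log(low)))
        else:
            u.append((v - low) / (high - low))
    return np.array(u)


def _unit_to_space(space: dict, u: np.ndarray) -> dict:
    params = {}
    for x, (name, (low, high, kind)) in zip(u, space.items()):
        if kind == "log":
            v = float(np.exp(np.log(low) + x * (np.log(high) - np.log(low))))
        else:
            v = float(low + x * (high - low))
        if kind == "int":
            v = int(round(v))
        params[name] = v
    return params


def smbo_maximize(
    objective: Callable[[dict], float],
    space: dict,
    budget: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[dict, list[dict]]:
    """Maximize a black-box objective over a box-bounded space.

    Random initial design of ``n_init`` points, then a Matern-5/2
    Gaussian-process surrogate with expected-improvement acquisition
    over 256 random candidates per iteration.  Deterministic for a
    fixed seed; returns the best parameters and the full evaluation
    trace.
    """
    if not space:
        raise ValueError("empty search space")
    if budget < n_init:
        raise ValueError(f"budget={budget} smaller than initial design size {n_init}")
    rng = np.random.default_rng(seed)
    dim = len(space)
    trace: list[dict] = []
    xs: list[np.ndarray] = []
    ys: list[float] = []

    def evaluate(u: np.ndarray) -> None:
        params = _unit_to_space(space, u)
        score = float(objective(params))
        xs.append(_space_to_unit(space, params))  # snap ints back to grid
        ys.append(score)
        trace.append({"params": params, "score": score})

    for _ in range(n_init):
        evaluate(rng.random(dim))
    while len(trace) < budget:
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), normalize_y=True, random_state=seed, alpha=1e-6
        )
        gp.fit(np.vstack(xs), np.array(ys))
        cand = rng.random((256, dim))
        mu, sigma = gp.predict(cand, return_std=True)
        best = max(ys)
        sigma = np.maximum(sigma, 1e-12)
        z = (mu - best) / sigma
        from scipy.stats import norm

        ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
        evaluate(cand[int(np.argmax(ei))])
    best_i = int(np.argmax(ys))
    return trace[best_i]["params"], trace


DEFAULT_SEARCH_SPACE = {
    "n_estimators": (100, 2000, "int"),
    "max_depth": (3, 10, "int"),
    "learning_rate": (1e-3, 0.3, "log"),
    "subsample": (0.5, 1.0, "float"),
    "colsample_bytree": (0.5, 1.0, "float"),
    "min_child_weight": (1, 10, "int"),
}


def tune_hyperparameters(
    fm: pd.DataFrame,
    labels: Sequence[int],
    algorithm: str = "xgboost",
    search_space: dict | None = None,
    budget: int = 50,
    seed: int = 0,
    cv_folds: int = 5,
    n_init: int = 10,
) -> tuple[dict, list[dict]]:
    """Bayesian hyperparameter optimization; objective is mean CV MCC."""
    space = search_space or DEFAULT_SEARCH_SPACE
    y = np.asarray(labels)

    def objective(params: dict) -> float:
        result = cross_validate(
            fm, y, algorithm, scheme=CVScheme(n_folds=cv_folds, seed=seed), params=params
        )
        return result["metrics"]["MCC"]

    return smbo_maximize(objective, space, budget=budget, seed=seed, n_init=n_init)


# ---------------------------------------------------------------------------
# Persistence (gradient-boosting families: text payloads, no pickled code)
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Persist a trained gradient-boosting model as a portable archive:
    ``meta.json`` plus the library's own text model dump."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if model.algorithm == "xgboost":
        payload = "model.xgb.json"
        model.estimator.get_booster().save_model(str(directory / payload))
    elif model.algorithm == "lightgbm":
        payload = "model.lgb.txt"
        model.estimator.booster_.save_model(str(directory / payload))
    else:
        raise ValueError(
            f"persistence is supported for gradient-boosting models, not {model.algorithm!r}"
        )
    meta = {
        "algorithm": model.algorithm,
        "feature_names": model.feature_names,
        "threshold": model.threshold,
        "seed": model.seed,
        "config_hash": model.config_hash,
        "payload": payload,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    if meta["algorithm"] == "xgboost":
        import xgboost

        booster = xgboost.Booster()
        booster.load_model(str(directory / meta["payload"]))
        est = _XGBoosterProbaAdapter(booster)
    elif meta["algorithm"] == "lightgbm":
        import lightgbm

        booster = lightgbm.Booster(model_file=str(directory / meta["payload"]))
        est = _BoosterProbaAdapter(booster)
    else:
        raise ValueError(f"unsupported archived algorithm {meta['algorithm']!r}")
    return TrainedModel(
        algorithm=meta["algorithm"],
        estimator=est,
        feature_names=meta["feature_names"],
        threshold=meta["threshold"],
        seed=meta["seed"],
        config_hash=meta["config_hash"],
    )


class _BoosterProbaAdapter:
    """Give a raw LightGBM booster the predict_proba surface."""

    def __init__(self, booster):
        self.booster = booster

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p = np.asarray(self.booster.predict(x))
        return np.column_stack([1 - p, p])


class _XGBoosterProbaAdapter:
    """Give a raw XGBoost booster the predict_proba surface."""

    def __init__(self, booster):
        self.booster = booster

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p = np.asarray(self.booster.inplace_predict(x))
        return np.column_stack([1 - p, p])
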