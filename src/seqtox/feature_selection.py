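"""Four-stage feature-selection cascade.

1. zero-variance removal,
2. greedy Pearson-correlation filter (|r| >= threshold drops the later
   column),
3. graphical ensemble feature selection (GEFS): bootstrap an ensemble of
   gradient-boosted learners, let each nominate its top features, build a
   co-selection graph and rank features by weighted degree,
4. recursive feature elimination with cross-validation (RFECV), keeping
   the smallest subset within one standard error of the best CV score.

Stages 3 and 4 use labels, so inside cross-validation they must be refit
on each training fold (see :func:`seqtox.classifier.cross_validate`).
Every stage appends to a :class:`SelectionReport` so the bookkeeping
identity ``in - dropped = out`` is auditable at each step.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionReport",
    "drop_zero_variance",
    "correlation_filter",
    "gefs_top_features",
    "rfecv_select",
    "select_features",
]


@dataclasses.dataclass
class SelectionStage:
    name: str
    n_in: int
    dropped: list[dict]
    n_out: int

    def check(self) -> None:
        if self.n_in - len(self.dropped) != self.n_out:
            raise AssertionError(
                f"stage {self.name}: {self.n_in} - {len(self.dropped)} != {self.n_out}"
            )


@dataclasses.dataclass
class SelectionReport:
    """Audit trail of what each cascade stage kept and why it dropped."""

    stages: list[SelectionStage] = dataclasses.field(default_factory=list)
    final_features: list[str] = dataclasses.field(default_factory=list)

    def add(self, name: str, n_in: int, dropped: list[dict], n_out: int) -> None:
        stage = SelectionStage(name, n_in, dropped, n_out)
        stage.check()
        if self.stages and self.stages[-1].n_out != n_in:
            raise AssertionError(
                f"stage {name}: n_in={n_in} != previous n_out={self.stages[-1].n_out}"
            )
        self.stages.append(stage)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "stages": [dataclasses.asdict(s) for s in self.stages],
            "final_features": self.final_features,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _default_member(seed: int, n_estimators: int = 100) -> LGBMClassifier:
    return LGBMClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
        deterministic=True,
        force_row_wise=True,
    )


def drop_zero_variance(
    fm: pd.DataFrame, report: SelectionReport | None = None
) -> tuple[pd.DataFrame, SelectionReport]:
    """Remove constant columns (standard deviation exactly 0)."""
    if fm.shape[1] == 0:
        raise ValueError("empty feature matrix")
    report = report or SelectionReport()
    sd = fm.to_numpy(dtype=float).std(axis=0)
    constant = fm.columns[sd == 0]
    if len(constant) == fm.shape[1]:
        raise ValueError("all columns are constant; nothing to learn from")
    dropped = [{"feature": c, "reason": "zero variance"} for c in constant]
    out = fm.drop(columns=constant)
    report.add("zero_variance", fm.shape[1], dropped, out.shape[1])
    return out, report


def correlation_filter(
    fm: pd.DataFrame,
    threshold: float = 0.8,
    report: SelectionReport | None = None,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Greedy Pearson filter: scanning columns in order, drop any column
    with |r| >= ``threshold`` against an already-kept column.

    Afterwards no surviving pair correlates at or above the threshold,
    and re-running the filter is a no-op (idempotence).  The earlier
    column of each offending pair is the one kept, making the outcome
    deterministic.
    """
    report = report or SelectionReport()
    x = fm.to_numpy(dtype=float)
    n, p = x.shape
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("run drop_zero_variance before the correlation filter")
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / n
    keep: list[int] = []
    dropped: list[dict] = []
    for j in range(p):
        partner = next((i for i in keep if abs(corr[i, j]) >= threshold), None)
        if partner is None:
            keep.append(j)
        else:
            dropped.append(
                {
                    "feature": fm.columns[j],
                    "reason": "correlated",
                    "partner": fm.columns[partner],
                    "r": round(float(corr[partner, j]), 6),
                }
            )
    out = fm.iloc[:, keep]
    report.add("correlation_filter", p, dropped, out.shape[1])
    return out, report


def rank_coselection(
    graph: nx.Graph, nominations: dict[str, int]
) -> tuple[list[str], dict[str, int]]:
    """Rank ever-nominated features by weighted co-selection degree.

    Ties break on total nomination count, then feature name.  Returns
    the ranking and the weighted-degree map.
    """
    degree = {f: 0 for f in graph.nodes}
    for a, b, data in graph.edges(data=True):
        degree[a] += data["weight"]
        degree[b] += data["weight"]
    ranked = sorted(
        (f for f, n in nominations.items() if n > 0),
        key=lambda f: (-degree.get(f, 0), -nominations[f], f),
    )
    return ranked, degree


def gefs_top_features(
    fm: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_members: int = 20,
    member_top: int = 50,
    top_k: int = 100,
    seed: int = 0,
    n_estimators: int = 100,
    report: SelectionReport | None = None,
) -> tuple[list[str], nx.Graph, SelectionReport]:
    """Graphical ensemble feature selection.

    ``n_members`` gradient-boosted learners are trained on bootstrap
    resamples of the rows; each nominates its ``member_top`` features by
    gain importance.  Vertices of the co-selection graph are features,
    edge weights count how many members nominated both endpoints.
    Features are ranked by weighted degree (ties: total nomination
    count, then name) and the ``top_k`` best are returned.
    """
    report = report or SelectionReport()
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = len(fm)
    graph = nx.Graph()
    graph.add_nodes_from(fm.columns)
    nominations: dict[str, int] = {c: 0 for c in fm.columns}
    for m in range(n_members):
        idx = rng.integers(0, n, size=n)
        member = _default_member(seed=seed * 1000 + m, n_estimators=n_estimators)
        member.fit(fm.iloc[idx], y[idx])
        imp = pd.Series(
            member.booster_.feature_importance(importance_type="gain"),
            index=fm.columns,
        )
        selected = list(imp.sort_values(ascending=False, kind="stable").index[:member_top])
        for f in selected:
            nominations[f] += 1
        for i, a in enumerate(selected):
            for b in selected[i + 1 :]:
                w = graph.get_edge_data(a, b, {}).get("weight", 0)
                graph.add_edge(a, b, weight=w + 1)
    ranked, degree = rank_coselection(graph, nominations)
    if len(ranked) < top_k:
        import warnings

        warnings.warn(
            f"only {len(ranked)} features were ever selected by ensemble members "
            f"(requested top_k={top_k})"
        )
    top = ranked[:top_k]
    dropped = [
        {"feature": f, "reason": "low co-selection degree", "degree": int(degree[f])}
        for f in fm.columns
        if f not in set(top)
    ]
    report.add("gefs", fm.shape[1], dropped, len(top))
    return top, graph, report


def export_graph(graph: nx.Graph, path: str | Path) -> None:
    """Co-selection graph as an edge-list TSV (feature_a, feature_b, weight)."""
    with open(path, "w") as fh:
        fh.write("feature_a\tfeature_b\tweight\n")
        for a, b, data in graph.edges(data=True):
            fh.write(f"{a}\t{b}\t{data['weight']}\n")


def rfecv_select(
    fm: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
    report: SelectionReport | None = None,
) -> tuple[list[str], SelectionReport]:
    """Recursive feature elimination with cross-validated scoring.

    At each step the estimator is refit on the surviving features, the
    subset's mean CV accuracy recorded, and the least-important feature
    removed (step size 1).  The returned subset is the smallest whose
    mean score is within one standard error of the best mean score —
    a reproducible parsimony rule.
    """
    report = report or SelectionReport()
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    features = list(fm.columns)
    if not features:
        raise ValueError("empty feature matrix")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(fm, y))
    path: list[tuple[list[str], float, float]] = []  # (features, mean, se)
    current = features[:]
    while current:
        x = fm[current]
        scores = []
        for tr, va in splits:
            est = _default_member(seed=seed, n_estimators=n_estimators)
            est.fit(x.iloc[tr], y[tr])
            scores.append(float((est.predict(x.iloc[va]) == y[va]).mean()))
        mean = float(np.mean(scores))
        se = float(np.std(scores, ddof=1) / np.sqrt(len(scores))) if len(scores) > 1 else 0.0
        path.append((current[:], mean, se))
        if len(current) == 1:
            break
        est = _default_member(seed=seed, n_estimators=n_estimators)
        est.fit(x, y)
        imp = pd.Series(
            est.booster_.feature_importance(importance_type="gain"), index=current
        )
        weakest = imp.sort_values(kind="stable").index[0]
        current = [f for f in current if f != weakest]
    best_mean, best_se = max((m, s) for _, m, s in path)
    eligible = [(feats, m) for feats, m, _ in path if m >= best_mean - best_se]
    final = min(eligible, key=lambda t: len(t[0]))[0]
    dropped = [
        {"feature": f, "reason": "eliminated by RFECV"}
        for f in features
        if f not in set(final)
    ]
    report.add("rfecv", len(features), dropped, len(final))
    report.final_features = final
    return final, report


def select_features(
    fm: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    corr_threshold: float = 0.8,
    n_members: int = 20,
    member_top: int = 50,
    top_k: int = 100,
    cv_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
) -> tuple[list[str], SelectionReport, nx.Graph]:
    """Run the full cascade; deterministic given the seed and input."""
    x, report = drop_zero_variance(fm)
    x, report = correlation_filter(x, threshold=corr_threshold, report=report)
    top, graph, report = gefs_top_features(
        x, labels, n_members=n_members, member_top=member_top, top_k=top_k,
        seed=seed, n_estimators=n_estimators, report=report,
    )
    final, report = rfecv_select(
        x[top], labels, cv_folds=cv_folds, seed=seed,
        n_estimators=n_estimators, report=report,
    )
    return final, report, graph
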