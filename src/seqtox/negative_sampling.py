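"""Clustering-based sampling of a balanced negative set.

Non-toxin sequences vastly outnumber toxins, so the negative training
pool is summarized by k-means in descriptor space: the number of
clusters is picked from the elbow of the SSE-versus-k curve, then a
balanced negative set is drawn with per-cluster quotas proportional to
cluster size.  Compared with plain random undersampling this keeps
rare regions of the non-toxin feature space represented.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ClusterModel",
    "kmeans_fit",
    "sse_curve",
    "elbow_select",
    "sample_representatives",
]


@dataclasses.dataclass
class ClusterModel:
    """Fitted k-means model over a feature matrix.

    ``sse`` is the within-cluster sum of squared Euclidean distances to
    the assigned centroid (k-means inertia) in the standardized space
    when ``standardize=True`` was used.
    """

    k: int
    centroids: np.ndarray
    assignments: pd.Series  # row id -> cluster index
    sse: float
    seed: int

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments.to_numpy(), minlength=self.k)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def kmeans_fit(
    fm: pd.DataFrame,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    standardize: bool = True,
) -> ClusterModel:
    """Best-of-``restarts`` k-means fit (deterministic for a fixed seed).

    Features are z-scored by default so heterogeneous descriptor scales
    do not dominate the Euclidean SSE.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(fm):
        raise ValueError(f"k={k} exceeds number of rows {len(fm)}")
    x = fm.to_numpy(dtype=float)
    if standardize:
        x = _standardize(x)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=pd.Series(labels, index=fm.index),
        sse=float(km.inertia_),
        seed=seed,
    )


def sse_curve(
    fm: pd.DataFrame,
    k_values=range(2, 21),
    seed: int = 0,
    restarts: int = 10,
    standardize: bool = True,
) -> dict[int, float]:
    """SSE for each candidate k (the elbow-method input curve)."""
    return {
        k: kmeans_fit(fm, k, seed=seed, restarts=restarts, standardize=standardize).sse
        for k in k_values
    }


def elbow_select(sse_by_k: dict[int, float]) -> int:
    """Pick the elbow of an SSE curve: the interior k maximizing the
    second difference ``SSE(k-1) - 2*SSE(k) + SSE(k+1)``.

    Ties (e.g. a perfectly linear curve) resolve to the smallest k.
    Requires at least three consecutive k values.
    """
    ks = sorted(sse_by_k)
    if len(ks) < 3:
        raise ValueError("elbow selection needs at least 3 consecutive k values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k values must be consecutive")
    best_k, best_val = None, -np.inf
    for k in ks[1:-1]:
        val = sse_by_k[k - 1] - 2 * sse_by_k[k] + sse_by_k[k + 1]
        if val > best_val + 1e-12:
            best_k, best_val = k, val
    return best_k


def _proportional_quotas(sizes: np.ndarray, n_total: int) -> np.ndarray:
    """Largest-remainder allocation, minimum 1 per non-empty cluster.

    Quotas never exceed cluster sizes; any excess is redistributed to
    clusters with spare capacity by largest remainder.
    """
    n_rows = sizes.sum()
    if n_total > n_rows:
        raise ValueError(f"n_total={n_total} exceeds available rows {n_rows}")
    nonempty = sizes > 0
    if n_total < nonempty.sum():  # fewer draws than clusters: favour the largest
        quotas = np.zeros_like(sizes)
        quotas[np.argsort(-sizes, kind="stable")[:n_total]] = 1
        return quotas
    ideal = sizes / n_rows * n_total
    quotas = np.minimum(np.floor(ideal).astype(int), sizes)
    remainder = ideal - np.floor(ideal)
    order = list(np.argsort(-remainder, kind="stable"))
    for idx in order * 2:  # second pass if capacity limits bite
        if quotas.sum() == n_total:
            break
        if quotas[idx] < sizes[idx]:
            quotas[idx] += 1
    # every non-empty cluster contributes at least one representative
    for j in np.flatnonzero(nonempty & (quotas == 0)):
        donor = int(np.argmax(quotas))
        if quotas[donor] > 1:
            quotas[donor] -= 1
            quotas[j] = 1
    return quotas


def sample_representatives(cm: ClusterModel, n_total: int, seed: int = 0) -> list[str]:
    """Draw a balanced sample: per-cluster quotas proportional to cluster
    size (largest remainder, >=1 per non-empty cluster), uniform draws
    without replacement inside each cluster.  Deterministic per seed."""
    sizes = cm.cluster_sizes()
    quotas = _proportional_quotas(sizes, n_total)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for j in range(cm.k):
        members = cm.assignments.index[cm.assignments.to_numpy() == j]
        if quotas[j] == 0:
            continue
        picks = rng.choice(len(members), size=int(quotas[j]), replace=False)
        chosen.extend(members[sorted(picks)])
    return chosen


def export_provenance(cm: ClusterModel, ids: list[str], path: str | Path) -> None:
    """Record seed, k and the selected ids next to a sampling run."""
    payload = {"k": cm.k, "seed": cm.seed, "sse": cm.sse, "n_selected": len(ids), "ids": ids}
    Path(path).write_text(json.dumps(payload, indent=2))
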