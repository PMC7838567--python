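"""Clustering, embedding and partition scoring on key-based distances.

Thin, deterministic wrappers over scipy/scikit-learn: average-linkage
dendrograms and k-means partitions of a ``1 - similarity`` distance
matrix, MDS / classical-PCA embeddings, Adjusted Rand Index scoring and
the cutoff sweep used to compare clustering methods at their best ARI.
No algorithmic content of its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.manifold import MDS
from sklearn.metrics import adjusted_rand_score

__all__ = ["ClusterResult", "cluster", "ari", "sweep_cutoff", "embed"]


@dataclass
class ClusterResult:
    method: str
    assignments: dict[str, int]
    params: dict
    ari_vs_truth: float | None = None


def _check_distances(distances: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    ids = list(distances.index)
    d = np.asarray(distances, dtype=float)
    if d.shape != (len(ids), len(ids)):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return ids, d


def cluster(
    distances: pd.DataFrame,
    method: str = "average_linkage",
    k: int | None = None,
    cutoff: float | None = None,
    seed: int = 0,
    truth: Mapping[str, int] | None = None,
) -> ClusterResult:
    """Partition structures from a distance matrix.

    ``average_linkage`` cuts the hierarchical tree at ``cutoff``
    (distance criterion) or into ``k`` clusters; ``kmeans`` runs on an
    MDS embedding of the distances (k-means needs coordinates) with
    ``min(10, n-1)`` dimensions and the given seed.
    """
    ids, d = _check_distances(distances)
    n = len(ids)
    if method == "average_linkage":
        z = linkage(squareform(d, checks=False), method="average")
        if cutoff is not None:
            labels = fcluster(z, t=cutoff, criterion="distance")
            params = {"cutoff": cutoff}
        elif k is not None:
            if k > n:
                raise ValueError(f"k={k} exceeds {n} items")
            labels = fcluster(z, t=k, criterion="maxclust")
            params = {"k": k}
        else:
            raise ValueError("average_linkage needs k or cutoff")
    elif method == "kmeans":
        if k is None:
            raise ValueError("kmeans needs k")
        if k > n:
            raise ValueError(f"k={k} exceeds {n} items")
        coords, _ = embed(distances, method="mds", dims=min(10, n - 1), seed=seed)
        labels = (
            KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(coords) + 1
        )
        params = {"k": k, "seed": seed}
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    assignments = {i: int(c) for i, c in zip(ids, labels)}
    score = ari(assignments, truth) if truth is not None else None
    return ClusterResult(method=method, assignments=assignments, params=params,
                         ari_vs_truth=score)


def ari(assignment_a: Mapping[str, int], assignment_b: Mapping[str, int]) -> float:
    """Adjusted Rand Index between two partitions over the same ids."""
    if set(assignment_a) != set(assignment_b):
        raise ValueError("partitions cover different id sets")
    ids = sorted(assignment_a)
    return float(
        adjusted_rand_score([assignment_a[i] for i in ids], [assignment_b[i] for i in ids])
    )


def sweep_cutoff(
    distances: pd.DataFrame,
    truth: Mapping[str, int],
    step: float = 0.01,
) -> tuple[float, float]:
    """Best average-linkage cutoff by ARI against a reference partition.

    Distances are normalized by their maximum; cutoffs scan [step, 1]
    in the given step.  Returns ``(best_cutoff, best_ari)`` with ties
    resolved toward the smaller cutoff.
    """
    ids, d = _check_distances(distances)
    dmax = d.max()
    dn = d / dmax if dmax > 0 else d
    z = linkage(squareform(dn, checks=False), method="average")
    best = (np.nan, -np.inf)
    for c in np.arange(step, 1.0 + step / 2, step):
        labels = fcluster(z, t=c, criterion="distance")
        score = ari({i: int(l) for i, l in zip(ids, labels)}, truth)
        if score > best[1]:
            best = (float(c), score)
    return best


def embed(
    distances: pd.DataFrame,
    method: str = "mds",
    dims: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Low-dimensional coordinates from a distance matrix.

    ``mds``: metric MDS on the precomputed distances (returns the final
    stress).  ``pca``: classical (Torgerson) scaling — eigendecomposition
    of the double-centered squared distances — returning the fraction of
    total (positive) eigenvalue mass explained.  Both deterministic for
    a fixed seed.
    """
    ids, d = _check_distances(distances)
    n = len(ids)
    if dims >= n:
        raise ValueError(f"dims={dims} must be < {n} items")
    if method == "mds":
        mds = MDS(
            n_components=dims,
            metric="precomputed",
            init="random",
            random_state=seed,
            normalized_stress=False,
            n_init=4,
        )
        coords = mds.fit_transform(d)
        quality = float(mds.stress_)
    elif method == "pca":
        sq = d**2
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ sq @ j
        w, v = np.linalg.eigh(b)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        pos = np.clip(w, 0, None)
        coords = v[:, :dims] * np.sqrt(pos[:dims])
        total = pos.sum()
        quality = float(pos[:dims].sum() / total) if total > 0 else 1.0
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    frame = pd.DataFrame(coords, index=ids,
                         columns=[f"dim{i + 1}" for i in range(dims)])
    return frame, quality
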