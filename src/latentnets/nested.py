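"""The network of networks: comparing whole latent networks across series.

Each per-series latent network A_k is lifted to an SPD matrix through its
regularized graph Laplacian L_k = (D_k - A_k) + lambda*I.  Two comparison
strategies are provided:

* ``"tangent"`` (default) — compute the Karcher mean of the L_k under the
  affine-invariant metric, log-map every L_k to the tangent space at that
  reference point, and take Frobenius distances there.  The tangent space is a
  genuine vector space, so the resulting K x K matrix B is a valid Euclidean
  distance matrix.
* ``"manifold"`` — geodesic distances between the L_k directly on the SPD
  manifold.

When the series carry class labels, :func:`separation_report` quantifies how
well B clusters them (mean within- vs between-class distance and the
silhouette score).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from sklearn.metrics import silhouette_score

from .manifold import (
    TangentVector,
    geodesic_distance,
    log_map,
    reference_mean,
    regularized_laplacian,
)
from .network import LatentNetwork

__all__ = [
    "NestedNetwork",
    "SeparationReport",
    "build_nested",
    "tangent_distance",
    "default_lambda",
    "separation_report",
    "write_distance_csv",
    "write_nested_graphml",
    "write_report_json",
]


@dataclass(frozen=True)
class NestedNetwork:
    """K x K distance structure over per-series latent networks."""

    distances: np.ndarray
    labels: np.ndarray
    tangent_vectors: tuple[TangentVector, ...] | None
    reference: np.ndarray | None
    lambda_used: float
    strategy: str
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        B = np.asarray(self.distances, dtype=float)
        K = B.shape[0]
        if B.ndim != 2 or B.shape != (K, K):
            raise ValueError("distances must be square")
        if np.max(np.abs(B - B.T)) > 1e-8 * max(1.0, float(np.abs(B).max())):
            raise ValueError("distances must be symmetric")
        object.__setattr__(self, "distances", 0.5 * (B + B.T))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if self.labels.size != K:
            raise ValueError("one label per series is required")

    @property
    def K(self) -> int:
        return self.distances.shape[0]


@dataclass(frozen=True)
class SeparationReport:
    mean_within: float
    mean_between: float
    silhouette: float


def default_lambda(networks: list[LatentNetwork]) -> float:
    """1e-3 times the mean node degree across all networks, floored at 1e-6.

    Scales the Laplacian ridge to the data so the regularization is small
    relative to typical degrees regardless of the weight scale.
    """
    mean_degree = float(np.mean([net.weights.sum(axis=1).mean() for net in networks]))
    return max(1e-3 * mean_degree, 1e-6)


def tangent_distance(yi: TangentVector, yj: TangentVector) -> float:
    """Distance between tangent vectors in the metric at their reference.

    The Frobenius norm of the whitened difference M^{-1/2}(yi - yj)M^{-1/2},
    i.e. the affine-invariant inner product on the tangent space; with this
    choice the norm of a single log-mapped point equals its geodesic distance
    from the reference.
    """
    if yi.entries.shape != yj.entries.shape:
        raise ValueError("tangent vectors must share a dimension")
    if not np.allclose(yi.reference, yj.reference, rtol=0, atol=1e-10):
        raise ValueError("tangent vectors live at different reference points")
    return float(np.linalg.norm(yi.whitened - yj.whitened))


def build_nested(
    networks: list[LatentNetwork],
    labels,
    lam: float | None = None,
    strategy: str = "tangent",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NestedNetwork:
    """Build the K x K network-of-networks distance matrix B."""
    K = len(networks)
    if K < 2:
        raise ValueError("need at least 2 latent networks")
    M = networks[0].M
    if any(net.M != M for net in networks):
        raise ValueError("all latent networks must have the same number of nodes")
    labels = np.asarray(labels, dtype=int)
    if labels.size != K:
        raise ValueError(f"expected {K} labels, got {labels.size}")
    if lam is None:
        lam = default_lambda(networks)
    if not lam > 0:
        raise ValueError("lambda must be positive")

    Ls = [regularized_laplacian(net.weights, lam) for net in networks]
    ids = tuple(net.source_id for net in networks)
    B = np.zeros((K, K))
    if strategy == "tangent":
        Mref = reference_mean(Ls, tol=tol, max_iter=max_iter)
        ys = tuple(log_map(L, Mref) for L in Ls)
        for i in range(K):
            for j in range(i + 1, K):
                B[i, j] = B[j, i] = tangent_distance(ys[i], ys[j])
        return NestedNetwork(
            distances=B, labels=labels, tangent_vectors=ys, reference=Mref,
            lambda_used=float(lam), strategy=strategy, ids=ids,
        )
    elif strategy == "manifold":
        for i in range(K):
            for j in range(i + 1, K):
                B[i, j] = B[j, i] = geodesic_distance(Ls[i], Ls[j])
        return NestedNetwork(
            distances=B, labels=labels, tangent_vectors=None, reference=None,
            lambda_used=float(lam), strategy=strategy, ids=ids,
        )
    raise ValueError(f"unknown strategy {strategy!r}")


def separation_report(nested: NestedNetwork) -> SeparationReport:
    """Class-separation diagnostics of B: within/between means and silhouette.

    Pairs within a singleton class contribute only to the between-class mean.
    """
    labels = nested.labels
    if np.unique(labels).size < 2:
        raise ValueError("separation_report needs at least 2 classes")
    B = nested.distances
    K = nested.K
    iu = np.triu_indices(K, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    within = B[iu][same]
    between = B[iu][~same]
    sil = float(silhouette_score(B, labels, metric="precomputed"))
    return SeparationReport(
        mean_within=float(within.mean()) if within.size else float("nan"),
        mean_between=float(between.mean()),
        silhouette=sil,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_distance_csv(nested: NestedNetwork, path: str | Path) -> None:
    np.savetxt(Path(path), nested.distances, delimiter=",", fmt="%.12g")


def write_nested_graphml(nested: NestedNetwork, path: str | Path) -> None:
    G = nx.Graph(strategy=nested.strategy, lambda_used=nested.lambda_used)
    for k in range(nested.K):
        sid = nested.ids[k] if nested.ids else str(k)
        G.add_node(k, label=int(nested.labels[k]), id=sid)
    for i in range(nested.K):
        for j in range(i + 1, nested.K):
            G.add_edge(i, j, weight=float(nested.distances[i, j]))
    nx.write_graphml(G, str(path))


def write_report_json(report: SeparationReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "mean_within": report.mean_within,
                "mean_between": report.mean_between,
                "silhouette": report.silhouette,
            },
            indent=2,
        )
        + "\n"
    )
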