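"""Per-series latent networks: adjacency construction, thresholding, and I/O.

The latent network of one series has the M latent univariate Gaussians as
nodes and the affine-invariant geodesic distance between their 2x2 SPD
embeddings as edge weights.  Thresholding keeps the strongest edges, either by
an explicit cut-off tau (entries strictly greater than tau survive) or by a
retained fraction q of the M(M-1)/2 undirected edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .manifold import GaussianNode, embed_gaussian, geodesic_distance
from .vae import LatentGaussianSet

__all__ = [
    "LatentNetwork",
    "build_adjacency",
    "apply_threshold",
    "threshold_by_fraction",
    "similarity_transform",
    "to_graph",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
    "write_adjacency_csv",
    "read_adjacency_csv",
]


@dataclass(frozen=True)
class LatentNetwork:
    """Weighted undirected graph over the M latent Gaussian nodes."""

    weights: np.ndarray
    nodes: tuple[GaussianNode, ...]
    source_id: str = ""
    threshold_applied: float | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        M = W.shape[0]
        if W.ndim != 2 or W.shape != (M, M) or M < 2:
            raise ValueError("weights must be a square matrix with M >= 2")
        if np.max(np.abs(W - W.T)) > 1e-10 * max(1.0, float(np.abs(W).max())):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("weights must have a zero diagonal")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        if len(self.nodes) != M:
            raise ValueError("node list length must match weight matrix size")
        object.__setattr__(self, "weights", 0.5 * (W + W.T))
        object.__setattr__(self, "nodes", tuple(self.nodes))

    @property
    def M(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.M, k=1)
        return int(np.count_nonzero(self.weights[iu]))


def build_adjacency(
    latent: LatentGaussianSet, squared: bool = False, sigma_as_variance: bool = False
) -> LatentNetwork:
    """Pairwise geodesic distances between the embedded latent Gaussians.

    ``sigma_as_variance`` places the encoder's std directly in the variance
    slot of the embedding (a sensitivity check; default squares it).
    """
    if latent.M < 2:
        raise ValueError("need at least 2 latent dimensions to build a network")
    nodes = []
    for i, (mu, sd) in enumerate(zip(latent.means, latent.stds)):
        if sd <= 0:
            raise ValueError(f"latent dimension {i} has nonpositive std")
        v = float(sd) if sigma_as_variance else float(sd) ** 2
        nodes.append(GaussianNode(mean=float(mu), variance=v, index=i))
    P = [embed_gaussian(n) for n in nodes]
    M = len(nodes)
    W = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            W[i, j] = W[j, i] = geodesic_distance(P[i], P[j], squared=squared)
    return LatentNetwork(weights=W, nodes=tuple(nodes), source_id=latent.source_id)


def apply_threshold(net: LatentNetwork, tau: float) -> LatentNetwork:
    """Keep entries strictly greater than tau; everything else becomes 0."""
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    W = np.where(net.weights > tau, net.weights, 0.0)
    np.fill_diagonal(W, 0.0)
    return replace(net, weights=W, threshold_applied=float(tau))


def threshold_by_fraction(
    net: LatentNetwork, keep_fraction: float, mode: str = "distance"
) -> LatentNetwork:
    """Retain a fraction q of the undirected edges.

    tau is the (1-q) linear-interpolation quantile of the upper-triangle
    weights and edges with weight >= tau are kept, so edges tied exactly at
    the threshold all survive.  ``mode="similarity"`` keeps the *smallest*
    distances instead (tau becomes the q-quantile, weights <= tau kept).
    """
    q = keep_fraction
    if not 0 < q <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    iu = np.triu_indices(net.M, k=1)
    w = net.weights[iu]
    if mode == "distance":
        tau = float(np.quantile(w, 1.0 - q))
        keep = net.weights >= tau
    elif mode == "similarity":
        tau = float(np.quantile(w, q))
        keep = net.weights <= tau
    else:
        raise ValueError(f"unknown mode {mode!r}")
    W = np.where(keep, net.weights, 0.0)
    np.fill_diagonal(W, 0.0)
    return replace(net, weights=W, threshold_applied=tau)


def similarity_transform(net: LatentNetwork, scale: float | None = None) -> LatentNetwork:
    """Gaussian-kernel similarity weights w -> exp(-w^2 / (2 s^2)) on existing edges."""
    iu = np.triu_indices(net.M, k=1)
    w = net.weights[iu]
    if scale is None:
        nz = w[w > 0]
        scale = float(np.median(nz)) if nz.size else 1.0
    if scale <= 0:
        raise ValueError("scale must be positive")
    W = np.where(net.weights > 0, np.exp(-(net.weights**2) / (2 * scale**2)), 0.0)
    np.fill_diagonal(W, 0.0)
    return replace(net, weights=W)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def to_graph(net: LatentNetwork) -> nx.Graph:
    G = nx.Graph(source_id=net.source_id)
    for n in net.nodes:
        G.add_node(n.index, mu=n.mean, sigma=float(np.sqrt(n.variance)))
    iu = np.triu_indices(net.M, k=1)
    for i, j in zip(*iu):
        w = net.weights[i, j]
        if w > 0:
            G.add_edge(int(i), int(j), weight=float(w))
    return G


def write_graphml(net: LatentNetwork, path: str | Path) -> None:
    nx.write_graphml(to_graph(net), str(path))


def write_edge_list(net: LatentNetwork, path: str | Path) -> None:
    """Tab-separated rows: node_i, node_j, weight (upper triangle, nonzero)."""
    iu = np.triu_indices(net.M, k=1)
    with Path(path).open("w") as fh:
        for i, j in zip(*iu):
            w = net.weights[i, j]
            if w > 0:
                fh.write(f"{i}\t{j}\t{w:.12g}\n")


def read_edge_list(path: str | Path, M: int | None = None) -> np.ndarray:
    """Read an edge list back into a dense symmetric adjacency array."""
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                i, j, w = line.split("\t")
                rows.append((int(i), int(j), float(w)))
    if M is None:
        M = max(max(i, j) for i, j, _ in rows) + 1 if rows else 0
    W = np.zeros((M, M))
    for i, j, w in rows:
        W[i, j] = W[j, i] = w
    return W


def write_adjacency_csv(net: LatentNetwork, path: str | Path) -> None:
    np.savetxt(Path(path), net.weights, delimiter=",", fmt="%.12g")


def read_adjacency_csv(path: str | Path) -> np.ndarray:
    W = np.loadtxt(Path(path), delimiter=",")
    return np.atleast_2d(W)
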