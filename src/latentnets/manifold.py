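"""SPD-manifold mathematics for Gaussian embeddings and latent networks.

A D-dimensional Gaussian N(mu, Sigma) is embedded as the (D+1)x(D+1) symmetric
positive-definite (SPD) matrix

    P = (det Sigma)^(-2/(D+1)) [[Sigma + mu mu^T, mu], [mu^T, 1]],

so in the univariate case (variance v = sigma^2)

    P = v^(-1) [[v + mu^2, mu], [mu, 1]].

Distances between embedded distributions use the affine-invariant Riemannian
metric (AIRM): d(P, Q) = ||log(P^{-1/2} Q P^{-1/2})||_F, computable from the
eigenvalues of P^{-1} Q.  The same metric underlies the Karcher mean and the
log-map to the tangent space used for the network-of-networks stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "GaussianNode",
    "TangentVector",
    "check_spd",
    "is_spd",
    "embed_gaussian",
    "embed_multivariate",
    "spd_log",
    "spd_exp",
    "spd_sqrt",
    "spd_inv_sqrt",
    "geodesic_distance",
    "regularized_laplacian",
    "reference_mean",
    "log_map",
    "exp_map",
]

# eigenvalues below this are treated as a violation of positive-definiteness
EIG_FLOOR = 1e-12
SYM_TOL = 1e-10


@dataclass(frozen=True)
class GaussianNode:
    """One univariate latent Gaussian N(mean, variance)."""

    mean: float
    variance: float
    index: int = 0

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"node {self.index}: variance must be positive")


@dataclass(frozen=True)
class TangentVector:
    """A symmetric matrix in the tangent space at a reference SPD point."""

    entries: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        if e.shape != r.shape:
            raise ValueError("tangent vector and reference must share a shape")
        object.__setattr__(self, "entries", e)
        object.__setattr__(self, "reference", r)

    @property
    def whitened(self) -> np.ndarray:
        """M^{-1/2} Y M^{-1/2}: coordinates of the tangent vector in the
        affine-invariant inner product at the reference point."""
        Mih = spd_inv_sqrt(self.reference)
        return Mih @ self.entries @ Mih

    @property
    def norm(self) -> float:
        """Riemannian norm at the reference; equals the geodesic distance to
        the point this vector log-maps back to."""
        return float(np.linalg.norm(self.whitened))


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


def check_spd(P: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate symmetry and positive-definiteness; return the symmetrized array."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"{name} must be square, got shape {P.shape}")
    if not np.all(np.isfinite(P)):
        raise ValueError(f"{name} contains non-finite entries")
    asym = np.max(np.abs(P - P.T)) if P.size else 0.0
    scale = max(1.0, float(np.max(np.abs(P))))
    if asym > SYM_TOL * scale:
        raise ValueError(f"{name} is not symmetric (max asymmetry {asym:.3g})")
    P = _symmetrize(P)
    w = np.linalg.eigvalsh(P)
    if w.min() < EIG_FLOOR:
        raise ValueError(
            f"{name} is not positive definite (min eigenvalue {w.min():.3g})"
        )
    return P


def is_spd(P: np.ndarray) -> bool:
    try:
        check_spd(P)
        return True
    except ValueError:
        return False


def embed_gaussian(node: GaussianNode | tuple[float, float]) -> np.ndarray:
    """Embed a univariate Gaussian as a 2x2 SPD matrix.

    ``node`` may be a :class:`GaussianNode` or a ``(mean, variance)`` pair.
    """
    if not isinstance(node, GaussianNode):
        node = GaussianNode(mean=float(node[0]), variance=float(node[1]))
    mu, v = node.mean, node.variance
    return (1.0 / v) * np.array([[v + mu * mu, mu], [mu, 1.0]])


def embed_multivariate(mean: np.ndarray, covariance: np.ndarray) -> np.ndarray:
    """Embed N(mean, covariance) as a (d+1)x(d+1) SPD matrix."""
    mu = np.atleast_1d(np.asarray(mean, dtype=float))
    Sigma = check_spd(np.atleast_2d(covariance), "covariance")
    d = mu.size
    if Sigma.shape != (d, d):
        raise ValueError("mean and covariance dimensions disagree")
    P = np.empty((d + 1, d + 1))
    P[:d, :d] = Sigma + np.outer(mu, mu)
    P[:d, d] = mu
    P[d, :d] = mu
    P[d, d] = 1.0
    sign, logdet = np.linalg.slogdet(Sigma)
    return np.exp(-2.0 / (d + 1) * logdet) * P


def _eig_fn(P: np.ndarray, fn, name: str, require_pd: bool) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    P = _symmetrize(P)
    w, U = np.linalg.eigh(P)
    if require_pd and w.min() < EIG_FLOOR:
        raise ValueError(f"{name}: eigenvalue {w.min():.3g} below floor {EIG_FLOOR}")
    return _symmetrize((U * fn(w)) @ U.T)


def spd_log(P: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (symmetric result)."""
    return _eig_fn(P, np.log, "spd_log", require_pd=True)


def spd_sqrt(P: np.ndarray) -> np.ndarray:
    """Principal square root of an SPD matrix."""
    return _eig_fn(P, np.sqrt, "spd_sqrt", require_pd=True)


def spd_inv_sqrt(P: np.ndarray) -> np.ndarray:
    """P^{-1/2} for SPD P."""
    return _eig_fn(P, lambda w: 1.0 / np.sqrt(w), "spd_inv_sqrt", require_pd=True)


def spd_exp(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix; result is SPD."""
    S = np.asarray(S, dtype=float)
    if np.max(np.abs(S - S.T)) > SYM_TOL * max(1.0, float(np.max(np.abs(S))) if S.size else 1.0):
        raise ValueError("spd_exp expects a symmetric matrix")
    return _eig_fn(S, np.exp, "spd_exp", require_pd=False)


def geodesic_distance(Pi: np.ndarray, Pj: np.ndarray, squared: bool = False) -> float:
    """Affine-invariant geodesic distance between SPD matrices.

    Computed from the generalized eigenvalues lambda of (Pj, Pi), i.e. the
    eigenvalues of Pi^{-1} Pj:  d = sqrt(sum log^2 lambda).  With
    ``squared=True`` the square root is omitted.
    """
    Pi = check_spd(Pi, "Pi")
    Pj = check_spd(Pj, "Pj")
    if Pi.shape != Pj.shape:
        raise ValueError(f"dimension mismatch: {Pi.shape} vs {Pj.shape}")
    lam = scipy.linalg.eigvalsh(Pj, Pi)
    lam = np.maximum(lam, EIG_FLOOR)
    d2 = float(np.sum(np.log(lam) ** 2))
    return d2 if squared else float(np.sqrt(d2))


def regularized_laplacian(A: np.ndarray, lam: float) -> np.ndarray:
    """Graph Laplacian of a weighted adjacency plus a ridge: (D - A) + lam*I.

    A must be symmetric with nonnegative weights and a zero diagonal; the
    Laplacian is positive semidefinite, so any lam > 0 yields an SPD matrix.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.max(np.abs(A - A.T)) > SYM_TOL * max(1.0, float(np.max(np.abs(A))) if A.size else 1.0):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency weights must be nonnegative")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if not lam > 0:
        raise ValueError("regularization lambda must be positive")
    D = np.diag(A.sum(axis=1))
    return D - A + lam * np.eye(A.shape[0])


def log_map(Lk: np.ndarray, Mref: np.ndarray) -> TangentVector:
    """Riemannian log-map at Mref:  M^{1/2} log(M^{-1/2} Lk M^{-1/2}) M^{1/2}."""
    Lk = check_spd(Lk, "Lk")
    Mref = check_spd(Mref, "Mref")
    if Lk.shape != Mref.shape:
        raise ValueError("log_map: dimension mismatch")
    Mh = spd_sqrt(Mref)
    Mih = spd_inv_sqrt(Mref)
    Y = Mh @ spd_log(Mih @ Lk @ Mih) @ Mh
    return TangentVector(entries=_symmetrize(Y), reference=Mref)


def exp_map(Y: TangentVector | np.ndarray, Mref: np.ndarray | None = None) -> np.ndarray:
    """Inverse of :func:`log_map` at the same reference point."""
    if isinstance(Y, TangentVector):
        entries, Mref = Y.entries, Y.reference
    else:
        if Mref is None:
            raise ValueError("exp_map needs a reference point")
        entries = np.asarray(Y, dtype=float)
    Mref = check_spd(Mref, "Mref")
    Mh = spd_sqrt(Mref)
    Mih = spd_inv_sqrt(Mref)
    return _symmetrize(Mh @ spd_exp(Mih @ entries @ Mih) @ Mh)


def reference_mean(
    mats: list[np.ndarray], tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """Karcher (Frechet) mean of SPD matrices under the affine-invariant metric.

    Fixed-point iteration M <- exp_M(mean_k log_M(L_k)), initialized at the
    log-Euclidean mean; at convergence the tangent-space mean of the log-maps
    vanishes (gradient condition of the Frechet variance).
    """
    if len(mats) == 0:
        raise ValueError("reference_mean needs at least one matrix")
    mats = [check_spd(P, f"mats[{i}]") for i, P in enumerate(mats)]
    d = mats[0].shape[0]
    if any(P.shape != (d, d) for P in mats):
        raise ValueError("reference_mean: matrices must share a dimension")
    if len(mats) == 1:
        return mats[0]
    M = spd_exp(np.mean([spd_log(P) for P in mats], axis=0))
    for _ in range(max_iter):
        Mh = spd_sqrt(M)
        Mih = spd_inv_sqrt(M)
        T = np.mean([spd_log(Mih @ P @ Mih) for P in mats], axis=0)
        # tangent residual measured in the AIRM norm at M
        resid = float(np.linalg.norm(T))
        if resid < tol:
            return _symmetrize(M)
        M = _symmetrize(Mh @ spd_exp(T) @ Mh)
    raise RuntimeError(
        f"Karcher mean did not converge in {max_iter} iterations "
        f"(residual {resid:.3g} > tol {tol:.3g})"
    )
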