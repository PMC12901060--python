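"""Connectivity-gradient extraction.

Pipeline: row-wise sparsification of the FC matrix, an affinity kernel
(gaussian / cosine / normalized_angle / pearson / spearman / none), and one
of three spectral dimensionality reductions — diffusion map embedding
("dm"), principal component analysis ("pca"), or Laplacian eigenmaps
("le").  Components carry a deterministic sign convention (largest-|entry|
positive) so that repeated extraction is bit-reproducible; cross-subject
sign and order differences are left for Procrustes alignment to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from .datatypes import ConnectivityMatrix, GradientSet

__all__ = [
    "AffinityMatrix",
    "sparsify_rows",
    "affinity",
    "diffusion_map",
    "pca_embed",
    "laplacian_eigenmaps",
    "extract_gradients",
    "GradientMaps",
]

KERNELS = ("gaussian", "cosine", "normalized_angle", "pearson", "spearman", "none")
APPROACHES = ("dm", "pca", "le")

_EIGENVALUE_FLOOR = 1e-12


@dataclass
class AffinityMatrix:
    """Symmetric parcel-by-parcel affinity matrix produced by a kernel."""

    values: np.ndarray
    kernel_name: str = "normalized_angle"
    gamma: Optional[float] = None
    sparsity: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("affinity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("affinity matrix is not symmetric (tol 1e-8)")
        self.values = (self.values + self.values.T) / 2.0

    def clipped(self) -> np.ndarray:
        """Non-negative copy for spectral methods (negatives clipped to 0)."""
        return np.clip(self.values, 0.0, None)


def sparsify_rows(fc: ConnectivityMatrix | np.ndarray, sparsity: float) -> np.ndarray:
    """Zero out, independently per row, entries strictly below the row's
    ``sparsity`` quantile.  Surviving entries keep their values; the result
    need not be symmetric."""
    if not 0 <= sparsity < 1:
        raise ValueError(f"sparsity must lie in [0, 1), got {sparsity}")
    values = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
    if sparsity == 0:
        return values.copy()
    thresh = np.quantile(values, sparsity, axis=1, keepdims=True)
    out = values.copy()
    out[values < thresh] = 0.0
    return out


def _rowwise_kernel(matrix: np.ndarray, kernel_name: str,
                    gamma: Optional[float]) -> np.ndarray:
    x = np.asarray(matrix, dtype=float)
    p = x.shape[0]
    if kernel_name == "gaussian":
        g = 1.0 / x.shape[1] if gamma is None else float(gamma)
        sq = (x ** 2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * x @ x.T
        return np.exp(-g * np.clip(d2, 0.0, None))
    if kernel_name in ("cosine", "normalized_angle", "pearson"):
        if kernel_name == "pearson":
            x = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(x, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(
                f"zero-norm row(s) {bad[:5].tolist()} — cosine-family kernel undefined")
        c = (x @ x.T) / np.outer(norms, norms)
        c = np.clip(c, -1.0, 1.0)
        if kernel_name == "normalized_angle":
            return 1.0 - np.arccos(c) / np.pi
        return c
    if kernel_name == "spearman":
        ranks = stats.rankdata(x, axis=1)
        return _rowwise_kernel(ranks, "pearson", None)
    if kernel_name == "none":
        return x.copy()
    raise ValueError(f"unknown kernel {kernel_name!r}; choose from {KERNELS}")


def affinity(matrix: np.ndarray, kernel_name: str = "normalized_angle",
             gamma: Optional[float] = None, sparsity: float = 0.0) -> AffinityMatrix:
    """Affinity between sparsified row vectors under the named kernel.

    gaussian: exp(-gamma * ||x - y||^2), gamma defaulting to 1/P;
    cosine: x·y / (||x|| ||y||);
    normalized_angle: 1 - arccos(cossim)/pi;
    pearson: cosine of mean-centered rows;
    spearman: pearson of within-row ranks;
    none: pass-through.
    """
    a = _rowwise_kernel(np.asarray(matrix, float), kernel_name, gamma)
    return AffinityMatrix(values=a, kernel_name=kernel_name, gamma=gamma,
                          sparsity=sparsity)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Orient each component so its maximum-|value| entry is positive; ties
    broken by lowest parcel index (np.argmax convention)."""
    out = components.copy()
    for k in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, k])))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


def _check_connected(w: np.ndarray) -> None:
    """Breadth-first search over the positive support of the affinity graph."""
    p = w.shape[0]
    adj = w > 0
    np.fill_diagonal(adj, True)
    seen = np.zeros(p, dtype=bool)
    frontier = np.zeros(p, dtype=bool)
    frontier[0] = True
    while frontier.any():
        seen |= frontier
        frontier = adj[frontier].any(axis=0) & ~seen
    if not seen.all():
        raise ValueError(
            "affinity graph is disconnected; lower the sparsity or use a "
            "kernel with wider support")


def diffusion_map(aff: AffinityMatrix, n_components: int = 10) -> GradientSet:
    """Diffusion map embedding of a non-negative symmetric affinity matrix.

    Anisotropic normalization with alpha = 0.5 (W = D^-a A D^-a), row
    normalization to a Markov transition operator, eigendecomposition via the
    symmetric similarity transform, removal of the trivial constant
    eigenvector, and automatic diffusion-time scaling of the remaining
    eigenvectors by lambda / (1 - lambda).
    """
    w = aff.clipped()
    _check_connected(w)
    d = w.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("affinity matrix has an all-zero row")
    inv_sqrt_like = d ** -0.5  # alpha = 0.5
    l_mat = w * np.outer(inv_sqrt_like, inv_sqrt_like)
    d2 = l_mat.sum(axis=1)
    # symmetric similarity of the row-normalized operator M = D2^-1 L
    d2_inv_sqrt = d2 ** -0.5
    s = l_mat * np.outer(d2_inv_sqrt, d2_inv_sqrt)
    s = (s + s.T) / 2.0
    evals, evecs = linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of M; the leading one is constant (eigenvalue 1)
    vecs = evecs * d2_inv_sqrt[:, None]
    lam = np.clip(evals[1:], None, 1.0 - 1e-12)
    vecs = vecs[:, 1:]
    keep = lam > _EIGENVALUE_FLOOR
    lam, vecs = lam[keep], vecs[:, keep]
    if lam.size < n_components:
        raise ValueError(
            f"only {lam.size} non-degenerate components available, "
            f"requested {n_components}")
    lam = lam[:n_components]
    vecs = vecs[:, :n_components] * (lam / (1.0 - lam))[None, :]
    return GradientSet(
        components=_fix_signs(vecs),
        eigenvalues=lam,
        method="dm",
        params={"kernel": aff.kernel_name, "sparsity": aff.sparsity,
                "gamma": aff.gamma, "alpha": 0.5},
    )


def pca_embed(matrix: np.ndarray, n_components: int = 10) -> GradientSet:
    """PCA scores of the (column-centered) input matrix.

    Rows are observations (parcels); eigenvalues are the explained variances
    in descending order.
    """
    x = np.asarray(matrix, dtype=float)
    p = x.shape[0]
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _vt = linalg.svd(xc, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    explained = (s[:n_components] ** 2) / (p - 1)
    return GradientSet(
        components=_fix_signs(scores),
        eigenvalues=explained,
        method="pca",
        params={},
    )


def laplacian_eigenmaps(aff: AffinityMatrix, n_components: int = 10) -> GradientSet:
    """Laplacian eigenmaps: generalized eigenproblem L v = lambda D v with
    L = D - A.  The trivial constant eigenvector (lambda = 0) is dropped and
    the ``n_components`` eigenvectors of smallest nonzero eigenvalue are
    returned, smallest (most important) first."""
    w = aff.clipped()
    _check_connected(w)
    d = w.sum(axis=1)
    lap = np.diag(d) - w
    evals, evecs = linalg.eigh(lap, np.diag(d))
    order = np.argsort(evals)
    evals, evecs = evals[order], evecs[:, order]
    # drop the lambda ~ 0 kernel of L (constant vector on a connected graph)
    evals, evecs = evals[1:], evecs[:, 1:]
    keep = evals > _EIGENVALUE_FLOOR
    evals, evecs = evals[keep], evecs[:, keep]
    if evals.size < n_components:
        raise ValueError(
            f"only {evals.size} non-degenerate components available, "
            f"requested {n_components}")
    return GradientSet(
        components=_fix_signs(evecs[:, :n_components]),
        eigenvalues=evals[:n_components],
        method="le",
        params={"kernel": aff.kernel_name, "sparsity": aff.sparsity,
                "gamma": aff.gamma},
    )


def extract_gradients(fc: ConnectivityMatrix,
                      kernel_name: str = "normalized_angle",
                      sparsity: float = 0.9,
                      approach: str = "dm",
                      n_components: int = 20,
                      gamma: Optional[float] = None) -> GradientSet:
    """Full extraction: sparsify_rows -> affinity -> spectral reduction."""
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; choose from {APPROACHES}")
    sp = sparsify_rows(fc, sparsity)
    aff = affinity(sp, kernel_name=kernel_name, gamma=gamma, sparsity=sparsity)
    if approach == "dm":
        grads = diffusion_map(aff, n_components)
    elif approach == "le":
        grads = laplacian_eigenmaps(aff, n_components)
    else:
        grads = pca_embed(aff.values, n_components)
        grads.params.update({"kernel": kernel_name, "sparsity": sparsity,
                             "gamma": gamma})
    grads.params.update({"approach": approach})
    return grads


class GradientMaps(BaseEstimator):
    """Scikit-learn style estimator for connectivity-gradient extraction.

    Parameters
    ----------
    kernel : str, default="normalized_angle"
        Affinity kernel applied to the sparsified FC rows.
    sparsity : float, default=0.9
        Row-wise quantile below which FC entries are zeroed.
    approach : {"dm", "pca", "le"}, default="dm"
        Spectral dimensionality reduction.
    n_components : int, default=20
        Number of gradients returned.
    gamma : float or None
        Inverse gaussian kernel width (1/P when None).

    Attributes
    ----------
    gradients_ : ndarray of shape (P, n_components)
    eigenvalues_ : ndarray of shape (n_components,)
    """

    def __init__(self, kernel: str = "normalized_angle", sparsity: float = 0.9,
                 approach: str = "dm", n_components: int = 20,
                 gamma: Optional[float] = None):
        self.kernel = kernel
        self.sparsity = sparsity
        self.approach = approach
        self.n_components = n_components
        self.gamma = gamma

    def fit(self, X, y=None) -> "GradientMaps":
        """Extract gradients from a P x P connectivity matrix ``X``."""
        fc = X if isinstance(X, ConnectivityMatrix) else ConnectivityMatrix(np.asarray(X, float))
        gs = extract_gradients(fc, kernel_name=self.kernel, sparsity=self.sparsity,
                               approach=self.approach, n_components=self.n_components,
                               gamma=self.gamma)
        self.gradient_set_ = gs
        self.gradients_ = gs.components
        self.eigenvalues_ = gs.eigenvalues
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).gradients_
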