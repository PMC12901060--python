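"""Orthogonal Procrustes alignment of gradient sets and its diagnostics.

Given a subject gradient matrix A (P parcels x n gradients) and a reference
B of the same shape, the orthogonal Procrustes problem finds the n x n
orthogonal matrix T minimizing ||A T - B||_F.  The closed-form solution
(Schönemann) is T = U V' where U S V' is the SVD of the cross-covariance
C = (B' A)' = A' B.  No centering and no isotropic scaling are applied, and
no iterative (generalized) refinement is performed: the alignment is a pure
one-shot rotation/reflection of the gradient basis.

Scalar diagnostics of the fitted transform:

- correspondence c = max_i |t_i1| / sum_i |t_i1| — how much the aligned
  principal gradient is dominated by a single unaligned gradient;
- trans_total = sum_ij |t_ij| and trans_pg = sum_i |t_i1| — heuristic
  transformation magnitudes (whole matrix / principal-gradient column);
- w_norm = ||w||_2, the l2-norm of the singular values of C;
- theta_norm = ||Theta||_2, the l2-norm of the principal angles between the
  column spans of A and B (Björck-Golub definition on orthonormalized
  bases).  w_norm and theta_norm are opposing indicators of subspace
  similarity: coincident subspaces give high w_norm and theta_norm = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import GradientSet

logger = logging.getLogger(__name__)

__all__ = [
    "ProcrustesResult",
    "AlignmentDiagnostics",
    "fit_procrustes",
    "apply_transform",
    "correspondence",
    "transformation_magnitudes",
    "subspace_similarity",
    "principal_angles",
    "align_to_reference",
    "ProcrustesAlignment",
]


@dataclass
class ProcrustesResult:
    """Fitted orthogonal Procrustes transform and its SVD factors."""

    transform: np.ndarray        # T = U V', n x n orthogonal
    singular_values: np.ndarray  # w, descending, >= 0
    cross_covariance: np.ndarray  # C = A' B
    u: np.ndarray
    v: np.ndarray                # right factor V (not transposed)
    n_align: int

    def __post_init__(self) -> None:
        t = np.asarray(self.transform, float)
        n = t.shape[0]
        if not np.allclose(t.T @ t, np.eye(n), atol=1e-8):
            raise ValueError("transform is not orthogonal (tol 1e-8)")


@dataclass
class AlignmentDiagnostics:
    """Scalar descriptors of one subject-to-reference alignment."""

    correspondence: float
    trans_total: float
    trans_pg: float
    w_norm: float
    theta_norm: float
    n_align: int

    def as_dict(self) -> dict:
        return {
            "correspondence": self.correspondence,
            "trans_total": self.trans_total,
            "trans_pg": self.trans_pg,
            "w_norm": self.w_norm,
            "theta_norm": self.theta_norm,
            "n_align": self.n_align,
        }


def _components(obj) -> np.ndarray:
    return obj.components if isinstance(obj, GradientSet) else np.asarray(obj, float)


def fit_procrustes(a, b) -> ProcrustesResult:
    """Solve the orthogonal Procrustes problem min_T ||A T - B||_F.

    ``a`` and ``b`` may be GradientSets or plain arrays of equal shape.
    The cross-covariance is C = (B'A)' = A'B; its SVD U S V' gives
    T = U V'.  Rank-deficient C still yields a valid (non-unique) T; a
    warning is logged.
    """
    a_mat, b_mat = _components(a), _components(b)
    if a_mat.shape != b_mat.shape:
        raise ValueError(f"shape mismatch: A {a_mat.shape} vs B {b_mat.shape}")
    c = a_mat.T @ b_mat  # = (B'A)'
    u, w, vt = linalg.svd(c)
    if w.size and w[-1] < 1e-12 * max(1.0, w[0]):
        logger.warning("rank-deficient cross-covariance; transform not unique")
    t = u @ vt
    return ProcrustesResult(
        transform=t,
        singular_values=w,
        cross_covariance=c,
        u=u,
        v=vt.T,
        n_align=a_mat.shape[1],
    )


def apply_transform(a: GradientSet | np.ndarray, result: ProcrustesResult):
    """Apply the fitted transform: A' = A T.  GradientSet metadata (including
    eigenvalues) is carried through with an ``aligned`` provenance flag."""
    a_mat = _components(a)
    if a_mat.shape[1] != result.transform.shape[0]:
        raise ValueError("component count does not match transform size")
    aligned = a_mat @ result.transform
    if isinstance(a, GradientSet):
        return replace(a, components=aligned,
                       params=dict(a.params, aligned=True))
    return aligned


def correspondence(result: ProcrustesResult) -> float:
    """c = max_i |t_i1| / sum_i |t_i1|: dominance of the single strongest
    unaligned gradient in the aligned principal gradient.  Always in
    [1/n, 1]; 1 means the aligned principal gradient is (a sign flip of) one
    unaligned gradient."""
    col = np.abs(result.transform[:, 0])
    total = col.sum()
    if total == 0:
        raise ValueError("all-zero first column: corrupted transform")
    return float(col.max() / total)


def transformation_magnitudes(result: ProcrustesResult) -> Tuple[float, float]:
    """(trans_total, trans_pg): sums of absolute entries of T over the whole
    matrix and over the first column."""
    t = np.abs(result.transform)
    return float(t.sum()), float(t[:, 0].sum())


def principal_angles(a, b) -> np.ndarray:
    """Principal angles between the column spans of A and B.

    Orthonormal bases Q_A, Q_B are obtained by reduced QR; the angles are
    arccos of the singular values of Q_A' Q_B, clipped to [0, 1] to absorb
    rounding.  Returned ascending (Björck-Golub convention).
    """
    a_mat, b_mat = _components(a), _components(b)
    for name, m in (("A", a_mat), ("B", b_mat)):
        if np.linalg.matrix_rank(m) < m.shape[1]:
            raise ValueError(f"rank-deficient gradient set {name}: principal "
                             "angles undefined")
    qa, _ = linalg.qr(a_mat, mode="economic")
    qb, _ = linalg.qr(b_mat, mode="economic")
    sv = linalg.svdvals(qa.T @ qb)
    return np.arccos(np.clip(sv, 0.0, 1.0))


def subspace_similarity(a, b, n_align: Optional[int] = None
                        ) -> Tuple[float, np.ndarray, float]:
    """(w_norm, theta_vector, theta_norm) between two gradient sets.

    w_norm uses the raw (un-orthonormalized) Procrustes singular values;
    theta uses orthonormalized bases.  Both are reported because they answer
    different questions: w_norm mixes subspace geometry with gradient
    scaling, theta is purely geometric.
    """
    a_mat, b_mat = _components(a), _components(b)
    if n_align is not None:
        a_mat, b_mat = a_mat[:, :n_align], b_mat[:, :n_align]
    res = fit_procrustes(a_mat, b_mat)
    theta = principal_angles(a_mat, b_mat)
    return (float(np.linalg.norm(res.singular_values)), theta,
            float(np.linalg.norm(theta)))


def align_to_reference(subject: GradientSet, reference: GradientSet,
                       n_align: int,
                       component_indices: Optional[Sequence[int]] = None
                       ) -> Tuple[GradientSet, ProcrustesResult, AlignmentDiagnostics]:
    """Align a subject gradient set to a reference over a component subset.

    By default the first ``n_align`` components of both sets are used; an
    explicit ordered ``component_indices`` (e.g. reversed cumulative
    {19, ..., k}) overrides this.  Returns the aligned set, the fitted
    transform, and all scalar diagnostics.
    """
    if component_indices is not None:
        idx = np.asarray(component_indices, dtype=int)
    else:
        if n_align < 1:
            raise ValueError("n_align must be >= 1")
        idx = np.arange(n_align)
    if idx.max() >= subject.n_components or idx.max() >= reference.n_components:
        raise ValueError(
            f"requested components {idx.max() + 1} exceed available "
            f"({subject.n_components} subject / {reference.n_components} reference)")
    sub = subject.select(idx)
    ref = reference.select(idx)
    result = fit_procrustes(sub, ref)
    aligned = apply_transform(sub, result)
    w_norm, _theta, theta_norm = subspace_similarity(sub, ref)
    trans_total, trans_pg = transformation_magnitudes(result)
    diags = AlignmentDiagnostics(
        correspondence=correspondence(result),
        trans_total=trans_total,
        trans_pg=trans_pg,
        w_norm=w_norm,
        theta_norm=theta_norm,
        n_align=int(idx.size),
    )
    return aligned, result, diags


class ProcrustesAlignment(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer wrapping the orthogonal alignment.

    ``fit(B)`` stores the reference; ``transform(A)`` fits T for A against
    the stored reference and returns A T.  Diagnostics for the most recent
    transform are kept in ``diagnostics_``.
    """

    def __init__(self, n_align: Optional[int] = None):
        self.n_align = n_align

    def fit(self, X, y=None) -> "ProcrustesAlignment":
        ref = _components(X)
        n = self.n_align if self.n_align is not None else ref.shape[1]
        self.reference_ = ref[:, :n].copy()
        return self

    def transform(self, X) -> np.ndarray:
        a = _components(X)[:, : self.reference_.shape[1]]
        result = fit_procrustes(a, self.reference_)
        trans_total, trans_pg = transformation_magnitudes(result)
        w_norm, _theta, theta_norm = subspace_similarity(a, self.reference_)
        self.result_ = result
        self.diagnostics_ = AlignmentDiagnostics(
            correspondence=correspondence(result),
            trans_total=trans_total,
            trans_pg=trans_pg,
            w_norm=w_norm,
            theta_norm=theta_norm,
            n_align=result.n_align,
        )
        return apply_transform(a, result)
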