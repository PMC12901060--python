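"""Connectome fingerprinting from the aligned principal gradient.

Identification accuracy: subject i in session A is "identified" if the
session-B principal gradient most correlated with theirs is their own.
Differential identifiability I_Diff = (I_self - I_other) x 100 compares the
mean within-subject correlation against the mean between-subject
correlation, optionally after Fisher r-to-z transforming every correlation
(which changes the metric's behaviour qualitatively — see the methods
note).  Both are swept over the number of gradients used in Procrustes
alignment and over all unordered session pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .connectivity import fisher_z
from .datatypes import GradientSet
from .procrustes import align_to_reference

logger = logging.getLogger(__name__)

__all__ = [
    "GradientBank",
    "IdentifiabilityResult",
    "identification_accuracy",
    "differential_identifiability",
    "sweep_identifiability",
]


@dataclass
class GradientBank:
    """Per-session database of principal gradients, one vector per subject."""

    session_id: str
    vectors: Dict[str, np.ndarray]
    n_align: int = 0
    provenance: Optional[dict] = None

    def __post_init__(self) -> None:
        if len(self.vectors) < 2:
            raise ValueError("a gradient bank needs at least 2 subjects")
        lengths = {v.size for v in self.vectors.values()}
        if len(lengths) != 1:
            raise ValueError("all principal-gradient vectors must share length")

    @property
    def subject_ids(self) -> List[str]:
        return sorted(self.vectors)

    def matrix(self) -> np.ndarray:
        """Subjects x parcels matrix in sorted subject order."""
        return np.vstack([self.vectors[s] for s in self.subject_ids])


@dataclass
class IdentifiabilityResult:
    session_pair: Tuple[str, str]
    n_align: int
    accuracy: float
    i_self: float
    i_other: float
    i_diff: float
    fisher_z_applied: bool


def _cross_correlation(bank_a: GradientBank, bank_b: GradientBank) -> np.ndarray:
    if bank_a.subject_ids != bank_b.subject_ids:
        raise ValueError("mismatched subject sets between banks")
    a = bank_a.matrix()
    b = bank_b.matrix()
    a = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    b = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return np.clip(a @ b.T / a.shape[1], -1.0, 1.0)


def _directional_accuracy(corr: np.ndarray) -> float:
    n = corr.shape[0]
    best = np.argmax(corr, axis=1)  # ties resolve to the lowest index
    for i in range(n):
        row = corr[i]
        if np.sum(row == row[best[i]]) > 1:
            logger.warning("identification tie for subject index %d; "
                           "lowest index wins", i)
    return float(np.mean(best == np.arange(n)))


def identification_accuracy(bank_a: GradientBank, bank_b: GradientBank) -> float:
    """Mean of the two directional identification proportions (a->b, b->a)."""
    corr = _cross_correlation(bank_a, bank_b)
    return (_directional_accuracy(corr) + _directional_accuracy(corr.T)) / 2.0


def differential_identifiability(bank_a: GradientBank, bank_b: GradientBank,
                                 fisher_z_applied: bool = False
                                 ) -> IdentifiabilityResult:
    """I_Diff = (I_self - I_other) x 100 over the cross-session correlation
    matrix; I_other averages both off-diagonal triangles (ordered pairs)."""
    corr = _cross_correlation(bank_a, bank_b)
    if fisher_z_applied:
        corr = np.asarray(fisher_z(corr))
    n = corr.shape[0]
    diag = np.trace(corr) / n
    off = (corr.sum() - np.trace(corr)) / (n * (n - 1))
    return IdentifiabilityResult(
        session_pair=(bank_a.session_id, bank_b.session_id),
        n_align=bank_a.n_align,
        accuracy=identification_accuracy(bank_a, bank_b),
        i_self=float(diag),
        i_other=float(off),
        i_diff=float((diag - off) * 100.0),
        fisher_z_applied=fisher_z_applied,
    )


def sweep_identifiability(gradient_sets: Dict[str, Dict[str, GradientSet]],
                          reference: GradientSet,
                          n_align_values: Sequence[int],
                          fisher_z_options: Sequence[bool] = (False, True)
                          ) -> pd.DataFrame:
    """Identifiability over every unordered session pair and n_align value.

    ``gradient_sets`` maps subject_id -> session_id -> GradientSet; every
    subject must hold every session.  Returns a tidy table with one row per
    (session pair, n_align, fisher variant).
    """
    subjects = sorted(gradient_sets)
    sessions = sorted({ses for subj in gradient_sets.values() for ses in subj})
    missing = [s for s in subjects
               if set(gradient_sets[s]) != set(sessions)]
    if missing:
        raise ValueError(f"subjects missing sessions: {missing}")
    max_n = max(n_align_values)
    if reference.n_components < max_n:
        raise ValueError("reference has fewer components than max n_align")

    rows = []
    for n_align in n_align_values:
        banks = {}
        for ses in sessions:
            vectors = {}
            for sub in subjects:
                aligned, _res, _diag = align_to_reference(
                    gradient_sets[sub][ses], reference, n_align)
                vectors[sub] = aligned.principal_gradient
            banks[ses] = GradientBank(session_id=ses, vectors=vectors,
                                      n_align=n_align)
        for ses_a, ses_b in combinations(sessions, 2):
            for use_z in fisher_z_options:
                res = differential_identifiability(banks[ses_a], banks[ses_b],
                                                   fisher_z_applied=use_z)
                rows.append({
                    "session_a": ses_a, "session_b": ses_b,
                    "n_align": n_align, "accuracy": res.accuracy,
                    "i_self": res.i_self, "i_other": res.i_other,
                    "i_diff": res.i_diff,
                    "variant": "fisher_z" if use_z else "raw",
                })
    return pd.DataFrame(rows)
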