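"""Functional connectivity and head-motion metrics.

Builds Pearson FC matrices, Fisher-z group averages, framewise
displacement (FD), typicality of functional connectivity (TFC), parcel-wise
BOLD-FD correlations, and two-sample Kolmogorov-Smirnov comparisons of
correlation distributions.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .datatypes import ConnectivityMatrix, MotionSeries, ParcelTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_fc",
    "fisher_z",
    "inverse_fisher_z",
    "group_mean_fc",
    "framewise_displacement",
    "tfc",
    "bold_fd_correlations",
    "ks_compare",
]

# correlations at |r| = 1 are clipped before atanh so group averaging stays total
_FISHER_CLIP = 1.0 - 1e-7


def pearson_fc(ts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation between parcel time series.

    The diagonal is set to exactly 1.  Raises if any parcel series is
    constant (zero variance), naming the offending parcel.
    """
    x = ts.values
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        labels = ", ".join(ts.parcel_labels[i] for i in bad[:5])
        raise ValueError(f"zero-variance parcel series: {labels}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, parcel_labels=ts.parcel_labels)


def fisher_z(r) -> np.ndarray | float:
    """Fisher r-to-z transform, ``z = atanh(r)``.

    Values with ``|r| >= 1`` are clipped to ``±(1 - 1e-7)`` with a logged
    warning so that downstream averaging remains finite.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) >= 1.0):
        logger.warning("fisher_z: clipping %d correlation(s) at |r| >= 1",
                       int(np.sum(np.abs(r_arr) >= 1.0)))
        r_arr = np.clip(r_arr, -_FISHER_CLIP, _FISHER_CLIP)
    z = np.arctanh(r_arr)
    return z if np.ndim(r) else float(z)


def inverse_fisher_z(z) -> np.ndarray | float:
    """Inverse Fisher transform, ``r = tanh(z)``."""
    r = np.tanh(np.asarray(z, dtype=float))
    return r if np.ndim(z) else float(r)


def group_mean_fc(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Group-average FC: mean in Fisher-z space, mapped back to correlations."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("group_mean_fc needs a non-empty list of matrices")
    p = matrices[0].n_parcels
    for m in matrices:
        if m.n_parcels != p:
            raise ValueError(
                f"dimension mismatch: {m.n_parcels} parcels vs expected {p}")
    z_sum = np.zeros((p, p))
    for m in matrices:
        z_sum += np.asarray(fisher_z(m.values))
    mean = np.asarray(inverse_fisher_z(z_sum / len(matrices)))
    np.fill_diagonal(mean, 1.0)
    mean = (mean + mean.T) / 2.0
    return ConnectivityMatrix(values=mean, parcel_labels=matrices[0].parcel_labels)


def framewise_displacement(motion: MotionSeries, head_radius: float = 50.0) -> MotionSeries:
    """Compute Power-style framewise displacement from rigid-body parameters.

    FD at frame t (t >= 2) is the sum of absolute backward differences of the
    three translations (mm) plus the three rotations converted to arc length
    at ``head_radius`` mm.  The first frame is set to 0 by convention and is
    excluded from ``mean_fd``.
    """
    if motion.translations is None or motion.rotations is None:
        raise ValueError("framewise_displacement requires the six rigid-body parameters")
    d_trans = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1) * head_radius
    fd = np.concatenate([[0.0], d_trans + d_rot])
    return MotionSeries(
        translations=motion.translations,
        rotations=motion.rotations,
        fd_series=fd,
        subject_id=motion.subject_id,
        session_id=motion.session_id,
    )


def tfc(fc: ConnectivityMatrix, group_fc: ConnectivityMatrix) -> float:
    """Typicality of functional connectivity, ``TFC = (1 + r(FC, FC_group)) / 2``.

    The Pearson correlation is computed over the vectorized strictly-upper
    triangles (the diagonal is constant 1 and would distort r).  TFC lies in
    [0, 1]; lower values indicate an atypical, often motion-burdened, FC.
    """
    if fc.n_parcels != group_fc.n_parcels:
        raise ValueError("dimension mismatch between subject and group FC")
    a = fc.upper_triangle()
    b = group_fc.upper_triangle()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant upper triangle: TFC correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return (1.0 + r) / 2.0


def bold_fd_correlations(ts: ParcelTimeSeries, motion: MotionSeries) -> np.ndarray:
    """Per-parcel Pearson correlation between BOLD series and the FD series.

    The first frame is dropped (FD is undefined there).  Parcels whose series
    are constant over frames 2..T are returned as NaN and should be excluded
    downstream.
    """
    if motion.fd_series is None:
        raise ValueError("motion record has no FD series")
    fd = motion.fd_series
    if fd.size != ts.n_frames:
        raise ValueError(
            f"FD length {fd.size} incompatible with {ts.n_frames} frames")
    fd_tail = fd[1:]
    if fd_tail.std() == 0:
        raise ValueError("constant FD series: correlation undefined")
    x = ts.values[1:, :]
    xc = x - x.mean(axis=0)
    fc = fd_tail - fd_tail.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0) * (fc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * fc[:, None]).sum(axis=0) / denom
    r = np.where((xc ** 2).sum(axis=0) == 0, np.nan, r)
    return np.clip(r, -1.0, 1.0)


def ks_compare(sample_a: Iterable[float], sample_b: Iterable[float],
               fisher_transform: bool = False) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test between correlation samples.

    With ``fisher_transform`` both samples are mapped through the r-to-z
    transform first, which is how distributions of correlation coefficients
    are conventionally compared.  Returns ``(D, p)``.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_compare requires non-empty samples")
    if fisher_transform:
        a = np.asarray(fisher_z(a))
        b = np.asarray(fisher_z(b))
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
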