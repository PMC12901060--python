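"""Core data containers for the gradient-alignment pipeline.

All containers are lightweight dataclasses around numpy arrays with
validation at construction time; heavier tabular results are plain
pandas DataFrames produced by the analysis functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ParcelTimeSeries",
    "ConnectivityMatrix",
    "MotionSeries",
    "GradientSet",
]


def _as_float_array(values, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class ParcelTimeSeries:
    """Parcellated BOLD time series: T frames by P parcels."""

    values: np.ndarray
    subject_id: str = ""
    session_id: str = ""
    parcel_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "time series", 2)
        t, p = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 frames, got {t}")
        if p < 2:
            raise ValueError(f"need at least 2 parcels, got {p}")
        if self.parcel_labels is None:
            self.parcel_labels = [f"parcel_{i:03d}" for i in range(p)]
        elif len(self.parcel_labels) != p:
            raise ValueError("parcel_labels length does not match parcel count")
        self.parcel_labels = list(self.parcel_labels)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric P x P Pearson functional-connectivity matrix, unit diagonal."""

    values: np.ndarray
    parcel_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "connectivity matrix", 2)
        p, q = self.values.shape
        if p != q:
            raise ValueError(f"connectivity matrix must be square, got {p}x{q}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix is not symmetric (tol 1e-10)")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("connectivity matrix diagonal must be 1")
        off = self.values[~np.eye(p, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-10 or off.max() > 1 + 1e-10):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        # enforce exact symmetry / unit diagonal after the tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 1.0)
        if self.parcel_labels is None:
            self.parcel_labels = [f"parcel_{i:03d}" for i in range(p)]
        self.parcel_labels = list(self.parcel_labels)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Vectorized strictly-upper-triangle entries (the unique FC edges)."""
        p = self.n_parcels
        iu = np.triu_indices(p, k=1)
        return self.values[iu]


@dataclass
class MotionSeries:
    """Rigid-body head-motion record for one scanning session.

    Either the six rigid-body parameter columns (translations in mm,
    rotations in radians) or a precomputed framewise-displacement series
    may be supplied.  ``fd_series[0]`` is 0 by convention (FD is undefined
    at the first frame) and ``mean_fd`` excludes it.
    """

    translations: Optional[np.ndarray] = None
    rotations: Optional[np.ndarray] = None
    fd_series: Optional[np.ndarray] = None
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.translations is not None:
            self.translations = _as_float_array(self.translations, "translations", 2)
            if self.translations.shape[1] != 3:
                raise ValueError("translations must have 3 columns")
        if self.rotations is not None:
            self.rotations = _as_float_array(self.rotations, "rotations", 2)
            if self.rotations.shape[1] != 3:
                raise ValueError("rotations must have 3 columns")
        if (self.translations is None) != (self.rotations is None):
            raise ValueError("translations and rotations must be supplied together")
        if self.translations is not None and self.rotations is not None:
            if len(self.translations) != len(self.rotations):
                raise ValueError("translations and rotations must have equal length")
        if self.fd_series is not None:
            self.fd_series = _as_float_array(self.fd_series, "fd_series", 1)
            if self.fd_series.size < 2:
                raise ValueError("fd_series needs at least 2 frames")
            if np.any(self.fd_series < 0):
                raise ValueError("fd_series must be non-negative")
        if self.fd_series is None and self.translations is None:
            raise ValueError("need either rigid-body parameters or an FD series")

    @property
    def n_frames(self) -> int:
        if self.fd_series is not None:
            return self.fd_series.size
        return len(self.translations)

    @property
    def mean_fd(self) -> float:
        if self.fd_series is None:
            raise ValueError("FD series not computed; call framewise_displacement first")
        return float(np.mean(self.fd_series[1:]))


@dataclass
class GradientSet:
    """A set of connectivity gradients: P x K component matrix with eigenvalues.

    Columns are ordered by decreasing importance (descending eigenvalue for
    diffusion maps / PCA; ascending generalized eigenvalue for Laplacian
    eigenmaps, where small eigenvalues carry the smooth structure).
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    method: str = "dm"
    params: dict = field(default_factory=dict)
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.components = _as_float_array(self.components, "components", 2)
        self.eigenvalues = _as_float_array(self.eigenvalues, "eigenvalues", 1)
        if self.components.shape[1] != self.eigenvalues.size:
            raise ValueError("component count must equal eigenvalue count")
        if self.components.shape[1] < 1:
            raise ValueError("need at least one component")

    @property
    def n_parcels(self) -> int:
        return self.components.shape[0]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def select(self, indices) -> "GradientSet":
        """Sub-select components by (ordered) column indices."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError("empty component selection")
        if idx.min() < 0 or idx.max() >= self.n_components:
            raise ValueError("component index out of range")
        return replace(
            self,
            components=self.components[:, idx].copy(),
            eigenvalues=self.eigenvalues[idx].copy(),
            params=dict(self.params, selected=idx.tolist()),
        )

    @property
    def principal_gradient(self) -> np.ndarray:
        return self.components[:, 0]
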