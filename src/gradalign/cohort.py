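"""Synthetic multi-session cohort generator.

Emulates the statistical structure the gradient-alignment analyses assume,
so the full pipeline is testable without any imaging data:

- all subjects share a group gradient basis with a geometrically decaying
  variance spectrum;
- each subject's basis is a small random rotation of the group basis,
  optionally composed with per-component sign flips and adjacent-component
  swaps (the order/sign indeterminacies Procrustes alignment exists to fix);
- each session applies a further small rotation, plus a motion-coupled
  rotation whose magnitude scales with the subject's mean framewise
  displacement and which is directed preferentially (``trailing_emphasis``)
  at components beyond the principal one;
- BOLD-like time series are latent signals through the session basis plus a
  motion artifact (the FD trace broadcast onto a random spatial map) and
  white noise;
- the FD frame series is a rectified AR(1) process rescaled to the subject's
  mean; phenotypes (an age-like and a fluid-score-like variable) follow a
  linear model in motion and gradient loadings.

None of this simulates hemodynamics or scanner physics; it reproduces the
relational structure (reliability, motion coupling, sign/order ambiguity)
that the downstream analyses measure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import expm

from . import io as gio
from .datatypes import MotionSeries, ParcelTimeSeries

__all__ = [
    "PhenotypeModel",
    "CohortSpec",
    "SyntheticRecord",
    "generate_group_basis",
    "generate_cohort",
    "cohort_to_files",
]


@dataclass
class PhenotypeModel:
    """Linear model linking the synthetic phenotypes to motion and gradients.

    The age-like variable is positively coupled to the subject's latent
    motion level; the score-like variable decreases with age and carries a
    gradient-loading term so that gradients are (weakly) predictive of it.
    """

    age_mean: float = 45.0
    age_sd: float = 12.0
    age_motion_corr: float = 0.4
    score_mean: float = 100.0
    score_age_coef: float = -0.4
    score_gradient_coef: float = 5.0
    score_noise_sd: float = 5.0


@dataclass
class CohortSpec:
    """Full parameterization of the synthetic generative model."""

    n_subjects: int = 60
    n_parcels: int = 100
    n_sessions: int = 2
    n_latent: int = 25
    n_frames: int = 400
    eigen_decay: float = 0.95
    subject_rotation_scale: float = 1.0
    session_rotation_scale: float = 0.8
    motion_location: float = 0.15
    motion_scale: float = 0.08
    motion_coupling: float = 8.0
    trailing_emphasis: float = 0.8
    noise_sd: float = 0.5
    flip_probability: float = 0.3
    swap_probability: float = 0.3
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.phenotype_model, dict):
            self.phenotype_model = PhenotypeModel(**self.phenotype_model)
        if self.n_latent >= self.n_parcels:
            raise ValueError("n_latent must be smaller than n_parcels")
        if self.n_frames < 30:
            raise ValueError("n_frames must be at least 30")
        if not 0 <= self.trailing_emphasis <= 1:
            raise ValueError("trailing_emphasis must lie in [0, 1]")
        for name in ("eigen_decay", "subject_rotation_scale",
                     "session_rotation_scale", "motion_location",
                     "motion_scale", "motion_coupling", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(**d)

    def save(self, path: Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json" else yaml.safe_dump(self.to_dict()))
        path.write_text(text)

    @classmethod
    def load(cls, path: Path) -> "CohortSpec":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class SyntheticRecord:
    """One subject-session observation of the synthetic cohort."""

    subject_id: str
    session_id: str
    time_series: ParcelTimeSeries
    motion: MotionSeries
    phenotypes: Dict[str, float]


def generate_group_basis(p: int, k: int, seed: int,
                         eigen_decay: float = 0.75
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Random orthonormal P x K group basis and its geometric variance
    spectrum (first variance 1, ratio ``eigen_decay``)."""
    if k >= p:
        raise ValueError(f"need K < P, got K={k}, P={p}")
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.standard_normal((p, k)))
    # deterministic orientation (QR sign ambiguity)
    for j in range(k):
        i = int(np.argmax(np.abs(basis[:, j])))
        if basis[i, j] < 0:
            basis[:, j] = -basis[:, j]
    variances = eigen_decay ** np.arange(k)
    return basis, variances


def _random_rotation_generator(rng: np.random.Generator, dim: int) -> np.ndarray:
    """Random antisymmetric matrix with unit spectral norm."""
    m = rng.standard_normal((dim, dim))
    a = (m - m.T) / 2.0
    nrm = np.linalg.norm(a, 2)
    return a / nrm if nrm > 0 else a


def _subject_basis(rng: np.random.Generator, group_basis: np.ndarray,
                   spec: CohortSpec) -> np.ndarray:
    p, k = group_basis.shape
    omega = _random_rotation_generator(rng, p) * spec.subject_rotation_scale
    basis = expm(omega) @ group_basis if spec.subject_rotation_scale > 0 else group_basis.copy()
    # sign flips and adjacent swaps: the indeterminacies alignment must undo
    flips = rng.random(k) < spec.flip_probability
    basis[:, flips] *= -1.0
    for j in range(k - 1):
        if rng.random() < spec.swap_probability:
            basis[:, [j, j + 1]] = basis[:, [j + 1, j]]
    return basis


def _session_basis(rng: np.random.Generator, subject_basis: np.ndarray,
                   mean_fd: float, spec: CohortSpec) -> np.ndarray:
    p, k = subject_basis.shape
    basis = subject_basis
    if spec.session_rotation_scale > 0:
        # session noise mixes the subject's components (coefficient-space
        # rotation): emulates the eigenvector instability across sessions
        # that gradient alignment exists to undo
        mix = expm(_random_rotation_generator(rng, k)
                   * spec.session_rotation_scale)
        basis = basis @ mix
    motion_angle = spec.motion_coupling * mean_fd
    if motion_angle > 0:
        # trailing part: rotation confined to the span of components 2..K
        trail = basis[:, 1:]
        gen_small = _random_rotation_generator(rng, k - 1)
        omega_trail = trail @ gen_small @ trail.T
        omega_full = _random_rotation_generator(rng, p)
        omega = motion_angle * (spec.trailing_emphasis * omega_trail
                                + (1.0 - spec.trailing_emphasis) * omega_full)
        basis = expm(omega) @ basis
    return basis.copy() if basis is subject_basis else basis


def _fd_series(rng: np.random.Generator, n_frames: int, mean_fd: float,
               ar_coef: float = 0.6) -> np.ndarray:
    eps = rng.standard_normal(n_frames)
    e = np.empty(n_frames)
    e[0] = eps[0]
    for t in range(1, n_frames):
        e[t] = ar_coef * e[t - 1] + eps[t]
    fd = np.abs(e)
    fd *= mean_fd / fd[1:].mean()
    fd[0] = 0.0
    return fd


def generate_cohort(spec: CohortSpec) -> List[SyntheticRecord]:
    """Generate the full cohort deterministically from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    p, k = spec.n_parcels, spec.n_latent
    pm = spec.phenotype_model
    group_basis, variances = generate_group_basis(p, k, spec.seed,
                                                  spec.eigen_decay)
    # fixed direction giving each subject a scalar "gradient loading"
    loading_dir = rng.standard_normal(p)
    loading_dir /= np.linalg.norm(loading_dir)
    scale = np.sqrt(variances) * np.sqrt(p)  # unit-ish per-parcel signal sd

    records: List[SyntheticRecord] = []
    for s in range(spec.n_subjects):
        subject_id = f"{s:03d}"
        u_motion = rng.standard_normal()
        mean_fd = max(0.01, spec.motion_location + spec.motion_scale * u_motion)
        basis = _subject_basis(rng, group_basis, spec)

        z_age = (pm.age_motion_corr * u_motion
                 + np.sqrt(max(0.0, 1 - pm.age_motion_corr ** 2))
                 * rng.standard_normal())
        age = pm.age_mean + pm.age_sd * z_age
        loading = float(np.sqrt(p) * basis[:, 0] @ loading_dir)
        score = (pm.score_mean + pm.score_age_coef * (age - pm.age_mean)
                 + pm.score_gradient_coef * loading
                 + pm.score_noise_sd * rng.standard_normal())
        phenos = {"age": float(age), "score": float(score),
                  "true_mean_fd": float(mean_fd)}

        # latent signals are subject-level: with all session-variability
        # knobs at zero, a subject's sessions are exact replicas
        latents = rng.standard_normal((spec.n_frames, k))
        for ses in range(spec.n_sessions):
            session_id = f"{ses + 1:02d}"
            ses_basis = _session_basis(rng, basis, mean_fd, spec)
            fd = _fd_series(rng, spec.n_frames, mean_fd)
            # spatial pattern of the motion artifact is session-specific
            artifact_map = rng.standard_normal(p)
            x = latents @ (ses_basis * scale[None, :]).T
            x += spec.motion_coupling * np.outer(fd, artifact_map)
            if spec.noise_sd > 0:
                x += spec.noise_sd * rng.standard_normal(x.shape)
            ts = ParcelTimeSeries(values=x, subject_id=subject_id,
                                  session_id=session_id)
            motion = MotionSeries(fd_series=fd, subject_id=subject_id,
                                  session_id=session_id)
            records.append(SyntheticRecord(subject_id=subject_id,
                                           session_id=session_id,
                                           time_series=ts, motion=motion,
                                           phenotypes=phenos))
    return records


def cohort_to_files(records: List[SyntheticRecord], directory: Path) -> Path:
    """Write a cohort as the pipeline's on-disk input tree.

    One time-series TSV and one confounds TSV per record, a phenotype CSV,
    and a JSON manifest listing everything written.  An empty record list
    yields just the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: List[str] = []
    pheno_rows = {}
    for rec in records:
        ts_path = gio.write_time_series(rec.time_series, directory)
        conf_path = gio.write_confounds(rec.motion, directory)
        files += [ts_path.name, conf_path.name]
        pheno_rows[rec.subject_id] = {"subject_id": rec.subject_id,
                                      **rec.phenotypes}
    if pheno_rows:
        pheno = pd.DataFrame([pheno_rows[k] for k in sorted(pheno_rows)])
        files.append(gio.write_phenotypes(pheno, directory).name)
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"files": sorted(files),
                                    "n_records": len(records)}, indent=2))
    return directory
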