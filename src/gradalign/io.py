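"""Reading and writing of the pipeline's on-disk formats.

- time series: ``sub-<ID>_ses-<ID>_timeseries.tsv`` — one row per frame,
  one column per parcel, header row of parcel labels;
- confounds:  ``sub-<ID>_ses-<ID>_confounds.tsv`` — the six rigid-body
  columns (trans_x/y/z in mm, rot_x/y/z in radians) and/or a
  ``framewise_displacement`` column in mm whose first entry may be ``n/a``
  (fMRIPrep dialect);
- phenotypes: ``phenotypes.csv`` with subject_id, age, score columns;
- gradient sets: delimited text with a ``#``-prefixed header block carrying
  method, kernel, sparsity and eigenvalues.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .connectivity import framewise_displacement
from .datatypes import GradientSet, MotionSeries, ParcelTimeSeries

__all__ = [
    "timeseries_filename",
    "confounds_filename",
    "write_time_series",
    "read_time_series",
    "write_confounds",
    "read_confounds",
    "write_phenotypes",
    "read_phenotypes",
    "write_gradient_set",
    "read_gradient_set",
    "discover_sessions",
]

_TS_PATTERN = re.compile(r"sub-(?P<sub>[^_]+)_ses-(?P<ses>[^_]+)_timeseries\.tsv$")

RIGID_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def timeseries_filename(subject_id: str, session_id: str) -> str:
    return f"sub-{subject_id}_ses-{session_id}_timeseries.tsv"


def confounds_filename(subject_id: str, session_id: str) -> str:
    return f"sub-{subject_id}_ses-{session_id}_confounds.tsv"


def write_time_series(ts: ParcelTimeSeries, directory: Path) -> Path:
    directory = Path(directory)
    path = directory / timeseries_filename(ts.subject_id, ts.session_id)
    df = pd.DataFrame(ts.values, columns=ts.parcel_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_time_series(path: Path, subject_id: str = "", session_id: str = "") -> ParcelTimeSeries:
    path = Path(path)
    m = _TS_PATTERN.search(path.name)
    if m:
        subject_id = subject_id or m.group("sub")
        session_id = session_id or m.group("ses")
    try:
        df = pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise OSError(f"cannot read time series {path}: {exc}") from exc
    return ParcelTimeSeries(values=df.to_numpy(dtype=float),
                            subject_id=subject_id, session_id=session_id,
                            parcel_labels=list(df.columns))


def write_confounds(motion: MotionSeries, directory: Path) -> Path:
    directory = Path(directory)
    path = directory / confounds_filename(motion.subject_id, motion.session_id)
    cols: Dict[str, np.ndarray] = {}
    if motion.translations is not None:
        for i, name in enumerate(RIGID_COLUMNS[:3]):
            cols[name] = motion.translations[:, i]
        for i, name in enumerate(RIGID_COLUMNS[3:]):
            cols[name] = motion.rotations[:, i]
    if motion.fd_series is not None:
        cols["framewise_displacement"] = motion.fd_series
    df = pd.DataFrame(cols)
    if "framewise_displacement" in df.columns:
        # fMRIPrep convention: FD undefined at the first frame
        df.loc[0, "framewise_displacement"] = np.nan
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="n/a")
    return path


def read_confounds(path: Path, subject_id: str = "", session_id: str = "",
                   head_radius: float = 50.0) -> MotionSeries:
    """Read a confounds TSV.  A ``framewise_displacement`` column, when
    present, is used verbatim (first-frame ``n/a`` mapped to 0); otherwise FD
    is computed from the six rigid-body columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    except OSError as exc:
        raise OSError(f"cannot read confounds {path}: {exc}") from exc
    trans = rot = None
    if all(c in df.columns for c in RIGID_COLUMNS):
        trans = df[RIGID_COLUMNS[:3]].to_numpy(float)
        rot = df[RIGID_COLUMNS[3:]].to_numpy(float)
    if "framewise_displacement" in df.columns:
        fd = df["framewise_displacement"].to_numpy(float)
        fd[0] = 0.0 if np.isnan(fd[0]) else fd[0]
        if np.any(np.isnan(fd)):
            raise ValueError(f"NaN FD beyond the first frame in {path}")
        return MotionSeries(translations=trans, rotations=rot, fd_series=fd,
                            subject_id=subject_id, session_id=session_id)
    if trans is None:
        raise ValueError(
            f"{path} has neither framewise_displacement nor the six "
            f"rigid-body columns {RIGID_COLUMNS}")
    motion = MotionSeries(translations=trans, rotations=rot,
                          subject_id=subject_id, session_id=session_id)
    return framewise_displacement(motion, head_radius=head_radius)


def write_phenotypes(phenotypes: pd.DataFrame, directory: Path) -> Path:
    path = Path(directory) / "phenotypes.csv"
    phenotypes.to_csv(path, index=False, float_format="%.10g")
    return path


def read_phenotypes(directory: Path) -> pd.DataFrame:
    path = Path(directory) / "phenotypes.csv"
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = {"subject_id", "age", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def write_gradient_set(gs: GradientSet, path: Path) -> Path:
    path = Path(path)
    header = {
        "method": gs.method,
        "subject_id": gs.subject_id,
        "session_id": gs.session_id,
        "eigenvalues": gs.eigenvalues.tolist(),
        "params": {k: v for k, v in gs.params.items()
                   if isinstance(v, (int, float, str, bool, type(None)))},
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        np.savetxt(fh, gs.components, delimiter="\t", fmt="%.12g")
    return path


def read_gradient_set(path: Path) -> GradientSet:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path} is not a gradient-set file (missing header)")
        header = json.loads(first[2:])
        components = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return GradientSet(components=components,
                       eigenvalues=np.asarray(header["eigenvalues"], float),
                       method=header.get("method", "dm"),
                       params=header.get("params", {}),
                       subject_id=header.get("subject_id", ""),
                       session_id=header.get("session_id", ""))


def discover_sessions(directory: Path) -> List[Tuple[str, str, Path, Optional[Path]]]:
    """Enumerate (subject_id, session_id, timeseries path, confounds path)
    tuples in a dataset directory, sorted for determinism."""
    directory = Path(directory)
    out = []
    for ts_path in sorted(directory.glob("sub-*_ses-*_timeseries.tsv")):
        m = _TS_PATTERN.search(ts_path.name)
        if not m:
            continue
        sub, ses = m.group("sub"), m.group("ses")
        conf = directory / confounds_filename(sub, ses)
        out.append((sub, ses, ts_path, conf if conf.exists() else None))
    return out
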