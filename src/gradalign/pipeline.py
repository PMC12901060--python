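"""End-to-end study orchestration.

Given a dataset directory of parcellated time series and confounds, the
full study runs: FC construction -> FD/TFC motion metrics -> seeded holdout
split -> holdout group-average reference gradients -> per-subject gradient
extraction -> Procrustes alignment sweep over the number of gradients ->
identifiability sweep -> BH-FDR-corrected motion-correlation sweep ->
confound-aware nested-CV prediction.  Every stage writes tidy CSVs carrying
full parameter provenance, and a JSON manifest makes the run reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import io as gio
from .connectivity import group_mean_fc, pearson_fc, tfc
from .datatypes import ConnectivityMatrix, GradientSet
from .embedding import extract_gradients
from .identifiability import sweep_identifiability
from .prediction import (CVConfig, FeatureTable, binarize_by_median,
                         nested_cv_classification, nested_cv_regression)
from .procrustes import align_to_reference

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "holdout_split",
    "build_reference",
    "bh_fdr",
    "motion_correlation_sweep",
    "run_full_study",
]

MOTION_METRICS = ("mean_fd", "tfc")
DIAGNOSTICS = ("trans_total", "trans_pg", "w_norm", "theta_norm",
               "correspondence")


@dataclass
class RunConfig:
    """Parameters of one full study run."""

    input_dir: str = "."
    output_dir: str = "results"
    holdout_fraction: float = 0.2
    seed: int = 0
    kernel: str = "normalized_angle"
    sparsity: float = 0.9
    approach: str = "dm"
    n_components_extracted: int = 20
    n_align_values: Tuple[int, ...] = tuple(range(1, 21))
    reversed_cumulative: bool = False
    fdr_q: float = 0.05
    prediction_scenarios: Tuple[str, ...] = ("none", "fd", "fd+age")
    prediction_n_align: Tuple[int, ...] = (5, 10, 20)
    prediction_models: Tuple[str, ...] = ("ridge",)
    run_prediction: bool = True
    cv: CVConfig = field(default_factory=CVConfig)

    def __post_init__(self) -> None:
        if isinstance(self.cv, dict):
            self.cv = CVConfig(**self.cv)
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        self.n_align_values = tuple(int(v) for v in self.n_align_values)
        bad = [v for v in self.n_align_values
               if not 1 <= v <= self.n_components_extracted]
        if bad:
            raise ValueError(f"n_align values out of range: {bad}")
        self.prediction_n_align = tuple(
            v for v in self.prediction_n_align if v in self.n_align_values)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cv"]["ridge_alpha_grid"] = list(map(float, d["cv"]["ridge_alpha_grid"]))
        d["cv"]["svm_c_grid"] = list(map(float, d["cv"]["svm_c_grid"]))
        d["cv"]["rbf_gamma_grid"] = list(map(float, d["cv"]["rbf_gamma_grid"]))
        d["cv"]["rf_max_depth_grid"] = list(d["cv"]["rf_max_depth_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cv" in d and isinstance(d["cv"], dict):
            cv = dict(d["cv"])
            for key in ("ridge_alpha_grid", "svm_c_grid", "rbf_gamma_grid"):
                if key in cv:
                    cv[key] = np.asarray(cv[key], float)
            if "rf_max_depth_grid" in cv:
                cv["rf_max_depth_grid"] = tuple(cv["rf_max_depth_grid"])
            d["cv"] = CVConfig(**cv)
        for key in ("n_align_values", "prediction_scenarios",
                    "prediction_n_align", "prediction_models"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path: Path) -> "RunConfig":
        text = Path(path).read_text()
        d = (json.loads(text) if str(path).endswith(".json")
             else yaml.safe_load(text))
        return cls.from_dict(d)


def holdout_split(subject_ids: Sequence[str], fraction: float,
                  seed: int) -> Tuple[List[str], List[str]]:
    """Seeded uniform split into (analysis, holdout); |holdout| =
    round(fraction * n)."""
    ids = sorted(set(subject_ids))
    if len(ids) < 5:
        raise ValueError("need at least 5 subjects for a holdout split")
    n_hold = int(round(fraction * len(ids)))
    if n_hold == 0 or n_hold == len(ids):
        raise ValueError(
            f"holdout fraction {fraction} yields an empty partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    holdout = sorted(ids[i] for i in perm[:n_hold])
    analysis = sorted(ids[i] for i in perm[n_hold:])
    return analysis, holdout


def build_reference(holdout_fcs: Sequence[ConnectivityMatrix],
                    kernel: str = "normalized_angle", sparsity: float = 0.9,
                    approach: str = "dm",
                    n_components: int = 20) -> Tuple[GradientSet, ConnectivityMatrix]:
    """Group-average (Fisher-z pooled) FC over the holdout and its gradient
    set, tagged "reference".  Returns (reference gradients, mean FC)."""
    if not holdout_fcs:
        raise ValueError("empty holdout: cannot build a reference")
    mean_fc = group_mean_fc(holdout_fcs)
    ref = extract_gradients(mean_fc, kernel_name=kernel, sparsity=sparsity,
                            approach=approach, n_components=n_components)
    ref.subject_id = "reference"
    return ref, mean_fc


def bh_fdr(p_values, q: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: returns (rejection flags, adjusted
    p-values)."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted


def motion_correlation_sweep(diagnostics: pd.DataFrame,
                             motion_table: pd.DataFrame,
                             n_align_values: Sequence[int],
                             q: float = 0.05) -> pd.DataFrame:
    """Across-subject correlations between motion metrics and alignment
    diagnostics, per session and per n_align, with BH-FDR correction applied
    per (motion metric, diagnostic) family across n_align within session.

    ``diagnostics`` columns: subject_id, session_id, n_align, plus the
    diagnostic columns; ``motion_table`` columns: subject_id, session_id,
    mean_fd, tfc.  A row whose correlation is undefined (constant input) is
    excluded.  The ``significant_all_sessions`` flag marks (metric,
    diagnostic, n_align) cells whose correlations survive FDR in every
    session — the asterisk rule of the correlation-sweep figures.
    """
    merged = diagnostics.merge(motion_table, on=["subject_id", "session_id"])
    sessions = sorted(merged["session_id"].unique())
    rows = []
    for ses in sessions:
        sub = merged[merged["session_id"] == ses]
        for metric, diag in product(MOTION_METRICS, DIAGNOSTICS):
            if diag not in sub.columns:
                continue
            family = []
            for n_align in n_align_values:
                cell = sub[sub["n_align"] == n_align]
                if len(cell) < 4:
                    raise ValueError(
                        f"fewer than 4 subjects for session {ses}, "
                        f"n_align {n_align}")
                x = cell[metric].to_numpy(float)
                y = cell[diag].to_numpy(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    logger.warning("constant %s/%s at session %s n_align %d; "
                                   "row excluded", metric, diag, ses, n_align)
                    continue
                r, p = stats.pearsonr(x, y)
                if not np.isfinite(r):
                    logger.warning("undefined correlation %s/%s at session %s "
                                   "n_align %d; row excluded", metric, diag,
                                   ses, n_align)
                    continue
                family.append({"session_id": ses, "n_align": n_align,
                               "motion_metric": metric, "diagnostic": diag,
                               "pearson_r": float(r), "p_value": float(p)})
            if family:
                reject, adjusted = bh_fdr([f["p_value"] for f in family], q)
                for f, rej, adj in zip(family, reject, adjusted):
                    f["p_adjusted"] = float(adj)
                    f["fdr_significant"] = bool(rej)
                rows.extend(family)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    all_sig = (out.groupby(["motion_metric", "diagnostic", "n_align"])
               ["fdr_significant"].transform(
                   lambda s: bool(s.all()) and s.size == len(sessions)))
    out["significant_all_sessions"] = all_sig
    return out


def _reversed_indices(n_components: int, count: int) -> List[int]:
    """Reversed cumulative selection: the last component first, extending
    downward (e.g. 20th, 19th, ... gradients)."""
    return list(range(n_components - 1, n_components - 1 - count, -1))


def _provenance(config: RunConfig) -> Dict[str, object]:
    return {"kernel": config.kernel, "sparsity": config.sparsity,
            "approach": config.approach, "seed": config.seed}


def run_full_study(config: RunConfig) -> Path:
    """Execute every stage of the study on a dataset directory; returns the
    output directory.  Raises with a stage-tagged message on failure."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("gradalign")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        _run_stages(config, out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out_dir


def _run_stages(config: RunConfig, out_dir: Path) -> None:
    prov = _provenance(config)

    # ---- stage: read + FC + motion metrics -------------------------------
    sessions = gio.discover_sessions(Path(config.input_dir))
    if not sessions:
        raise RuntimeError(f"[read] no sessions found in {config.input_dir}")
    fcs: Dict[Tuple[str, str], ConnectivityMatrix] = {}
    mean_fd: Dict[Tuple[str, str], float] = {}
    for sub, ses, ts_path, conf_path in sessions:
        ts = gio.read_time_series(ts_path, sub, ses)
        fcs[(sub, ses)] = pearson_fc(ts)
        if conf_path is None:
            raise RuntimeError(f"[read] missing confounds for sub-{sub} ses-{ses}")
        motion = gio.read_confounds(conf_path, sub, ses)
        mean_fd[(sub, ses)] = motion.mean_fd
    subjects = sorted({sub for sub, _ in fcs})
    session_ids = sorted({ses for _, ses in fcs})
    logger.info("[read] %d subjects x %d sessions", len(subjects),
                len(session_ids))

    # ---- stage: holdout split + reference --------------------------------
    analysis, holdout = holdout_split(subjects, config.holdout_fraction,
                                      config.seed)
    holdout_fcs = [fcs[(sub, ses)] for sub in holdout for ses in session_ids
                   if (sub, ses) in fcs]
    reference, holdout_mean_fc = build_reference(
        holdout_fcs, config.kernel, config.sparsity, config.approach,
        config.n_components_extracted)
    gio.write_gradient_set(reference, out_dir / "reference_gradients.tsv")

    # ---- stage: motion table (TFC vs the holdout mean FC) ----------------
    motion_rows = []
    for sub in analysis:
        for ses in session_ids:
            if (sub, ses) not in fcs:
                continue
            motion_rows.append({
                "subject_id": sub, "session_id": ses,
                "mean_fd": mean_fd[(sub, ses)],
                "tfc": tfc(fcs[(sub, ses)], holdout_mean_fc), **prov})
    motion_table = pd.DataFrame(motion_rows)
    motion_table.to_csv(out_dir / "motion_metrics.csv", index=False)

    # ---- stage: per-subject gradient extraction --------------------------
    gradient_sets: Dict[str, Dict[str, GradientSet]] = {}
    for sub in analysis:
        gradient_sets[sub] = {}
        for ses in session_ids:
            if (sub, ses) not in fcs:
                continue
            gs = extract_gradients(fcs[(sub, ses)], kernel_name=config.kernel,
                                   sparsity=config.sparsity,
                                   approach=config.approach,
                                   n_components=config.n_components_extracted)
            gs.subject_id, gs.session_id = sub, ses
            gradient_sets[sub][ses] = gs

    # ---- stage: alignment sweep ------------------------------------------
    diag_rows = []
    aligned_pg: Dict[Tuple[str, str, int], np.ndarray] = {}
    for sub in analysis:
        for ses, gs in gradient_sets[sub].items():
            for n_align in config.n_align_values:
                aligned, _res, diags = align_to_reference(gs, reference,
                                                          n_align)
                aligned_pg[(sub, ses, n_align)] = aligned.principal_gradient
                diag_rows.append({"subject_id": sub, "session_id": ses,
                                  "direction": "standard",
                                  **diags.as_dict(), **prov})
                if config.reversed_cumulative and n_align >= 1:
                    idx = _reversed_indices(config.n_components_extracted,
                                            n_align)
                    _a, _r, rdiags = align_to_reference(
                        gs, reference, n_align, component_indices=idx)
                    diag_rows.append({"subject_id": sub, "session_id": ses,
                                      "direction": "reversed",
                                      **rdiags.as_dict(), **prov})
    diagnostics = pd.DataFrame(diag_rows)
    diagnostics.to_csv(out_dir / "alignment_diagnostics.csv", index=False)

    # ---- stage: identifiability sweep ------------------------------------
    if len(session_ids) >= 2:
        ident = sweep_identifiability(gradient_sets, reference,
                                      config.n_align_values)
        for key, val in prov.items():
            ident[key] = val
        ident.to_csv(out_dir / "identifiability.csv", index=False)

    # ---- stage: motion-correlation sweep ---------------------------------
    std_diags = diagnostics[diagnostics["direction"] == "standard"]
    sweep = motion_correlation_sweep(std_diags, motion_table,
                                     config.n_align_values, config.fdr_q)
    for key, val in prov.items():
        sweep[key] = val
    sweep.to_csv(out_dir / "motion_correlations.csv", index=False)

    # ---- stage: prediction ------------------------------------------------
    if config.run_prediction and config.prediction_n_align:
        _prediction_stage(config, out_dir, analysis, session_ids, aligned_pg,
                          motion_table, prov)

    # ---- manifest ---------------------------------------------------------
    manifest = {"config": config.to_dict(),
                "n_subjects": len(subjects),
                "n_analysis": len(analysis),
                "n_holdout": len(holdout),
                "analysis_subjects": analysis,
                "holdout_subjects": holdout,
                "sessions": session_ids}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _prediction_stage(config: RunConfig, out_dir: Path, analysis: List[str],
                      session_ids: List[str],
                      aligned_pg: Dict[Tuple[str, str, int], np.ndarray],
                      motion_table: pd.DataFrame,
                      prov: Dict[str, object]) -> None:
    try:
        phenotypes = gio.read_phenotypes(Path(config.input_dir))
    except FileNotFoundError:
        logger.info("[predict] no phenotype table; stage skipped")
        return
    phenotypes = phenotypes.set_index("subject_id")
    missing = [s for s in analysis if s not in phenotypes.index]
    if missing:
        raise RuntimeError(f"[predict] phenotypes missing subjects {missing[:5]}")
    subj_fd = (motion_table.groupby("subject_id")["mean_fd"].mean())

    scenario_map = {"none": None, "fd": ["mean_fd"], "fd+age": ["mean_fd", "age"]}
    result_rows = []
    for n_align in config.prediction_n_align:
        # subject-level features: aligned principal gradient averaged over sessions
        feats = np.vstack([
            np.mean([aligned_pg[(sub, ses, n_align)] for ses in session_ids
                     if (sub, ses, n_align) in aligned_pg], axis=0)
            for sub in analysis])
        confounds = np.column_stack([
            subj_fd.loc[analysis].to_numpy(float),
            phenotypes.loc[analysis, "age"].to_numpy(float)])
        # continuous targets
        for target_name in ("score", "age"):
            y = phenotypes.loc[analysis, target_name].to_numpy(float)
            scenarios = [s for s in config.prediction_scenarios
                         if not (target_name == "age" and "age" in s)]
            for scen in scenarios:
                table = FeatureTable(features=feats, target=y,
                                     confounds=confounds,
                                     confound_names=["mean_fd", "age"])
                res = nested_cv_regression(table, config.cv,
                                           scenario=scenario_map[scen])
                result_rows.append({"task": f"regression:{target_name}",
                                    "model": "ridge", "scenario": scen,
                                    "n_align": n_align,
                                    "mean_score": res.mean_score,
                                    "sd_score": res.sd_score, **prov})
        # motion classification from the median split of mean FD
        labels = binarize_by_median(subj_fd.loc[analysis].to_numpy(float))
        if np.bincount(labels).min() < config.cv.outer_folds:
            logger.warning("[predict] smallest motion class (%d) below "
                           "outer_folds; classification skipped",
                           int(np.bincount(labels).min()))
            continue
        for model in config.prediction_models:
            table = FeatureTable(features=feats, target=labels)
            res = nested_cv_classification(table, config.cv, model=model)
            result_rows.append({"task": "classification:motion",
                                "model": model, "scenario": "none",
                                "n_align": n_align,
                                "mean_score": res.mean_score,
                                "sd_score": res.sd_score,
                                "mean_auc": res.mean_auc,
                                "sd_auc": res.sd_auc, **prov})
    pd.DataFrame(result_rows).to_csv(out_dir / "predictions.csv", index=False)
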