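"""Batch drivers: per-case quantification runs and cohort analysis reports.

Everything here is a thin, deterministic layer over :mod:`geometry` and
:mod:`stats`; every number in an analysis report can be recomputed from the
cohort CSV by the statistics module alone.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ShapeFeatureError
from .geometry import quantify_case
from .grid import read_mask, read_volume
from .stats import compare_roc_paired, mann_whitney, roc, spearman
from .voi import brain_mask_from_ct

__all__ = ["RunConfig", "run_quantify", "run_analyze", "report_to_text"]

log = logging.getLogger("shapefeature")


@dataclass(frozen=True)
class RunConfig:
    """Run-wide options; the defaults reproduce the standard operating point
    (threshold multiple k = 6, mesh surfaces, no component filtering)."""

    k: float = 6.0
    surface_method: str = "mesh"
    scale_sigma: float = 1.0
    min_component_voxels: int = 0
    hu_low: float = 0.0
    hu_high: float = 80.0
    seed: int = 0

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"k": float, "surface_method": str, "scale_sigma": float,
                 "min_component_voxels": int, "hu_low": float, "hu_high": float,
                 "seed": int}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise ShapeFeatureError(f"unknown config key {key!r}")
                kwargs[key] = casts[key](value.strip())
        return cls(**kwargs)


def _load_case_masks(row: dict, config: RunConfig):
    pet = read_volume(row["pet"], clip_negative=True)
    if row.get("brain_mask"):
        mask = read_mask(row["brain_mask"])
    elif row.get("ct"):
        ct = read_volume(row["ct"])
        mask = brain_mask_from_ct(ct, low=config.hu_low, high=config.hu_high)
    else:
        raise ShapeFeatureError("case needs either a brain_mask or a ct path")
    return pet, mask


def run_quantify(case_rows, config: RunConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Quantify a list of cases; per-case failures are logged and collected,
    the run continues.  Returns (scores table, failure records)."""
    rows, failures = [], []
    for case in case_rows:
        case_id = str(case.get("case_id", case.get("pet", "?")))
        try:
            pet, mask = _load_case_masks(case, config)
            scores = quantify_case(
                pet, mask, k=config.k, scale_sigma=config.scale_sigma,
                surface_method=config.surface_method,
                min_component_voxels=config.min_component_voxels,
            )
        except Exception as exc:
            log.warning("case %s failed: %s", case_id, exc)
            failures.append({"case_id": case_id, "error": str(exc)})
            continue
        if scores.scale_sigma == 1.0 and scores.cass > 1.05:
            log.warning("case %s: CASS %.3f exceeds the isoperimetric bound — "
                        "check geometry/threshold", case_id, scores.cass)
        log.info("case %s: quantified (shape feature %.4f)", case_id,
                 scores.shape_feature)
        rows.append(scores.to_row(case_id))
    if not rows:
        raise ShapeFeatureError("no case quantified successfully")
    return pd.DataFrame(rows), failures


def _iqr_summary(values: np.ndarray) -> dict:
    return {
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
        "n": int(values.size),
    }


def run_analyze(table: pd.DataFrame, score_columns, reference: str | None = None,
                mmse_column: str | None = None, label_column: str = "label") -> dict:
    """Cohort analysis report.

    For every score column: per-group median/IQR, Mann-Whitney U and p, ROC
    AUC with DeLong 95% CI and the Youden-optimal cut-off.  When a
    ``reference`` score is given, every other score's ROC curve is compared
    with the reference's by the paired DeLong test; when an MMSE column is
    given, each score's Spearman correlation with MMSE is added.  No
    multiple-testing correction is applied across comparisons.
    """
    if label_column not in table:
        raise ShapeFeatureError(f"missing label column {label_column!r}")
    labels = table[label_column].to_numpy().astype(bool)
    if labels.all() or not labels.any():
        raise ShapeFeatureError("both groups must be present")
    report: dict = {"n_positive": int(labels.sum()),
                    "n_negative": int((~labels).sum()),
                    "scores": {}, "comparisons": {}, "mmse_correlations": {}}
    for col in score_columns:
        if col not in table:
            raise ShapeFeatureError(f"unknown score column {col!r}")
        if table[col].isna().any():
            raise ShapeFeatureError(f"score column {col!r} has missing values")
        values = table[col].to_numpy(dtype=np.float64)
        mw = mann_whitney(values[labels], values[~labels])
        r = roc(values, labels)
        report["scores"][col] = {
            "positive": _iqr_summary(values[labels]),
            "negative": _iqr_summary(values[~labels]),
            "mann_whitney_u": mw.u,
            "mann_whitney_p": mw.p,
            "auc": r.auc,
            "auc_se": r.se_auc,
            "auc_ci95": list(r.ci95),
            "optimal_cutoff": r.optimal_cutoff,
            "sensitivity": r.sensitivity_at_cutoff,
            "specificity": r.specificity_at_cutoff,
        }
    if reference is not None:
        if reference not in table:
            raise ShapeFeatureError(f"unknown reference score {reference!r}")
        ref_values = table[reference].to_numpy(dtype=np.float64)
        for col in score_columns:
            cmp = compare_roc_paired(table[col].to_numpy(dtype=np.float64),
                                     ref_values, labels)
            report["comparisons"][f"{col}_vs_{reference}"] = {
                "auc_score": cmp.auc_1, "auc_reference": cmp.auc_2,
                "delta": cmp.delta, "z": cmp.z, "p": cmp.p,
            }
    if mmse_column is not None:
        if mmse_column not in table:
            raise ShapeFeatureError(f"unknown MMSE column {mmse_column!r}")
        mmse = table[mmse_column].to_numpy(dtype=np.float64)
        for col in score_columns:
            sp = spearman(table[col].to_numpy(dtype=np.float64), mmse)
            report["mmse_correlations"][col] = {"rho": sp.rho, "p": sp.p,
                                                "n": sp.n, "method": sp.method}
    return report


def report_to_text(report: dict) -> str:
    """Human-readable table mirroring the usual two-group biomarker layout."""
    lines = [f"Cohort: {report['n_positive']} positive vs "
             f"{report['n_negative']} negative"]
    lines.append(f"{'score':<16}{'median+ (IQR)':<28}{'median- (IQR)':<28}"
                 f"{'MW p':<10}{'AUC (95% CI)':<24}{'cutoff':<10}{'sens':<7}{'spec':<7}")
    for name, s in report["scores"].items():
        pos = s["positive"]
        neg = s["negative"]
        lines.append(
            f"{name:<16}"
            + f"{pos['median']:.4g} ({pos['q1']:.4g}-{pos['q3']:.4g})".ljust(28)
            + f"{neg['median']:.4g} ({neg['q1']:.4g}-{neg['q3']:.4g})".ljust(28)
            + f"{s['mann_whitney_p']:.4f}".ljust(10)
            + f"{s['auc']:.3f} ({s['auc_ci95'][0]:.3f}-{s['auc_ci95'][1]:.3f})".ljust(24)
            + f"{s['optimal_cutoff']:.4g}".ljust(10)
            + f"{s['sensitivity']:.3f}".ljust(7)
            + f"{s['specificity']:.3f}".ljust(7)
        )
    if report["comparisons"]:
        lines.append("")
        lines.append("Paired ROC comparisons (DeLong):")
        for name, c in report["comparisons"].items():
            lines.append(f"  {name}: dAUC = {c['delta']:+.4f}, p = {c['p']:.4f}")
    if report["mmse_correlations"]:
        lines.append("")
        lines.append("Spearman correlation with MMSE:")
        for name, c in report["mmse_correlations"].items():
            lines.append(f"  {name}: rho = {c['rho']:+.3f}, p = {c['p']:.4f}")
    return "\n".join(lines)


def read_manifest(path) -> list[dict]:
    """Read a case-manifest CSV (columns: case_id, pet, brain_mask and/or ct)."""
    if not os.path.exists(path):
        raise ShapeFeatureError(f"no such manifest: {path}")
    df = pd.read_csv(path)
    if "pet" not in df.columns:
        raise ShapeFeatureError("manifest needs a 'pet' column")
    records = df.to_dict("records")
    for rec in records:
        for key in ("brain_mask", "ct"):
            if key in rec and (pd.isna(rec[key]) or rec[key] == ""):
                rec[key] = None
    return records
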