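"""Cohort-level statistics: group comparison, ROC, paired AUC tests, sweeps.

Score polarity follows the clinical convention of the shape-feature
biomarker: a HIGHER score predicts the positive (AD-like) group.  Polarity
is never auto-flipped; an AUC below 0.5 is reported as-is with a warning
flag, because it indicates an inverted biomarker rather than a better one.

The Mann-Whitney and Spearman tests wrap scipy; ROC construction, Youden
cut-off selection and the DeLong comparison of correlated AUCs are
implemented here (no pre-installed package provides a paired DeLong test).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyVOIError, MeshExtractionError, ShapeFeatureError
from .geometry import quantify_case

__all__ = [
    "MannWhitneyResult",
    "ROCResult",
    "PairedROCComparison",
    "SpearmanResult",
    "SweepResult",
    "mann_whitney",
    "roc",
    "compare_roc_paired",
    "spearman",
    "threshold_sweep",
]

# above this product of group sizes the exact U distribution is impractical
_EXACT_LIMIT = 400


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # number of (a, b) pairs with a > b, + 1/2 per tie
    p: float          # two-sided
    n_x: int
    n_y: int
    method: str       # "exact" or "asymptotic"


def mann_whitney(x, y) -> MannWhitneyResult:
    """Mann-Whitney U test, two-sided.

    Exact null distribution when ``n_x * n_y <= 400`` and the pooled sample
    is tie-free; otherwise the normal approximation with tie-corrected
    variance and continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= _EXACT_LIMIT and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                             n_x=x.size, n_y=y.size, method=method)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    thresholds: np.ndarray      # distinct score values, descending
    sensitivity: np.ndarray     # at "score >= threshold => positive"
    specificity: np.ndarray
    optimal_cutoff: float       # observed score value maximizing Youden's J
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    se_auc: float
    ci95: tuple[float, float]
    inverted: bool              # True when auc < 0.5 (polarity warning)


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return labels


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values: per-positive and per-negative mean of the
    Mann-Whitney kernel (1 if pos > neg, 1/2 on ties)."""
    pos = scores[labels]
    neg = scores[~labels]
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(np.float64) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def _delong_se(scores: np.ndarray, labels: np.ndarray) -> float:
    v10, v01, auc = _placements(scores, labels)
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    return math.sqrt(max(var, 0.0))


def roc(scores, labels) -> ROCResult:
    """ROC over all distinct score thresholds (``score >= t`` = positive call).

    AUC is the trapezoidal area of the curve (identical to the Mann-Whitney
    AUC with half-credit for ties); the optimal cut-off maximizes Youden's
    J = sensitivity + specificity - 1, ties broken toward higher
    specificity.  The standard error and 95% CI come from the DeLong
    variance of the AUC estimate.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = _check_labels(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos = scores[labels]
    neg = scores[~labels]

    thresholds = np.unique(scores)[::-1]
    sens = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] < thresholds[:, None]).mean(axis=1)

    # full curve: sentinel above the maximum gives (fpr, tpr) = (0, 0)
    fpr = np.concatenate([[0.0], 1.0 - spec])
    tpr = np.concatenate([[0.0], sens])
    auc = float(np.trapezoid(tpr, fpr))

    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    best = candidates[np.lexsort((thresholds[candidates], spec[candidates]))[-1]]

    se = _delong_se(scores, labels)
    ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))
    inverted = auc < 0.5
    if inverted:
        warnings.warn(f"AUC {auc:.3f} < 0.5: score polarity looks inverted",
                      stacklevel=2)
    return ROCResult(auc=auc, thresholds=thresholds, sensitivity=sens,
                     specificity=spec, optimal_cutoff=float(thresholds[best]),
                     sensitivity_at_cutoff=float(sens[best]),
                     specificity_at_cutoff=float(spec[best]),
                     se_auc=se, ci95=ci, inverted=inverted)


@dataclass(frozen=True)
class PairedROCComparison:
    auc_1: float
    auc_2: float
    delta: float     # auc_1 - auc_2
    se_delta: float
    z: float
    p: float         # two-sided


def compare_roc_paired(scores_1, scores_2, labels) -> PairedROCComparison:
    """DeLong test for two correlated AUCs measured on the same cases."""
    s1 = np.asarray(scores_1, dtype=np.float64)
    s2 = np.asarray(scores_2, dtype=np.float64)
    labels = _check_labels(labels)
    if s1.shape != s2.shape or s1.shape != labels.shape:
        raise ValueError("paired comparison needs equal-length score vectors and labels")

    v10_1, v01_1, auc1 = _placements(s1, labels)
    v10_2, v01_2, auc2 = _placements(s2, labels)
    m, n = v10_1.size, v01_1.size

    var = 0.0
    if m > 1:
        s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / n
    var = max(var, 0.0)
    delta = float(auc1 - auc2)
    se = math.sqrt(var)
    if se == 0.0:
        z = 0.0
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        z = delta / se
        p = float(2.0 * sps.norm.sf(abs(z)))
    return PairedROCComparison(auc_1=float(auc1), auc_2=float(auc2), delta=delta,
                               se_delta=se, z=float(z), p=min(p, 1.0))


def bootstrap_compare_roc_paired(scores_1, scores_2, labels, n_boot: int = 2000,
                                 seed: int = 0) -> PairedROCComparison:
    """Stratified paired-bootstrap alternative to the DeLong comparison.

    Cases are resampled within each class (the same resample is applied to
    both score vectors, preserving the pairing); the two-sided p-value is
    the tail fraction of the bootstrap distribution of the AUC difference.
    Used as a validation oracle for :func:`compare_roc_paired`.
    """
    s1 = np.asarray(scores_1, dtype=np.float64)
    s2 = np.asarray(scores_2, dtype=np.float64)
    labels = _check_labels(labels)
    rng = np.random.default_rng(seed)
    p1, n1 = s1[labels], s1[~labels]
    p2, n2 = s2[labels], s2[~labels]
    m, n = p1.size, n1.size
    pos_idx = rng.integers(0, m, size=(n_boot, m))
    neg_idx = rng.integers(0, n, size=(n_boot, n))

    def _auc(pos, neg):
        diff = pos[:, :, None] - neg[:, None, :]
        return ((diff > 0) + 0.5 * (diff == 0)).mean(axis=(1, 2))

    d = _auc(p1[pos_idx], n1[neg_idx]) - _auc(p2[pos_idx], n2[neg_idx])
    lo = (np.count_nonzero(d <= 0) + 1) / (n_boot + 1)
    hi = (np.count_nonzero(d >= 0) + 1) / (n_boot + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    _, _, auc1 = _placements(s1, labels)
    _, _, auc2 = _placements(s2, labels)
    return PairedROCComparison(auc_1=float(auc1), auc_2=float(auc2),
                               delta=float(auc1 - auc2),
                               se_delta=float(d.std(ddof=1)), z=float("nan"), p=p)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    method: str          # "exact-permutation" or "t-approximation"
    constant_input: bool  # True when rho is undefined


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Exact permutation p-value for n <= 8, otherwise the t approximation.
    A constant input vector leaves rho undefined and is flagged rather than
    raised, so batch reports can carry the case.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return SpearmanResult(rho=float("nan"), p=float("nan"), n=n,
                              method="undefined", constant_input=True)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        from itertools import permutations

        perms = np.array(list(permutations(ry)))
        pc = perms - perms.mean(axis=1, keepdims=True)
        xc = rx - rx.mean()
        rhos = (pc @ xc) / (np.linalg.norm(pc, axis=1) * np.linalg.norm(xc))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "exact-permutation"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "t-approximation"
    return SpearmanResult(rho=rho, p=p, n=n, method=method, constant_input=False)


@dataclass(frozen=True)
class SweepResult:
    table: pd.DataFrame       # columns: k, auc, n_used, n_empty, excluded
    argmax_k: tuple[float, ...]  # k values attaining the maximal AUC (ties as a set)


def threshold_sweep(cases, k_values, score: str = "shape_feature",
                    surface_method: str = "mesh", scale_sigma: float = 1.0,
                    min_component_voxels: int = 0) -> SweepResult:
    """Re-quantify every case at each threshold multiple k and report AUC(k).

    ``cases`` is a sequence of objects with ``pet``, ``brain_mask`` and
    ``label`` attributes (e.g. :class:`shapefeature.phantom.CaseVolumes`).
    A k at which more than half the cases yield an empty VOI is flagged as
    excluded (AUC reported as NaN), never silently dropped.
    """
    k_values = [float(k) for k in k_values]
    if not k_values:
        raise ValueError("k_values must be non-empty")
    cases = list(cases)
    if not cases:
        raise ValueError("no cases supplied")
    rows = []
    for k in k_values:
        scores, labels = [], []
        n_empty = 0
        for case in cases:
            try:
                s = quantify_case(case.pet, case.brain_mask, k=k,
                                  scale_sigma=scale_sigma,
                                  surface_method=surface_method,
                                  min_component_voxels=min_component_voxels)
            except (EmptyVOIError, MeshExtractionError):
                # a VOI too thin for an iso-surface is as unusable as an empty one
                n_empty += 1
                continue
            scores.append(getattr(s, score))
            labels.append(case.label)
        excluded = n_empty > len(cases) / 2
        if excluded or len(set(labels)) < 2:
            rows.append({"k": k, "auc": np.nan, "n_used": len(scores),
                         "n_empty": n_empty, "excluded": True})
            continue
        auc = roc(np.asarray(scores), np.asarray(labels)).auc
        rows.append({"k": k, "auc": auc, "n_used": len(scores),
                     "n_empty": n_empty, "excluded": False})
    table = pd.DataFrame(rows)
    valid = table[~table["excluded"]]
    if valid.empty:
        raise ShapeFeatureError("every k was excluded (empty VOIs in > 50% of cases)")
    best = valid["auc"].max()
    argmax = tuple(sorted(valid.loc[valid["auc"] >= best - 1e-12, "k"]))
    return SweepResult(table=table, argmax_k=argmax)
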