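"""Paired session comparison: Wilcoxon signed-rank, BH-FDR, percent difference.

For each feature the two sessions are compared with a two-sided paired
Wilcoxon signed-rank test (exact null distribution for small cohorts,
normal approximation with continuity correction otherwise), and the
resulting p-values are corrected across features with the
Benjamini-Hochberg step-up procedure. In a pure test-retest design no
feature should differ systematically, so the expected outcome is an
empty rejection set — the comparison is a calibration check, not a
discovery analysis.

Percent difference is the signed per-cell quantity

    100 * (test - retest) / test

(the test session is the denominator). Per-feature and overall summaries
average the absolute values — signed differences of opposite sign would
cancel and understate disagreement — but signed means are also reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_io import FeatureTable

logger = logging.getLogger("retest")

#: largest post-zero-drop sample size for which the exact signed-rank null is used
EXACT_N_MAX = 25


def paired_wilcoxon(
    table: FeatureTable, zero_method: str = "wilcox"
) -> np.ndarray:
    """Two-sided paired signed-rank p-value per feature.

    Zero differences are dropped by default (``zero_method='wilcox'``;
    ``'pratt'`` keeps them in the ranking); the drop count is logged. A
    feature whose differences are all zero gets p = 1 (no evidence of a
    shift, flagged in the log).
    """
    if table.n_subjects < 6:
        logger.warning(
            "only %d subjects: the exact signed-rank null cannot reach p < 0.05",
            table.n_subjects,
        )
    test, retest = table.session(0), table.session(1)
    p = np.empty(table.n_features)
    n_zero_total = 0
    for r in range(table.n_features):
        diff = test[:, r] - retest[:, r]
        nz = int((diff == 0).sum())
        n_zero_total += nz
        if np.all(diff == 0):
            p[r] = 1.0
            logger.warning(
                "feature %r: all differences zero, p set to 1",
                table.feature_names[r],
            )
            continue
        n_eff = len(diff) - (nz if zero_method == "wilcox" else 0)
        method = "exact" if n_eff <= EXACT_N_MAX else "approx"
        res = stats.wilcoxon(
            diff,
            zero_method=zero_method,
            alternative="two-sided",
            correction=(method == "approx"),
            method=method,
        )
        p[r] = res.pvalue
    if n_zero_total:
        logger.info("dropped %d zero difference(s) across features", n_zero_total)
    return p


def bh_fdr(
    p: np.ndarray, q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (q, reject) aligned with the input; NaN p-values are excluded
    from the adjustment (count logged) and come back NaN / not-rejected.
    """
    p = np.asarray(p, dtype=float)
    valid = ~np.isnan(p)
    if not valid.all():
        logger.warning("excluding %d NaN p-value(s) from FDR", int((~valid).sum()))
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    if valid.any():
        rej, qv, _, _ = multipletests(p[valid], alpha=q_level, method="fdr_bh")
        q[valid] = qv
        reject[valid] = rej
    return q, reject


@dataclass
class PercentDifference:
    per_feature_abs: np.ndarray  # mean over subjects of |signed %|
    per_feature_signed: np.ndarray
    overall_abs: float  # mean over features of the absolute means
    overall_signed: float
    n_excluded_cells: int  # cells with a zero test value


def percent_difference(table: FeatureTable) -> PercentDifference:
    """Signed and absolute percent difference, test session as denominator."""
    test, retest = table.session(0), table.session(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = 100.0 * (test - retest) / test
    bad = test == 0
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("excluding %d cell(s) with zero test value", n_bad)
        cells = np.where(bad, np.nan, cells)
    per_abs = np.nanmean(np.abs(cells), axis=0)
    per_signed = np.nanmean(cells, axis=0)
    return PercentDifference(
        per_feature_abs=per_abs,
        per_feature_signed=per_signed,
        overall_abs=float(np.nanmean(per_abs)),
        overall_signed=float(np.nanmean(per_signed)),
        n_excluded_cells=n_bad,
    )


@dataclass
class ComparisonReport:
    """Per-feature session comparison with FDR correction."""

    feature_names: list[str]
    per_feature_p: np.ndarray
    per_feature_q: np.ndarray
    reject: np.ndarray
    n_significant: int
    q_level: float
    percent: PercentDifference

    def summary(self) -> dict:
        return {
            "q_level": self.q_level,
            "n_features": len(self.feature_names),
            "n_significant": self.n_significant,
            "percent_difference_overall_abs": self.percent.overall_abs,
            "percent_difference_overall_signed": self.percent.overall_signed,
            "n_excluded_cells": self.percent.n_excluded_cells,
        }

    def write(self, csv_path: str | Path, json_path: str | Path) -> None:
        pd.DataFrame(
            {
                "feature": self.feature_names,
                "p": self.per_feature_p,
                "q": self.per_feature_q,
                "significant": self.reject,
                "percent_diff_abs": self.percent.per_feature_abs,
                "percent_diff_signed": self.percent.per_feature_signed,
            }
        ).to_csv(csv_path, index=False, float_format="%.17g")
        Path(json_path).write_text(json.dumps(self.summary(), indent=2))


def compare_sessions(
    table: FeatureTable, q_level: float = 0.05, zero_method: str = "wilcox"
) -> ComparisonReport:
    """Wilcoxon + BH-FDR + percent difference for one modality table."""
    p = paired_wilcoxon(table, zero_method=zero_method)
    q, reject = bh_fdr(p, q_level=q_level)
    return ComparisonReport(
        feature_names=list(table.feature_names),
        per_feature_p=p,
        per_feature_q=q,
        reject=reject,
        n_significant=int(reject.sum()),
        q_level=q_level,
        percent=percent_difference(table),
    )
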