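"""Per-feature ICC and the global multivariate I2C2, with bootstrap CIs.

The intraclass correlation coefficient is computed feature-by-feature from
the explicit two-way ANOVA mean squares of an I-subjects x 2-sessions
layout (n = I targets, k = 2 raters in the Shrout-Fleiss taxonomy):

    BMS = k * sum_i (S_i - m)^2 / (n - 1)          between-subject MS
    JMS = n * sum_j (M_j - m)^2 / (k - 1)          between-session MS
    EMS = sum_ij (x_ij - S_i - M_j + m)^2 / ((n-1)(k-1))   residual MS
    WMS = sum_ij (x_ij - S_i)^2 / (n (k - 1))      within-subject MS

    ICC(1,1) = (BMS - WMS) / (BMS + (k-1) WMS)
    ICC(2,1) = (BMS - EMS) / (BMS + (k-1) EMS + k (JMS - EMS) / n)
    ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS)

ICC(2,1) (two-way random effects, absolute agreement) is the default:
it penalises a systematic session shift, which is what a test-retest
study wants to detect. Negative estimates are reported as computed —
truncating at zero would bias simulation summaries — and flagged.

The image intraclass correlation coefficient (I2C2) is the multivariate
analogue: one number for the whole feature vector, from a method-of-moments
trace decomposition. With scan vectors W_ij (subject i, session j),
session-demeaned to W'_ij = W_ij - mean_i W_ij (demeaning is the default
and can be switched off), the within-subject and total traces are

    trKw   = (1 / 2I)     * sum_i  ||W'_i1 - W'_i2||^2
    trKtot = (1 / (2I-1)) * sum_ij ||W'_ij - Wbar||^2

and I2C2 = 1 - trKw / trKtot. Because the traces sum variances over
features, low-variability features contribute little, which is why I2C2
tends to sit below the average of per-feature ICCs when reliability is
heterogeneous.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_io import FeatureTable, SeedPairIndex

logger = logging.getLogger("retest")

ICC_FORMS = ("ICC(1,1)", "ICC(2,1)", "ICC(3,1)")


def _values(table: FeatureTable | np.ndarray) -> np.ndarray:
    x = table.values if isinstance(table, FeatureTable) else np.asarray(table, float)
    if x.ndim != 3 or x.shape[1] != 2:
        raise ValueError("expected an (I, 2, p) array")
    return x


def anova_mean_squares(table: FeatureTable | np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised two-way ANOVA mean squares per feature (k = 2 sessions)."""
    x = _values(table)
    n, k, _ = x.shape
    m = x.mean(axis=(0, 1))
    si = x.mean(axis=1)  # (I, p) subject means
    mj = x.mean(axis=0)  # (2, p) session means
    bms = k * ((si - m) ** 2).sum(axis=0) / (n - 1)
    jms = n * ((mj - m) ** 2).sum(axis=0) / (k - 1)
    resid = x - si[:, None, :] - mj[None, :, :] + m
    ems = (resid**2).sum(axis=(0, 1)) / ((n - 1) * (k - 1))
    wms = ((x - si[:, None, :]) ** 2).sum(axis=(0, 1)) / (n * (k - 1))
    return {"BMS": bms, "JMS": jms, "EMS": ems, "WMS": wms}


def icc(table: FeatureTable | np.ndarray, form: str = "ICC(2,1)") -> np.ndarray:
    """Per-feature ICC of the chosen Shrout-Fleiss form.

    Features with zero total variance have no defined ICC and come back as
    NaN (logged); they should be excluded from summaries.
    """
    if form not in ICC_FORMS:
        raise ValueError(f"form must be one of {ICC_FORMS}, got {form!r}")
    x = _values(table)
    n, k, _ = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    ms = anova_mean_squares(x)
    bms, jms, ems, wms = ms["BMS"], ms["JMS"], ms["EMS"], ms["WMS"]
    total = x.var(axis=(0, 1))
    degenerate = total <= np.finfo(float).eps * np.maximum(
        1.0, (x**2).mean(axis=(0, 1))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        if form == "ICC(1,1)":
            out = (bms - wms) / (bms + (k - 1) * wms)
        elif form == "ICC(3,1)":
            out = (bms - ems) / (bms + (k - 1) * ems)
        else:
            out = (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n)
    if degenerate.any():
        logger.warning(
            "%d feature(s) with zero total variance: ICC undefined (NaN)",
            int(degenerate.sum()),
        )
        out = np.where(degenerate, np.nan, out)
    # exact-agreement corner: all mean squares vanish except BMS -> ICC = 1
    return out


def i2c2(table: FeatureTable | np.ndarray, demean_sessions: bool = True) -> float:
    """Global method-of-moments I2C2 of a balanced two-session table."""
    x = _values(table)
    return float(_i2c2_resampled(x, np.arange(x.shape[0])[None, :], demean_sessions)[0])


def _i2c2_resampled(
    x: np.ndarray, idx: np.ndarray, demean_sessions: bool
) -> np.ndarray:
    """I2C2 for each row of subject-index matrix ``idx`` (B, I)."""
    w = x[idx]  # (B, I, 2, p)
    b, n, _, p = w.shape
    if demean_sessions:
        w = w - w.mean(axis=1, keepdims=True)
    d = w[:, :, 0, :] - w[:, :, 1, :]
    trkw = (d**2).sum(axis=(1, 2)) / (2 * n)
    flat = w.reshape(b, 2 * n, p)
    centered = flat - flat.mean(axis=1, keepdims=True)
    trktot = (centered**2).sum(axis=(1, 2)) / (2 * n - 1)
    if np.any(trktot == 0.0):
        raise ValueError("total trace is zero: I2C2 undefined")
    return 1.0 - trkw / trktot


def i2c2_bootstrap_ci(
    table: FeatureTable | np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    demean_sessions: bool = True,
    batch: int = 200,
) -> tuple[float, float]:
    """Percentile bootstrap CI for I2C2, resampling subjects with replacement.

    Both sessions of a resampled subject travel together, preserving the
    pairing. Degenerate resamples containing a single unique subject are
    redrawn (the redraw count is logged). Deterministic given the seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    x = _values(table)
    n = x.shape[0]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, n, size=(n_boot, n))
    redraws = 0
    degenerate = np.array([len(np.unique(row)) < 2 for row in idx])
    while degenerate.any():
        redraws += int(degenerate.sum())
        idx[degenerate] = rng.integers(0, n, size=(int(degenerate.sum()), n))
        degenerate = np.array([len(np.unique(row)) < 2 for row in idx])
    if redraws:
        logger.info("redrew %d degenerate bootstrap resample(s)", redraws)
    stats = np.empty(n_boot)
    for start in range(0, n_boot, batch):
        sl = slice(start, min(start + batch, n_boot))
        stats[sl] = _i2c2_resampled(x, idx[sl], demean_sessions)
    alpha = 1.0 - level
    lower, upper = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lower), float(upper)


def seed_mean_icc(
    per_pair_icc: np.ndarray, index: SeedPairIndex
) -> np.ndarray:
    """Average the per-pair ICCs over the s-1 pairs containing each seed.

    This is how a per-seed reliability is summarised for seed-pair
    connectivity vectors. NaN pair values are excluded pairwise (count
    logged).
    """
    v = np.asarray(per_pair_icc, dtype=float)
    if v.shape != (index.n_pairs,):
        raise ValueError(
            f"expected {index.n_pairs} pair ICCs for {index.n_seeds} seeds, "
            f"got {v.shape}"
        )
    n_nan = int(np.isnan(v).sum())
    if n_nan:
        logger.warning("excluding %d NaN pair ICC(s) from seed means", n_nan)
    out = np.empty(index.n_seeds)
    for s in range(index.n_seeds):
        vals = v[index.pairs_containing(s)]
        out[s] = np.nanmean(vals) if np.any(~np.isnan(vals)) else np.nan
    return out


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityReport:
    """Per-feature ICCs plus the global I2C2 with its bootstrap CI."""

    feature_names: list[str]
    per_feature_icc: np.ndarray
    icc_form: str
    i2c2: float
    i2c2_ci: tuple[float, float]
    n_boot: int
    demean_sessions: bool
    negative_flagged: bool
    per_seed_mean_icc: np.ndarray | None = None
    seed_names: list[str] | None = None

    def summary(self) -> dict:
        valid = self.per_feature_icc[~np.isnan(self.per_feature_icc)]
        return {
            "icc_form": self.icc_form,
            "icc_mean": float(valid.mean()) if valid.size else float("nan"),
            "icc_min": float(valid.min()) if valid.size else float("nan"),
            "icc_max": float(valid.max()) if valid.size else float("nan"),
            "n_features": len(self.feature_names),
            "n_icc_nan": int(np.isnan(self.per_feature_icc).sum()),
            "i2c2": self.i2c2,
            "i2c2_ci": list(self.i2c2_ci),
            "n_boot": self.n_boot,
            "demean_sessions": self.demean_sessions,
            "negative_estimates_present": self.negative_flagged,
        }

    def write(self, csv_path: str | Path, json_path: str | Path) -> None:
        df = pd.DataFrame(
            {"feature": self.feature_names, self.icc_form: self.per_feature_icc}
        )
        df.to_csv(csv_path, index=False, float_format="%.17g")
        Path(json_path).write_text(json.dumps(self.summary(), indent=2))


def reliability_report(
    table: FeatureTable,
    icc_form: str = "ICC(2,1)",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = 0,
    demean_sessions: bool = True,
    seed_index: SeedPairIndex | None = None,
) -> ReliabilityReport:
    """Compute the full reliability block for one modality table."""
    per_feature = icc(table, form=icc_form)
    point = i2c2(table, demean_sessions=demean_sessions)
    ci = i2c2_bootstrap_ci(
        table, n_boot=n_boot, level=level, seed=seed, demean_sessions=demean_sessions
    )
    negative = bool(np.nanmin(per_feature) < 0.0) or point < 0.0
    if negative:
        logger.warning("negative reliability estimate(s) present (reported raw)")
    per_seed = seeds = None
    if seed_index is not None:
        per_seed = seed_mean_icc(per_feature, seed_index)
        seeds = list(seed_index.seeds)
    return ReliabilityReport(
        feature_names=list(table.feature_names),
        per_feature_icc=per_feature,
        icc_form=icc_form,
        i2c2=point,
        i2c2_ci=ci,
        n_boot=n_boot,
        demean_sessions=demean_sessions,
        negative_flagged=negative,
        per_seed_mean_icc=per_seed,
        seed_names=seeds,
    )
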