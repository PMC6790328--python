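"""Subject fingerprinting in a low-dimensional PCA embedding.

All 2I scans (both sessions of every subject) are embedded jointly into
the top principal components of the feature matrix — three by default,
since three components capture the bulk of the variance for regional
imaging features and make the geometry plottable. Within that space the
cross-session Euclidean distance matrix D[i, k] = ||test_i - retest_k||
is ranked row-wise; a subject is correctly identified when their own
retest scan is rank 1, i.e. the nearest cross-session neighbour, and
misclassified otherwise. The diagonal distances D[i, i] are the
test-retest pair distances whose mean quantifies measurement variability
relative to the between-subject spread of the cloud.

Features are z-scored before the embedding by default: regional volumes,
diffusivities and z-correlations live on wildly different scales, and an
unstandardised PCA would be dominated by whichever feature has the
largest raw variance. Distances are computed on the raw PC scores (not
whitened), so PC1 dominates — the geometry a PCA scatter plot shows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .feature_io import FeatureTable

logger = logging.getLogger("retest")


@dataclass
class Embedding:
    """PC scores for the 2I stacked scans plus the fit metadata."""

    scores: np.ndarray  # (2I, n_components)
    components: np.ndarray  # (n_components, p_kept)
    explained_variance_ratio: np.ndarray
    kept_features: list[str]
    standardized: bool


def embed(
    table: FeatureTable, n_components: int = 3, standardize: bool = True
) -> Embedding:
    """Project all 2I scans onto the leading principal components.

    The PCA is fitted on the stacked scans jointly (never per session), so
    both scans of a subject live in one common space. Component signs are
    fixed deterministically: the loading entry of largest magnitude is made
    positive. Constant features are dropped with a warning when
    standardising (their z-score is undefined).
    """
    x = table.stacked()
    if x.shape[0] <= n_components:
        raise ValueError("need more scans than components")
    keep = np.ones(x.shape[1], dtype=bool)
    if standardize:
        sd = x.std(axis=0)
        keep = sd > 0
        if not keep.all():
            logger.warning(
                "dropping %d constant feature(s) before standardization",
                int((~keep).sum()),
            )
        x = x[:, keep]
        x = (x - x.mean(axis=0)) / x[:, :].std(axis=0)
    else:
        x = x - x.mean(axis=0)
    if x.shape[1] < n_components:
        raise ValueError("fewer usable features than components")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(n_components), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    u *= flip
    vt *= flip[:, None]
    total_var = (x**2).sum()
    return Embedding(
        scores=u * s,
        components=vt,
        explained_variance_ratio=s**2 / total_var,
        kept_features=[f for f, k in zip(table.feature_names, keep) if k],
        standardized=standardize,
    )


@dataclass
class FingerprintResult:
    """Cross-session distances, ranks and the misclassification tally.

    ``rank_matrix[i, k]`` is the rank (1 = closest) of subject k's retest
    scan among all retest scans, by distance to subject i's test scan.
    ``misclassified`` lists subjects whose own retest is not rank 1 in the
    primary (test -> retest) direction; the reverse direction is tallied in
    ``n_misclassified_reverse`` and the union in ``n_misclassified_either``.
    """

    subject_ids: list[str]
    scores: np.ndarray
    cross_distance: np.ndarray
    rank_matrix: np.ndarray
    misclassified: list[str]
    n_misclassified: int
    n_misclassified_reverse: int
    n_misclassified_either: int
    pair_distance_mean: float
    pair_distance_sd: float


def _row_ranks(d: np.ndarray) -> np.ndarray:
    """1-based rank of each column within its row; ties broken by column
    order (stable), which is the subject order."""
    order = np.argsort(d, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(d.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, d.shape[1] + 1)
    return ranks


def rank_and_classify(
    scores: np.ndarray | Embedding, subject_ids: list[str]
) -> FingerprintResult:
    """Rank cross-session distances and count misclassified subjects."""
    if isinstance(scores, Embedding):
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    n = len(subject_ids)
    if scores.shape[0] != 2 * n:
        raise ValueError(
            f"scores have {scores.shape[0]} rows, expected 2 x {n} subjects"
        )
    d = cdist(scores[:n], scores[n:])
    for i in range(n):
        if len(np.unique(d[i])) < n:
            logger.warning(
                "tied cross-session distances in row %d; ties broken by "
                "subject order",
                i,
            )
    ranks = _row_ranks(d)
    diag = np.arange(n)
    diag_ranks = ranks[diag, diag]
    miss_fwd = diag_ranks != 1
    ranks_rev = _row_ranks(d.T)
    miss_rev = ranks_rev[diag, diag] != 1
    pair = d[diag, diag]
    return FingerprintResult(
        subject_ids=list(subject_ids),
        scores=scores,
        cross_distance=d,
        rank_matrix=ranks,
        misclassified=[s for s, m in zip(subject_ids, miss_fwd) if m],
        n_misclassified=int(miss_fwd.sum()),
        n_misclassified_reverse=int(miss_rev.sum()),
        n_misclassified_either=int((miss_fwd | miss_rev).sum()),
        pair_distance_mean=float(pair.mean()),
        pair_distance_sd=float(pair.std(ddof=1)) if n > 1 else 0.0,
    )


def pair_distance_summary(result: FingerprintResult) -> tuple[float, float]:
    """Mean and SD of the diagonal (test-retest pair) distances."""
    return result.pair_distance_mean, result.pair_distance_sd


def fingerprint(
    table: FeatureTable, n_components: int = 3, standardize: bool = True
) -> FingerprintResult:
    """Convenience: embed a table and classify in one call."""
    emb = embed(table, n_components=n_components, standardize=standardize)
    return rank_and_classify(emb, table.subject_ids)
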