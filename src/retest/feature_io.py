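"""Balanced test-retest feature tables and label-volume pairs.

A test-retest study measures every subject twice with the same protocol.
The central container here, :class:`FeatureTable`, holds one real-valued
feature vector per subject per session in a dense ``(I, 2, p)`` array,
with the two sessions ordered ``("test", "retest")`` — the ordering
matters for signed percent differences downstream, where the test session
is the denominator.

Also provided: the Fisher z-transform used for seed-based functional
connectivity, the deterministic packing of a symmetric seed-by-seed
correlation matrix into an upper-triangle vector, and NIfTI loading of
aligned integer label volumes for Dice overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("retest")

SESSION_LABELS: tuple[str, str] = ("test", "retest")
MODALITIES = ("volume", "FA", "MD", "rsfmri_z", "generic")

#: significant digits used when writing CSV so that load -> write -> load
#: round-trips float64 values bit-exactly
CSV_FLOAT_FORMAT = "%.17g"


class InputError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects x sessions x features matrix for a balanced two-session design.

    Parameters
    ----------
    subject_ids : list of str
        Ordered subject identifiers (I entries).
    feature_names : list of str
        Ordered feature identifiers (p entries), e.g. region names.
    values : ndarray of shape (I, 2, p)
        ``values[i, 0]`` is subject *i*'s test-session feature vector,
        ``values[i, 1]`` the retest vector.
    modality : str
        One of ``volume, FA, MD, rsfmri_z, generic``; drives strict-mode
        range checks (FA in [0, 1], volume/MD strictly positive).
    """

    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    modality: str = "generic"
    session_labels: tuple[str, str] = SESSION_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), 2, len(self.feature_names)):
            raise InputError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x 2 sessions x "
                f"{len(self.feature_names)} features"
            )
        if self.modality not in MODALITIES:
            raise InputError(f"unknown modality {self.modality!r}")
        if len(self.session_labels) != 2:
            raise InputError("exactly two session labels required")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def session(self, which: int | str) -> np.ndarray:
        """Return the (I, p) matrix of one session ('test'/'retest' or 0/1)."""
        if isinstance(which, str):
            which = self.session_labels.index(which)
        return self.values[:, which, :]

    def stacked(self) -> np.ndarray:
        """All 2I scans as rows: the I test rows first, then the I retest rows."""
        return np.concatenate([self.values[:, 0, :], self.values[:, 1, :]], axis=0)

    # -- validation --------------------------------------------------------
    def validate(self, strict: bool = False) -> "FeatureTable":
        if not np.all(np.isfinite(self.values)):
            i, j, r = np.argwhere(~np.isfinite(self.values))[0]
            raise InputError(
                f"non-finite value for subject {self.subject_ids[i]!r}, "
                f"session {self.session_labels[j]!r}, "
                f"feature {self.feature_names[r]!r}"
            )
        if strict:
            if self.modality == "FA" and (
                self.values.min() < 0.0 or self.values.max() > 1.0
            ):
                raise InputError("FA values must lie in [0, 1] in strict mode")
            if self.modality in ("volume", "MD") and self.values.min() <= 0.0:
                raise InputError(
                    f"{self.modality} values must be positive in strict mode"
                )
        return self

    # -- conversions -------------------------------------------------------
    def to_wide(self) -> pd.DataFrame:
        rows = []
        for j, lab in enumerate(self.session_labels):
            df = pd.DataFrame(self.values[:, j, :], columns=self.feature_names)
            df.insert(0, "session", lab)
            df.insert(0, "subject", self.subject_ids)
            rows.append(df)
        wide = pd.concat(rows, ignore_index=True)
        # interleave so each subject's two rows are adjacent
        order = np.argsort(
            np.concatenate([np.arange(self.n_subjects)] * 2), kind="stable"
        )
        return wide.iloc[order].reset_index(drop=True)

    def to_long(self) -> pd.DataFrame:
        wide = self.to_wide()
        return wide.melt(
            id_vars=["subject", "session"], var_name="feature", value_name="value"
        )

    def write_csv(self, path: str | Path, layout: str = "wide") -> None:
        df = self.to_wide() if layout == "wide" else self.to_long()
        df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.feature_names == other.feature_names
            and self.modality == other.modality
            and np.array_equal(self.values, other.values)
        )


def _balance(
    df: pd.DataFrame, feature_names: list[str], modality: str
) -> FeatureTable:
    """Build a FeatureTable from an interim wide frame, dropping subjects that
    lack either session (the count is logged, never raised — incomplete
    subjects are a routine feature of test-retest cohorts)."""
    subjects = list(dict.fromkeys(df["subject"]))  # order of first appearance
    kept, dropped = [], []
    per_subject = {}
    for s in subjects:
        sub = df[df["subject"] == s]
        sessions = set(sub["session"])
        if sessions >= set(SESSION_LABELS):
            per_subject[s] = sub
            kept.append(s)
        else:
            dropped.append(s)
    if dropped:
        logger.warning(
            "excluded %d subject(s) missing a session: %s", len(dropped), dropped
        )
    if not kept:
        raise InputError("no subject has both sessions")
    values = np.empty((len(kept), 2, len(feature_names)))
    for i, s in enumerate(kept):
        sub = per_subject[s]
        for j, lab in enumerate(SESSION_LABELS):
            row = sub[sub["session"] == lab]
            values[i, j, :] = row[feature_names].to_numpy(dtype=float)[0]
    return FeatureTable(kept, list(feature_names), values, modality=modality)


def _check_numeric(df: pd.DataFrame, cols: list[str], path: str | Path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        converted = pd.to_numeric(out[c], errors="coerce")
        bad = converted.isna() & out[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"{path}: non-numeric value {out[c].iloc[row]!r} in column "
                f"{c!r}, data row {row}"
            )
        out[c] = converted
    return out


def load_feature_table(
    path: str | Path,
    layout: str = "wide",
    modality: str = "generic",
    strict: bool = False,
) -> FeatureTable:
    """Read a CSV/TSV feature table and enforce the balanced design.

    Wide layout: columns ``subject, session, <feature...>``.
    Long layout: columns ``subject, session, feature, value``.
    Subjects missing either session are excluded (logged); duplicate
    (subject, session, feature) entries are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(
        path,
        sep=sep,
        dtype={"subject": str, "session": str},
        float_precision="round_trip",
    )
    if layout == "wide":
        required = {"subject", "session"}
        if not required <= set(df.columns):
            raise InputError(f"{path}: wide layout needs columns {sorted(required)}")
        feature_names = [c for c in df.columns if c not in ("subject", "session")]
        if df.duplicated(["subject", "session"]).any():
            dup = df[df.duplicated(["subject", "session"])].iloc[0]
            raise InputError(
                f"{path}: duplicate rows for subject {dup['subject']!r} "
                f"session {dup['session']!r}"
            )
        df = _check_numeric(df, feature_names, path)
    elif layout == "long":
        required = {"subject", "session", "feature", "value"}
        if not required <= set(df.columns):
            raise InputError(f"{path}: long layout needs columns {sorted(required)}")
        if df.duplicated(["subject", "session", "feature"]).any():
            dup = df[df.duplicated(["subject", "session", "feature"])].iloc[0]
            raise InputError(
                f"{path}: duplicate (subject, session, feature) = "
                f"({dup['subject']!r}, {dup['session']!r}, {dup['feature']!r})"
            )
        df = _check_numeric(df, ["value"], path)
        feature_names = list(dict.fromkeys(df["feature"]))
        df = (
            df.pivot_table(
                index=["subject", "session"],
                columns="feature",
                values="value",
                sort=False,
            )
            .reindex(columns=feature_names)
            .reset_index()
        )
    else:
        raise InputError(f"unknown layout {layout!r}")
    unknown = set(df["session"]) - set(SESSION_LABELS)
    if unknown:
        raise InputError(f"{path}: unknown session label(s) {sorted(unknown)}")
    table = _balance(df, feature_names, modality)
    return table.validate(strict=strict)


# ---------------------------------------------------------------------------
# Fisher z and seed-pair packing
# ---------------------------------------------------------------------------

def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z-transform ``atanh(r)`` of correlation values, |r| < 1."""
    arr = np.asarray(r, dtype=float)
    bad = np.abs(arr) >= 1.0
    if np.any(bad):
        idx = tuple(int(v) for v in np.argwhere(bad)[0])
        raise InputError(
            f"|r| >= 1 at position {idx}: r = {float(arr[idx])} has no finite z"
        )
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def fisher_z_matrix(corr: np.ndarray) -> np.ndarray:
    """Fisher z of a square correlation matrix, diagonal excluded (set to 0)."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise InputError("correlation matrix must be square")
    off = ~np.eye(corr.shape[0], dtype=bool)
    bad = off & (np.abs(corr) >= 1.0)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise InputError(f"|r| >= 1 for seed pair ({i}, {j}): r = {corr[i, j]}")
    out = np.zeros_like(corr)
    out[off] = np.arctanh(corr[off])
    return out


@dataclass
class SeedPairIndex:
    """Deterministic bijection between unordered seed pairs and vector slots.

    Pair ``k`` corresponds to the row-major upper-triangle entry ``(i, j)``,
    ``i < j``; with ``s`` seeds the vector has ``s(s-1)/2`` entries (1,431
    for the 54 gray-matter seeds used in seed-based connectivity).
    """

    seeds: list[str]
    pairs: list[tuple[int, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        s = len(self.seeds)
        iu = np.triu_indices(s, k=1)
        self.pairs = list(zip(iu[0].tolist(), iu[1].tolist()))

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    @property
    def n_pairs(self) -> int:
        return len(self.seeds) * (len(self.seeds) - 1) // 2

    def pair_names(self) -> list[str]:
        return [f"{self.seeds[i]}~{self.seeds[j]}" for i, j in self.pairs]

    def pairs_containing(self, seed: int | str) -> np.ndarray:
        """Vector positions of the s-1 pairs that include the given seed."""
        if isinstance(seed, str):
            seed = self.seeds.index(seed)
        return np.array(
            [k for k, (i, j) in enumerate(self.pairs) if seed in (i, j)], dtype=int
        )


def seedpair_vector(
    corr_matrix: np.ndarray, index: SeedPairIndex, atol: float = 1e-8
) -> np.ndarray:
    """Pack a symmetric s x s matrix into its upper-triangle vector."""
    m = np.asarray(corr_matrix, dtype=float)
    s = index.n_seeds
    if m.shape != (s, s):
        raise InputError(f"matrix shape {m.shape} does not match {s} seeds")
    asym = np.abs(m - m.T).max()
    if asym > atol:
        raise InputError(f"matrix asymmetric: max |A - A.T| = {asym:g} > {atol:g}")
    iu = np.triu_indices(s, k=1)
    return m[iu]


def seedpair_matrix(
    vector: np.ndarray, index: SeedPairIndex, diagonal: float = 0.0
) -> np.ndarray:
    """Inverse of :func:`seedpair_vector` (symmetric, given diagonal)."""
    v = np.asarray(vector, dtype=float)
    s = index.n_seeds
    if v.shape != (index.n_pairs,):
        raise InputError(f"vector length {v.shape} != s(s-1)/2 = {index.n_pairs}")
    m = np.full((s, s), diagonal)
    iu = np.triu_indices(s, k=1)
    m[iu] = v
    m[(iu[1], iu[0])] = v
    return m


# ---------------------------------------------------------------------------
# Label volumes
# ---------------------------------------------------------------------------

@dataclass
class LabelVolumePair:
    """Two aligned 3D integer label volumes (label 0 = background)."""

    volume_a: np.ndarray
    volume_b: np.ndarray
    label_lut: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.volume_a = np.asarray(self.volume_a)
        self.volume_b = np.asarray(self.volume_b)
        if self.volume_a.shape != self.volume_b.shape:
            raise InputError(
                f"volume shapes differ: {self.volume_a.shape} vs "
                f"{self.volume_b.shape}"
            )
        for name, vol in (("volume_a", self.volume_a), ("volume_b", self.volume_b)):
            if vol.min() < 0:
                raise InputError(f"{name} contains negative labels")


def _load_int_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise InputError(f"{path}: label volume contains non-integer values")
        data = data.astype(np.int64)
    if data.min() < 0:
        raise InputError(f"{path}: negative label values")
    return data.astype(np.int64), img.affine


def load_label_volume_pair(
    path_a: str | Path, path_b: str | Path
) -> LabelVolumePair:
    """Load two NIfTI label volumes assumed to be in the same space.

    Alignment (registration) is the caller's responsibility; only the voxel
    grids are compared. A differing affine is warned about, differing shapes
    are a hard error.
    """
    vol_a, aff_a = _load_int_volume(path_a)
    vol_b, aff_b = _load_int_volume(path_b)
    if vol_a.shape != vol_b.shape:
        raise InputError(
            f"volume shapes differ: {vol_a.shape} ({path_a}) vs "
            f"{vol_b.shape} ({path_b})"
        )
    if not np.allclose(aff_a, aff_b):
        logger.warning("affines differ between %s and %s", path_a, path_b)
    return LabelVolumePair(vol_a, vol_b)
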