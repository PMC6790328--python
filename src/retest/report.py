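"""End-to-end reproducibility report over one or more modality tables.

A run takes a flat YAML config naming the input tables (or asking for
synthetic ones), runs the full statistical battery per modality —
per-feature ICC, global I2C2 with a subject-bootstrap CI, the PCA
fingerprint, paired Wilcoxon with BH-FDR and percent difference, and
optionally Dice overlap for a pair of label volumes — and writes every
result as CSV/JSON into one output directory, with a manifest capturing
the settings, seed and package version so any number in the bundle can
be regenerated. Inputs are never modified; a failing stage aborts with a
stage-named error and partial outputs are retained.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import compare_sessions
from .feature_io import (
    FeatureTable,
    SeedPairIndex,
    load_feature_table,
    load_label_volume_pair,
)
from .fingerprint import fingerprint
from .overlap import dice
from .reliability import reliability_report
from .synthetic import generate_feature_table, modality_preset

logger = logging.getLogger("retest")


class StageError(RuntimeError):
    """A named pipeline stage failed."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Settings for one report run (flat key-value YAML on disk)."""

    inputs: dict[str, str]  # modality -> CSV path, or "synthetic"
    output_dir: str
    icc_form: str = "ICC(2,1)"
    standardize_pca: bool = True
    n_boot: int = 1000
    q_level: float = 0.05
    seed: int = 0
    strict: bool = False
    layout: str = "wide"
    n_subjects_synthetic: int = 20
    dice_volumes: tuple[str, str] | None = None
    timestamp_dir: bool = False
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        if "dice_volumes" in kwargs and kwargs["dice_volumes"] is not None:
            kwargs["dice_volumes"] = tuple(kwargs["dice_volumes"])
        return cls(**kwargs)

    def validate(self) -> None:
        for modality, path in self.inputs.items():
            if path != "synthetic" and not Path(path).exists():
                raise FileNotFoundError(
                    f"input for modality {modality!r} not found: {path}"
                )
        if self.dice_volumes:
            for p in self.dice_volumes:
                if not Path(p).exists():
                    raise FileNotFoundError(f"label volume not found: {p}")


def _write_matrix(path: Path, m: np.ndarray, ids: list[str]) -> None:
    pd.DataFrame(m, index=ids, columns=ids).to_csv(path, float_format="%.17g")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def _load_modality(config: RunConfig, modality: str, path: str) -> FeatureTable:
    if path == "synthetic":
        spec = modality_preset(
            modality, n_subjects=config.n_subjects_synthetic, seed=config.seed
        )
        table, _ = generate_feature_table(spec)
        return table
    return load_feature_table(
        path, layout=config.layout, modality=modality, strict=config.strict
    )


def run_report(config: RunConfig) -> dict:
    """Run every stage for every configured modality; return the manifest."""
    config.validate()
    out = Path(config.output_dir)
    if config.timestamp_dir:
        out = out / datetime.datetime.now().strftime("run-%Y%m%dT%H%M%S")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "retest",
        "version": __version__,
        "created": datetime.datetime.now().isoformat(timespec="seconds"),
        "settings": {
            "icc_form": config.icc_form,
            "standardize_pca": config.standardize_pca,
            "n_boot": config.n_boot,
            "q_level": config.q_level,
            "seed": config.seed,
            "layout": config.layout,
        },
        "modalities": {},
    }
    for modality, path in config.inputs.items():
        mdir = out / modality
        mdir.mkdir(exist_ok=True)
        table = _stage(f"{modality}/load")(_load_modality)(config, modality, path)
        seed_index = None
        if modality == "rsfmri_z":
            s = int(round((1 + np.sqrt(1 + 8 * table.n_features)) / 2))
            if s * (s - 1) // 2 == table.n_features:
                seed_index = SeedPairIndex([f"seed_{k + 1:02d}" for k in range(s)])

        rel = _stage(f"{modality}/reliability")(reliability_report)(
            table,
            icc_form=config.icc_form,
            n_boot=config.n_boot,
            seed=config.seed,
            seed_index=seed_index,
        )
        rel.write(mdir / "icc.csv", mdir / "reliability.json")
        if rel.per_seed_mean_icc is not None:
            pd.DataFrame(
                {"seed": rel.seed_names, "mean_icc": rel.per_seed_mean_icc}
            ).to_csv(mdir / "seed_mean_icc.csv", index=False, float_format="%.17g")

        fp = _stage(f"{modality}/fingerprint")(fingerprint)(
            table, standardize=config.standardize_pca
        )
        pd.DataFrame(
            fp.scores,
            columns=[f"PC{k + 1}" for k in range(fp.scores.shape[1])],
        ).to_csv(mdir / "pca_scores.csv", index=False, float_format="%.17g")
        _write_matrix(mdir / "cross_distance.csv", fp.cross_distance, fp.subject_ids)
        _write_matrix(mdir / "rank_matrix.csv", fp.rank_matrix, fp.subject_ids)
        (mdir / "fingerprint.json").write_text(
            json.dumps(
                {
                    "n_misclassified": fp.n_misclassified,
                    "n_misclassified_reverse": fp.n_misclassified_reverse,
                    "n_misclassified_either": fp.n_misclassified_either,
                    "misclassified": fp.misclassified,
                    "pair_distance_mean": fp.pair_distance_mean,
                    "pair_distance_sd": fp.pair_distance_sd,
                },
                indent=2,
            )
        )

        cmp_report = _stage(f"{modality}/comparison")(compare_sessions)(
            table, q_level=config.q_level
        )
        cmp_report.write(mdir / "comparison.csv", mdir / "comparison.json")

        manifest["modalities"][modality] = {
            "input": str(path),
            "n_subjects": table.n_subjects,
            "n_features": table.n_features,
            "i2c2": rel.i2c2,
            "i2c2_ci": list(rel.i2c2_ci),
            "n_misclassified": fp.n_misclassified,
            "n_significant": cmp_report.n_significant,
            "percent_difference_overall_abs": cmp_report.percent.overall_abs,
        }

    if config.dice_volumes:
        pair = _stage("dice/load")(load_label_volume_pair)(*config.dice_volumes)
        rep = _stage("dice/compute")(dice)(pair)
        rep.write(out / "dice.csv", out / "dice.json")
        manifest["dice"] = {"mean": rep.mean_dice, "sd": rep.sd_dice}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("report written to %s", out)
    return manifest
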