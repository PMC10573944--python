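"""Run configuration and end-to-end pipeline orchestration.

A :class:`RunConfig` (YAML-serializable, schema-validated, unknown keys
rejected) drives the full chain: curate → featurize → train → screen →
(optional cross-eval) → consensus. Every stage writes its outputs into the
run directory and the pipeline finishes with ``manifest.json`` recording
the config hash, package version, all seeds and per-stage record counts.
A stage failure leaves partial outputs behind a ``FAILED`` marker naming
the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

import selectscreen
from selectscreen.activity_nn import ActivityClassifier, NNModelSpec
from selectscreen.consensus import (
    DEFAULT_CUTOFF,
    consensus_select,
    hits_to_frame,
    read_dock_table,
    read_vina_directory,
)
from selectscreen.dataset_io import (
    clean_dataset,
    read_activity_table,
    split_dataset,
    write_activity_table,
)
from selectscreen.fingerprints import fingerprint_matrix
from selectscreen.screening import results_to_frame, screen_library
from selectscreen.selectivity_eval import cross_evaluate
from selectscreen.synthetic_data import (
    GeneratorSpec,
    generate_dock_scores,
    generate_receptor_library,
    generate_screening_library,
    generate_subtype_pair,
)

logger = logging.getLogger(__name__)


class DatasetConfig(BaseModel):
    """Where the training data comes from: a file or the synthetic generator."""

    model_config = ConfigDict(extra="forbid")

    path: str | None = None
    dialect: str = "simple"
    receptor: str = "SYN1"
    synthetic: bool = False
    n_scaffolds: int = 12
    substituents_per_scaffold: int = 50
    inactive_fraction: float = 0.25
    noise_sd: float = 0.4


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fraction: float = 0.8
    epochs: int = 100
    hidden_layers: tuple[int, ...] = (512, 128)
    batch_size: int = 32
    learning_rate: float = 1e-3


class ScreenConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    library_path: str | None = None
    synthetic_library_size: int = 200
    min_class: int = 7


class DockConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    path: str | None = None  # CSV table or directory of PDBQT files
    synthetic: bool = True
    cutoff: float = DEFAULT_CUTOFF
    synthetic_mean: float = -9.5
    synthetic_sd: float = 1.0


class RunConfig(BaseModel):
    """Complete, schema-validated configuration of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_bits: int = 2048
    dataset: DatasetConfig = Field(default_factory=DatasetConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    screen: ScreenConfig = Field(default_factory=ScreenConfig)
    dock: DockConfig = Field(default_factory=DockConfig)
    crosseval: bool = False
    crosseval_overlap: float = 0.5
    crosseval_runs: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full virtual-screening pipeline into ``out_dir``.

    Returns the run directory; raises RuntimeError naming the failed stage
    (partial outputs are kept next to a FAILED marker file).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "package_version": selectscreen.__version__,
        "seed": config.seed,
        "stages": {},
    }
    stage = "init"
    try:
        # -- curate ----------------------------------------------------
        stage = "curate"
        if config.dataset.synthetic or config.dataset.path is None:
            gen = GeneratorSpec(
                n_scaffolds=config.dataset.n_scaffolds,
                substituents_per_scaffold=config.dataset.substituents_per_scaffold,
                inactive_fraction=config.dataset.inactive_fraction,
                noise_sd=config.dataset.noise_sd,
                seed=config.seed,
                n_bits=config.n_bits,
            )
            ds = generate_receptor_library(gen, receptor=config.dataset.receptor)
        else:
            path = Path(config.dataset.path)
            if not path.exists():
                raise FileNotFoundError(f"dataset path does not exist: {path}")
            ds = read_activity_table(
                path, dialect=config.dataset.dialect,
                receptor=config.dataset.receptor,
            )
        ds = clean_dataset(ds)
        write_activity_table(ds, out / "curated.csv")
        manifest["stages"]["curate"] = {"n_records": len(ds)}

        # -- split + featurize ------------------------------------------
        stage = "featurize"
        split = split_dataset(ds, fraction=config.train.fraction, seed=config.seed)
        train_ds = ds.subset(split.train_indices)
        val_ds = ds.subset(split.validation_indices)
        Xtr = fingerprint_matrix(train_ds.smiles(), n_bits=config.n_bits)
        Xva = fingerprint_matrix(val_ds.smiles(), n_bits=config.n_bits)
        manifest["stages"]["featurize"] = {
            "n_train": len(train_ds),
            "n_validation": len(val_ds),
            "n_bits": config.n_bits,
        }

        # -- train -------------------------------------------------------
        stage = "train"
        spec = NNModelSpec(
            input_width=config.n_bits,
            hidden_layers=config.train.hidden_layers,
            learning_rate=config.train.learning_rate,
            epochs=config.train.epochs,
            batch_size=config.train.batch_size,
            seed=config.seed,
        )
        model = ActivityClassifier.build(spec).train(Xtr, train_ds.classes())
        res = model.evaluate(Xva, val_ds.classes())
        model.save(out / "model")
        manifest["stages"]["train"] = {
            "epochs": config.train.epochs,
            "validation_loss": res.loss,
            "validation_accuracy": res.accuracy,
        }

        # -- optional cross-eval ----------------------------------------
        if config.crosseval:
            stage = "crosseval"
            gen = GeneratorSpec(
                n_scaffolds=config.dataset.n_scaffolds,
                substituents_per_scaffold=config.dataset.substituents_per_scaffold,
                inactive_fraction=config.dataset.inactive_fraction,
                noise_sd=config.dataset.noise_sd,
                overlap=config.crosseval_overlap,
                seed=config.seed,
                n_bits=config.n_bits,
            )
            ds_a, ds_b = generate_subtype_pair(gen)
            pairs = {}
            for sub in (ds_a, ds_b):
                s = split_dataset(sub, fraction=config.train.fraction,
                                  seed=config.seed)
                pairs[sub.receptor] = (
                    sub.subset(s.train_indices), sub.subset(s.validation_indices)
                )
            matrix = cross_evaluate(
                pairs, spec=spec, n_runs=config.crosseval_runs,
                base_seed=config.seed, epochs=config.train.epochs,
            )
            matrix.to_frame().to_csv(out / "crosseval.csv", index=False)
            manifest["stages"]["crosseval"] = {"n_cells": len(matrix.cells)}

        # -- screen ------------------------------------------------------
        stage = "screen"
        if config.screen.library_path is not None:
            lib_path = Path(config.screen.library_path)
            if not lib_path.exists():
                raise FileNotFoundError(f"library path does not exist: {lib_path}")
            lib_ds = read_activity_table(lib_path)
            library = list(zip(lib_ds.ids(), lib_ds.smiles()))
        else:
            library = generate_screening_library(
                config.screen.synthetic_library_size, seed=config.seed + 1
            )
        results = screen_library(model, library, n_bits=config.n_bits)
        results_to_frame(results).to_csv(out / "screen.csv", index=False)
        manifest["stages"]["screen"] = {"n_screened": len(results)}

        # -- consensus ---------------------------------------------------
        stage = "consensus"
        if config.dock.path is not None:
            dock_path = Path(config.dock.path)
            if dock_path.is_dir():
                dock = read_vina_directory(dock_path)
            else:
                dock = read_dock_table(dock_path)
        else:
            dock = generate_dock_scores(
                [cid for cid, _ in library],
                seed=config.seed + 2,
                mean=config.dock.synthetic_mean,
                sd=config.dock.synthetic_sd,
            )
        hits = consensus_select(
            results, dock, min_class=config.screen.min_class,
            cutoff=config.dock.cutoff,
        )
        hits_to_frame(hits).to_csv(out / "consensus.csv", index=False)
        manifest["stages"]["consensus"] = {
            "n_dock_scores": len(dock),
            "n_hits": len(hits),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
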