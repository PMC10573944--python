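"""Receptor-subtype selectivity cross-evaluation.

For each receptor a classifier is trained on that receptor's training set
and evaluated on *every* receptor's validation set. A model that has truly
learned subtype-specific structure–activity relationships should lose
accuracy on mismatched subtypes; the size of the drop, paired with the
Tanimoto similarity between the training and validation sets, quantifies
how much of the transfer (or failure to transfer) is explained by plain
chemical-space overlap. Metrics can be averaged over repeated independent
training runs (seeds base_seed, base_seed+1, ...), the protocol used when
reporting run-averaged tables.

The accuracy change of a cell is reported as other-minus-matched: the
model's accuracy on the foreign validation set minus the same ensemble's
accuracy on its own subtype, so matched cells have change exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from selectscreen.activity_nn import ActivityClassifier, NNModelSpec
from selectscreen.dataset_io import ActivityDataset
from selectscreen.fingerprints import cross_set_similarity, fingerprint_matrix

logger = logging.getLogger(__name__)

#: Seed list used by the packaged selectivity benchmark protocol.
SELECTIVITY_SEEDS: tuple[int, ...] = (101, 202, 303)

#: Scaffold-overlap grid of the packaged selectivity benchmark.
OVERLAP_GRID: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class CrossEvalCell:
    """One (training receptor × validation receptor) evaluation."""

    train_receptor: str
    val_receptor: str
    loss: float
    accuracy: float
    accuracy_change: float  # other-minus-matched; 0 on the diagonal
    avg_tanimoto: float
    mode_tanimoto: float
    n_train: int
    n_val: int
    loss_std: float = 0.0
    accuracy_std: float = 0.0


@dataclass
class CrossEvalMatrix:
    """All cells of a cross-receptor evaluation plus the run protocol used."""

    cells: list[CrossEvalCell]
    n_runs: int
    base_seed: int

    def to_frame(self) -> pd.DataFrame:
        """Tabular view mirroring the conventional selectivity-table layout."""
        return pd.DataFrame(
            {
                "train_receptor": [c.train_receptor for c in self.cells],
                "val_receptor": [c.val_receptor for c in self.cells],
                "n_train": [c.n_train for c in self.cells],
                "n_val": [c.n_val for c in self.cells],
                "loss": [c.loss for c in self.cells],
                "accuracy": [c.accuracy for c in self.cells],
                "accuracy_change": [c.accuracy_change for c in self.cells],
                "avg_tanimoto": [c.avg_tanimoto for c in self.cells],
                "mode_tanimoto": [c.mode_tanimoto for c in self.cells],
            }
        )

    def cell(self, train: str, val: str) -> CrossEvalCell:
        for c in self.cells:
            if c.train_receptor == train and c.val_receptor == val:
                return c
        raise KeyError(f"no cell ({train!r}, {val!r})")


def _featurize(ds: ActivityDataset, n_bits: int) -> tuple[np.ndarray, np.ndarray]:
    return fingerprint_matrix(ds.smiles(), n_bits=n_bits), ds.classes()


def cross_evaluate(
    datasets: Mapping[str, tuple[ActivityDataset, ActivityDataset]],
    spec: NNModelSpec | None = None,
    n_runs: int = 1,
    base_seed: int = 0,
    epochs: int | None = None,
) -> CrossEvalMatrix:
    """Train one model (ensemble) per receptor and evaluate on all subtypes.

    ``datasets`` maps receptor name → (training set, validation set). For
    each training receptor, ``n_runs`` models are trained with seeds
    ``base_seed + run`` and their loss/accuracy on every validation set is
    arithmetically averaged. Each cell also carries the all-pairs Tanimoto
    diagnostics between the training set and that validation set.
    """
    if len(datasets) < 2:
        raise ValueError("cross-evaluation needs at least 2 receptors")
    for name, pair in datasets.items():
        if len(pair) != 2 or pair[1] is None:
            raise ValueError(f"receptor {name!r} lacks a validation set")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    spec = spec or NNModelSpec()

    feats = {
        name: (_featurize(tr, spec.input_width), _featurize(va, spec.input_width))
        for name, (tr, va) in datasets.items()
    }
    receptors = list(datasets)
    cells: list[CrossEvalCell] = []
    for train_name in receptors:
        (Xtr, ytr), _ = feats[train_name]
        # run-level metric stacks: metrics[val_name] = list of (loss, acc)
        metrics: dict[str, list[tuple[float, float]]] = {r: [] for r in receptors}
        for run in range(n_runs):
            run_spec = NNModelSpec(
                input_width=spec.input_width,
                hidden_layers=spec.hidden_layers,
                learning_rate=spec.learning_rate,
                epochs=spec.epochs if epochs is None else epochs,
                batch_size=spec.batch_size,
                seed=base_seed + run,
            )
            model = ActivityClassifier.build(run_spec).train(Xtr, ytr)
            for val_name in receptors:
                _, (Xva, yva) = feats[val_name]
                res = model.evaluate(Xva, yva)
                metrics[val_name].append((res.loss, res.accuracy))
        matched_acc = float(np.mean([a for _, a in metrics[train_name]]))
        for val_name in receptors:
            losses = np.array([l for l, _ in metrics[val_name]])
            accs = np.array([a for _, a in metrics[val_name]])
            sim = cross_set_similarity(
                feats[train_name][0][0], feats[val_name][1][0]
            )
            cells.append(
                CrossEvalCell(
                    train_receptor=train_name,
                    val_receptor=val_name,
                    loss=float(losses.mean()),
                    accuracy=float(accs.mean()),
                    accuracy_change=float(accs.mean()) - matched_acc,
                    avg_tanimoto=sim.average,
                    mode_tanimoto=sim.mode,
                    n_train=len(ytr),
                    n_val=len(feats[val_name][1][1]),
                    loss_std=float(losses.std(ddof=0)),
                    accuracy_std=float(accs.std(ddof=0)),
                )
            )
        logger.info("cross_evaluate: finished training receptor %s (%d runs)",
                    train_name, n_runs)
    return CrossEvalMatrix(cells=cells, n_runs=n_runs, base_seed=base_seed)


@dataclass(frozen=True)
class RepeatedRunSummary:
    """Mean and dispersion of loss/accuracy over independent training runs."""

    mean_loss: float
    std_loss: float
    mean_accuracy: float
    std_accuracy: float
    n_runs: int
    run_metrics: tuple[tuple[float, float], ...] = field(default=())


def repeated_training_summary(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    spec: NNModelSpec | None = None,
    n_runs: int = 100,
    epochs: int = 100,
    base_seed: int = 0,
) -> RepeatedRunSummary:
    """Average validation loss/accuracy over ``n_runs`` independent trainings.

    Run ``i`` uses seed ``base_seed + i``; the summary is the arithmetic
    mean and population standard deviation over runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    spec = spec or NNModelSpec()
    Xtr, ytr = train
    Xva, yva = val
    run_metrics: list[tuple[float, float]] = []
    for run in range(n_runs):
        run_spec = NNModelSpec(
            input_width=spec.input_width,
            hidden_layers=spec.hidden_layers,
            learning_rate=spec.learning_rate,
            epochs=epochs,
            batch_size=spec.batch_size,
            seed=base_seed + run,
        )
        model = ActivityClassifier.build(run_spec).train(Xtr, ytr)
        res = model.evaluate(Xva, yva)
        run_metrics.append((res.loss, res.accuracy))
    losses = np.array([l for l, _ in run_metrics])
    accs = np.array([a for _, a in run_metrics])
    return RepeatedRunSummary(
        mean_loss=float(losses.mean()),
        std_loss=float(losses.std(ddof=0)),
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std(ddof=0)),
        n_runs=n_runs,
        run_metrics=tuple(run_metrics),
    )


def selectivity_benchmark(
    seeds: Sequence[int] = SELECTIVITY_SEEDS,
    overlaps: Sequence[float] = OVERLAP_GRID,
    n_scaffolds: int = 12,
    substituents_per_scaffold: int = 50,
    n_bits: int = 1024,
    hidden_layers: tuple[int, ...] = (256, 64),
    epochs: int = 100,
    fraction: float = 0.8,
    n_runs: int = 1,
) -> pd.DataFrame:
    """Run the packaged synthetic selectivity protocol.

    For every (seed, scaffold overlap) combination a receptor-subtype pair
    is generated, split 80/20, and cross-evaluated; the returned table has
    one row per cross-evaluation cell with ``seed``, ``overlap`` and
    ``matched`` columns added. Problem sizes default to a single-CPU-scale
    benchmark (600 compounds per receptor, 100 epochs).
    """
    from selectscreen.dataset_io import split_dataset
    from selectscreen.synthetic_data import GeneratorSpec, generate_subtype_pair

    frames = []
    for seed in seeds:
        for overlap in overlaps:
            gen = GeneratorSpec(
                n_scaffolds=n_scaffolds,
                substituents_per_scaffold=substituents_per_scaffold,
                overlap=overlap,
                seed=seed,
                n_bits=n_bits,
            )
            pairs = {}
            for ds in generate_subtype_pair(gen):
                split = split_dataset(ds, fraction=fraction, seed=seed)
                pairs[ds.receptor] = (
                    ds.subset(split.train_indices),
                    ds.subset(split.validation_indices),
                )
            spec = NNModelSpec(
                input_width=n_bits, hidden_layers=hidden_layers, seed=seed
            )
            matrix = cross_evaluate(
                pairs, spec=spec, n_runs=n_runs, base_seed=seed, epochs=epochs
            )
            df = matrix.to_frame()
            df.insert(0, "seed", seed)
            df.insert(1, "overlap", overlap)
            df["matched"] = df["train_receptor"] == df["val_receptor"]
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def accuracy_similarity_correlation(
    matrix: CrossEvalMatrix | Sequence[CrossEvalCell],
) -> tuple[float, pd.DataFrame]:
    """Spearman rank correlation between cell accuracy and average Tanimoto.

    Returns the coefficient and the (accuracy, avg_tanimoto) pairing table
    used, for audit. Requires at least 3 cells.
    """
    cells = matrix.cells if isinstance(matrix, CrossEvalMatrix) else list(matrix)
    if len(cells) < 3:
        raise ValueError("need at least 3 cells for a rank correlation")
    pairs = pd.DataFrame(
        {
            "train_receptor": [c.train_receptor for c in cells],
            "val_receptor": [c.val_receptor for c in cells],
            "accuracy": [c.accuracy for c in cells],
            "avg_tanimoto": [c.avg_tanimoto for c in cells],
        }
    )
    rho = stats.spearmanr(pairs["accuracy"], pairs["avg_tanimoto"]).statistic
    return float(rho), pairs
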