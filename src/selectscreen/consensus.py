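"""Docking-score ingestion and NN+docking consensus selection.

Docking results arrive either as AutoDock Vina PDBQT output (multi-MODEL
files with ``REMARK VINA RESULT`` lines) or as delimited score tables.
Affinities are in kcal/mol; more negative is stronger. Poses at or below
the energy cutoff (default −10.5 kcal/mol, inclusive) pass the filter, and
each compound is summarized by its best (minimum-affinity) pose.

The consensus step intersects the classifier's top-range selection with the
docking survivors: a compound becomes a hit only if both routes flag it.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from selectscreen.screening import ScreenResult

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = -10.5  # kcal/mol, inclusive

_VINA_RE = re.compile(
    r"REMARK VINA RESULT:\s+(-?\d+(?:\.\d+)?)\s+(-?\d+(?:\.\d+)?)\s+(-?\d+(?:\.\d+)?)"
)


@dataclass(frozen=True)
class DockScore:
    """One docking pose: compound, affinity (kcal/mol) and pose index (1-based)."""

    compound_id: str
    affinity: float
    pose_index: int = 1
    source: str = ""

    def __post_init__(self) -> None:
        if self.pose_index < 1:
            raise ValueError(f"pose_index must be >= 1, got {self.pose_index}")


@dataclass(frozen=True)
class ConsensusHit:
    """A compound selected by both the classifier and the docking filter."""

    compound_id: str
    predicted_class: int
    ranking_score: float
    best_affinity: float
    passed_nn: bool = True
    passed_dock: bool = True


def read_vina_scores(path: str | Path, compound_id: str | None = None) -> list[DockScore]:
    """Parse a Vina-output PDBQT file into one DockScore per pose.

    Pose indices follow MODEL numbering when present, otherwise the order of
    ``REMARK VINA RESULT`` lines. The compound id defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"docking file not found: {path}")
    cid = compound_id if compound_id is not None else path.stem
    scores: list[DockScore] = []
    current_model: int | None = None
    for line in path.read_text().splitlines():
        if line.startswith("MODEL"):
            parts = line.split()
            current_model = int(parts[1]) if len(parts) > 1 else None
        match = _VINA_RE.search(line)
        if match:
            pose = current_model if current_model is not None else len(scores) + 1
            scores.append(
                DockScore(
                    compound_id=cid,
                    affinity=float(match.group(1)),
                    pose_index=pose,
                    source=str(path),
                )
            )
            current_model = None
    if not scores:
        raise ValueError(f"no REMARK VINA RESULT lines found in {path}")
    return scores


def read_vina_directory(directory: str | Path, pattern: str = "*.pdbqt") -> list[DockScore]:
    """Parse every PDBQT file in a directory (file stem = compound id)."""
    directory = Path(directory)
    scores: list[DockScore] = []
    for path in sorted(directory.glob(pattern)):
        scores.extend(read_vina_scores(path))
    if not scores:
        raise ValueError(f"no docking scores found under {directory}")
    return scores


def read_dock_table(
    path: str | Path,
    id_column: str = "compound_id",
    affinity_column: str = "affinity",
    pose_column: str | None = "pose_index",
    sep: str | None = None,
) -> list[DockScore]:
    """Read a delimited docking-score table (id, affinity[, pose]) into DockScores."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"docking table not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in (id_column, affinity_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    has_pose = pose_column is not None and pose_column in df.columns
    return [
        DockScore(
            compound_id=str(row[id_column]).strip(),
            affinity=float(row[affinity_column]),
            pose_index=int(row[pose_column]) if has_pose else 1,
            source=str(path),
        )
        for _, row in df.iterrows()
    ]


def apply_energy_cutoff(
    scores: Sequence[DockScore], cutoff: float = DEFAULT_CUTOFF
) -> list[DockScore]:
    """Keep poses with affinity ≤ cutoff (inclusive); order-preserving and
    idempotent. ``cutoff=math.inf`` disables the filter."""
    return [s for s in scores if s.affinity <= cutoff]


def best_poses(scores: Sequence[DockScore]) -> dict[str, float]:
    """Best (minimum) affinity per compound."""
    best: dict[str, float] = {}
    for s in scores:
        cid = s.compound_id.strip()
        if cid not in best or s.affinity < best[cid]:
            best[cid] = s.affinity
    return best


def top_n_by_affinity(scores: Sequence[DockScore], n: int) -> list[DockScore]:
    """The n best-affinity poses across compounds (count-based alternative
    to the energy cutoff)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sorted(scores, key=lambda s: s.affinity)[:n]


def consensus_select(
    screen: Sequence["ScreenResult"],
    dock: Sequence[DockScore],
    min_class: int = 7,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[ConsensusHit]:
    """Intersect top-range classifier selections with docking survivors.

    A hit must (a) be predicted in class ≥ ``min_class`` and (b) have at
    least one pose at or below ``cutoff``. Hits are ordered by ranking
    score descending, then best affinity ascending. Non-overlapping id
    spaces yield an empty list with a warning.
    """
    from selectscreen.screening import select_top_by_range

    nn_selected = select_top_by_range(screen, min_class=min_class)
    surviving = apply_energy_cutoff(dock, cutoff=cutoff)
    best = best_poses(surviving)
    if nn_selected and dock and not (
        {r.compound_id.strip() for r in screen} & {s.compound_id.strip() for s in dock}
    ):
        logger.warning("consensus_select: screening and docking id spaces do not overlap")
    hits = [
        ConsensusHit(
            compound_id=r.compound_id,
            predicted_class=r.predicted_class,
            ranking_score=r.ranking_score,
            best_affinity=best[r.compound_id.strip()],
        )
        for r in nn_selected
        if r.compound_id.strip() in best
    ]
    hits.sort(key=lambda h: (-h.ranking_score, h.best_affinity))
    return hits


def hits_to_frame(hits: Sequence[ConsensusHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [h.compound_id for h in hits],
            "predicted_class": [h.predicted_class for h in hits],
            "ranking_score": [h.ranking_score for h in hits],
            "best_affinity": [h.best_affinity for h in hits],
        }
    )
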