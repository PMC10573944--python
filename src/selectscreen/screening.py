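"""Library screening with a trained activity classifier and percent-rank reporting.

Each library compound receives the model's seven-class probability
distribution, a predicted activity class/range, and a scalar ranking score
defined as the expected class ordinal Σₖ pₖ·k (k = 1..7). The library is
then ranked best-first and each compound's position is expressed as a
percent rank 100·rank/N — "in X% of top predictions". A within-range
percent rank is computed analogously among the compounds sharing the
predicted class, e.g. "top predictions in the 9-above activity range".

Ranking ties are broken by the probability of the top class and then by
library order, so percent ranks over a library are a permutation of
{100·i/N : i = 1..N}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from selectscreen.activity_nn import ActivityClassifier, N_CLASSES
from selectscreen.dataset_io import RANGE_LABELS
from selectscreen.fingerprints import fingerprint_matrix

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Prediction and ranking of one library compound."""

    compound_id: str
    class_distribution: np.ndarray  # 7-vector summing to 1
    predicted_class: int  # argmax, ties toward the lower class
    range_label: str
    ranking_score: float  # expected class ordinal in [1, 7]
    overall_percent_rank: float  # 100·rank/N, rank 1 = best
    within_range_percent_rank: float


def expected_class_score(proba: np.ndarray) -> np.ndarray:
    """Expected class ordinal Σ p_k·k per row; equals k for a one-hot row."""
    k = np.arange(1, N_CLASSES + 1)
    return np.asarray(proba) @ k


def screen_library(
    model: ActivityClassifier,
    library: Sequence[tuple[str, str]],
    n_bits: int | None = None,
) -> list[ScreenResult]:
    """Score a SMILES library; one :class:`ScreenResult` per parseable compound.

    ``library`` is a sequence of (compound_id, smiles) pairs. Compounds whose
    SMILES cannot be parsed are logged and skipped. Results are returned in
    library order with both percent ranks filled in.
    """
    if len(library) == 0:
        raise ValueError("screening library is empty")
    n_bits = n_bits if n_bits is not None else model.spec.input_width

    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for cid, smi in library:
        try:
            rows.append(fingerprint_matrix([smi], n_bits=n_bits)[0])
            ids.append(cid)
        except ValueError:
            n_skipped += 1
            logger.warning("screen_library: skipping unparseable SMILES %r (%s)",
                           smi, cid)
    if not rows:
        raise ValueError("no parseable compounds in the library")
    if n_skipped:
        logger.info("screen_library: skipped %d unparseable compounds", n_skipped)

    proba = model.predict_proba(np.stack(rows))
    pred = np.argmax(proba, axis=1) + 1
    scores = expected_class_score(proba)
    n = len(ids)

    order = _ranking_order(scores, proba, pred)
    overall_rank = np.empty(n, dtype=np.int64)
    overall_rank[order] = np.arange(1, n + 1)

    within_rank = np.empty(n, dtype=np.int64)
    within_n = np.empty(n, dtype=np.int64)
    for cls in np.unique(pred):
        members = np.flatnonzero(pred == cls)
        sub_order = members[np.argsort(overall_rank[members], kind="stable")]
        within_rank[sub_order] = np.arange(1, len(members) + 1)
        within_n[members] = len(members)

    return [
        ScreenResult(
            compound_id=ids[i],
            class_distribution=proba[i],
            predicted_class=int(pred[i]),
            range_label=RANGE_LABELS[int(pred[i])],
            ranking_score=float(scores[i]),
            overall_percent_rank=100.0 * overall_rank[i] / n,
            within_range_percent_rank=100.0 * within_rank[i] / within_n[i],
        )
        for i in range(n)
    ]


def _ranking_order(
    scores: np.ndarray, proba: np.ndarray, pred: np.ndarray
) -> np.ndarray:
    """Best-first index order: expected-class score desc, then probability of
    the top class desc, then library order (stable)."""
    p_top = proba[:, N_CLASSES - 1]
    return np.lexsort((np.arange(len(scores)), -p_top, -scores))


def select_top_by_range(
    results: Sequence[ScreenResult], min_class: int = 7
) -> list[ScreenResult]:
    """Compounds whose predicted class reaches ``min_class``, best first."""
    if not 1 <= min_class <= N_CLASSES:
        raise ValueError(f"min_class must be in 1..7, got {min_class}")
    if len(results) == 0:
        raise ValueError("no screening results to select from")
    chosen = [r for r in results if r.predicted_class >= min_class]
    return sorted(chosen, key=lambda r: r.overall_percent_rank)


def percent_rank_report(
    results: Sequence[ScreenResult], targets: Sequence[str]
) -> pd.DataFrame:
    """Percent-rank table for named target compounds, in target order.

    Columns: compound_id, range_label, overall and within-range percent
    ranks formatted to one decimal place.
    """
    by_id = {r.compound_id: r for r in results}
    rows = []
    for cid in targets:
        if cid not in by_id:
            raise KeyError(f"target compound {cid!r} not found in screening results")
        r = by_id[cid]
        rows.append(
            {
                "compound_id": cid,
                "range_label": r.range_label,
                "overall_percent_rank": round(r.overall_percent_rank, 1),
                "within_range_percent_rank": round(r.within_range_percent_rank, 1),
            }
        )
    return pd.DataFrame(rows)


def results_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Flatten screening results (ranked best-first) into a DataFrame."""
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in results],
            "predicted_class": [r.predicted_class for r in results],
            "range_label": [r.range_label for r in results],
            "ranking_score": [r.ranking_score for r in results],
            "overall_percent_rank": [r.overall_percent_rank for r in results],
            "within_range_percent_rank": [
                r.within_range_percent_rank for r in results
            ],
        }
    )
    return df.sort_values("overall_percent_rank", kind="stable").reset_index(
        drop=True
    )
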