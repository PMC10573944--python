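"""ECFP4 featurization, Tanimoto similarity and cross-dataset summaries.

Fingerprints are extended-connectivity (Morgan) fingerprints of radius 2
(bond diameter 4) folded to a fixed-length binary vector, computed with
RDKit. Similarity between two fingerprints is the Tanimoto (Jaccard)
coefficient |a∩b| / |a∪b|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

DEFAULT_N_BITS = 2048
RADIUS = 2  # bond diameter 4


@dataclass(frozen=True)
class Fingerprint:
    """A folded binary ECFP4 feature vector."""

    bits: np.ndarray  # uint8 0/1 vector of length n_bits
    n_bits: int = DEFAULT_N_BITS
    radius: int = RADIUS

    def __post_init__(self) -> None:
        if self.bits.shape != (self.n_bits,):
            raise ValueError(
                f"bit vector length {self.bits.shape} != n_bits {self.n_bits}"
            )

    def popcount(self) -> int:
        return int(self.bits.sum())

    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return self.n_bits == other.n_bits and bool(
            np.array_equal(self.bits, other.bits)
        )


@dataclass(frozen=True)
class SimilaritySummary:
    """Average and modal Tanimoto coefficient over a set of pairs."""

    average: float
    mode: float
    n_pairs: int


_GENERATORS: dict[int, "rdFingerprintGenerator.FingerprintGenerator64"] = {}


def _generator(n_bits: int):
    if n_bits not in _GENERATORS:
        _GENERATORS[n_bits] = rdFingerprintGenerator.GetMorganGenerator(
            radius=RADIUS, fpSize=n_bits
        )
    return _GENERATORS[n_bits]


def ecfp4(smiles: str, n_bits: int = DEFAULT_N_BITS) -> Fingerprint:
    """ECFP4 fingerprint of a molecule given as SMILES.

    Invariant to the SMILES spelling of the same molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    arr = np.zeros(n_bits, dtype=np.uint8)
    fp = _generator(n_bits).GetFingerprint(mol)
    arr[list(fp.GetOnBits())] = 1
    return Fingerprint(bits=arr, n_bits=n_bits)


def fingerprint_matrix(
    smiles: Sequence[str], n_bits: int = DEFAULT_N_BITS
) -> np.ndarray:
    """Stack ECFP4 fingerprints of many molecules into an (n, n_bits) matrix."""
    out = np.zeros((len(smiles), n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles):
        out[i] = ecfp4(smi, n_bits=n_bits).bits
    return out


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| in [0, 1].

    Defined as 0 when both bit vectors are empty.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        return 0.0
    return inter / union


def pairwise_tanimoto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto between the rows of two 0/1 matrices."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint length mismatch between matrices")
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def _round_to_grid(values: np.ndarray, bin_width: float) -> np.ndarray:
    # nearest grid multiple; exact halfway rounds to the lower bin
    return np.ceil(values / bin_width - 0.5) * bin_width


def cross_set_similarity(
    A: np.ndarray | Sequence[Fingerprint],
    B: np.ndarray | Sequence[Fingerprint],
    bin_width: float = 0.01,
    method: Literal["all_pairs", "max"] = "all_pairs",
) -> SimilaritySummary:
    """Average and modal Tanimoto coefficient between two fingerprint sets.

    ``method="all_pairs"`` (default) summarizes all |A|·|B| cross pairs;
    ``method="max"`` summarizes each A-member's best match in B (an
    asymmetric nearest-neighbour reading). The mode is the most frequent
    value after rounding to ``bin_width`` (ties resolved to the lower bin),
    matching the two-decimal resolution at which such diagnostics are
    conventionally reported.
    """
    A = _as_matrix(A)
    B = _as_matrix(B)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("cross_set_similarity requires non-empty collections")
    sims = pairwise_tanimoto(A, B)
    if method == "max":
        values = sims.max(axis=1)
        n_pairs = A.shape[0]
    elif method == "all_pairs":
        values = sims.ravel()
        n_pairs = sims.size
    else:
        raise ValueError(f"unknown method {method!r}")
    binned = _round_to_grid(values, bin_width)
    uniq, counts = np.unique(binned, return_counts=True)
    mode = float(uniq[np.argmax(counts)])  # first (lowest) bin on count ties
    return SimilaritySummary(
        average=float(values.mean()), mode=mode, n_pairs=int(n_pairs)
    )


def _as_matrix(X: np.ndarray | Sequence[Fingerprint]) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return X
    fps = list(X)
    if not fps:
        return np.zeros((0, DEFAULT_N_BITS), dtype=np.uint8)
    return np.stack([fp.bits for fp in fps])


def top_k_similar(
    query: Fingerprint,
    library: Sequence[tuple[str, Fingerprint]] | dict[str, Fingerprint],
    k: int,
) -> list[tuple[str, float]]:
    """The k library members most similar to the query, best first.

    Ties are broken by library order (stable sort); returns
    ``min(k, |library|)`` entries.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    items = list(library.items()) if isinstance(library, dict) else list(library)
    if not items:
        raise ValueError("library must be non-empty")
    sims = np.array([tanimoto(query, fp) for _, fp in items])
    order = np.argsort(-sims, kind="stable")[:k]
    return [(items[i][0], float(sims[i])) for i in order]


def save_fingerprint_matrix(
    X: np.ndarray, path: str | Path, n_bits: int, dataset_hash: str = ""
) -> None:
    """Persist a fingerprint matrix (compressed) plus a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, bits=X.astype(np.uint8))
    meta = {"n_bits": n_bits, "radius": RADIUS, "dataset_hash": dataset_hash,
            "n_compounds": int(X.shape[0])}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_fingerprint_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    data = np.load(npz)["bits"]
    meta = json.loads(Path(npz).with_suffix(".json").read_text())
    return data, meta
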