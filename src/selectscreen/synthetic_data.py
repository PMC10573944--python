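"""Synthetic congeneric-series activity data, screening libraries and docking scores.

The generator emulates the structure of curated ChEMBL bioactivity exports
without any pharmacological realism claim. Each dataset is a union of
congeneric series: a *scaffold* (a small ring-system template carrying one
fixed decoration) substituted at a single marked attachment point with
substituents drawn from a combinatorial fragment grammar. SMILES are built
by text substitution on vetted templates, which guarantees chemical validity
by construction (and is re-verified in tests).

Activity follows a latent model: pChEMBL = clip(scaffold base effect +
w·fingerprint_bits + Gaussian noise, 0, 11), where ``w`` is a sparse random
weight vector over ECFP4 bits. Scaffold identity is recoverable from the
fingerprint, so the induced class labels are learnable but — through noise,
clipping and an inactive fraction — imperfect. A configurable fraction of
records is set to pChEMBL = 0, the inactive sentinel, irrespective of
structure, mirroring the large inactive fractions of real curated sets.

Receptor-subtype pairs share a controllable fraction of scaffolds. Shared
scaffolds keep their base effect across the two receptors (plus a small
selectivity jitter), while each receptor draws its own latent bit weights;
unshared scaffolds come from chemically distinct template families, which
depresses cross-set Tanimoto similarity at low overlap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from selectscreen.consensus import DockScore
from selectscreen.dataset_io import (
    ActivityDataset,
    CompoundRecord,
    assign_activity_class,
)
from selectscreen.fingerprints import fingerprint_matrix

# Scaffold templates: {D} is a fixed decoration chosen at scaffold-creation
# time, {R} the congeneric substitution point. Family A is (hetero)aromatic,
# family B aliphatic — chemically distinct so that zero-overlap subtype
# pairs have low cross-set Tanimoto similarity.
TEMPLATES_A = (
    "c1cc({D})cc({R})c1",
    "c1cc({D})ccc1-c1ccc({R})cc1",
    "c1ccc2cc({R})c({D})cc2c1",
    "c1cc({D})nc({R})c1",
    "c1cc({R})oc1-c1ccc({D})cc1",
)
TEMPLATES_B = (
    "C1CC({D})CC({R})C1",
    "C({R})C1CCC({D})CC1",
    "C1COC({D})C({R})C1",
    "C1CN({D})CC({R})C1",
    "C1CSC({D})C({R})C1",
)

# Carbon-initial decorations (safe on ring carbons and ring nitrogens).
DECORATIONS = ("C", "CC", "CCC", "CO", "CN", "C(C)C", "CCO", "C(F)(F)F")

# Substituent grammar: alkyl linker of length 0..L prepended to a terminal
# group. All fragments start with an atom symbol valid at the attachment.
TERMINAL_GROUPS = (
    "C", "CC", "O", "OC", "N", "NC", "F", "Cl", "Br",
    "C#N", "C(=O)C", "C(=O)N", "C(=O)O", "S", "SC", "CO", "CN",
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic activity-data generator.

    noise_sd is in pChEMBL units; overlap is the fraction of scaffolds a
    subtype pair shares; inactive_fraction of records get the pChEMBL = 0
    sentinel regardless of structure.
    """

    n_scaffolds: int = 20
    substituents_per_scaffold: int = 100
    overlap: float = 0.0
    inactive_fraction: float = 0.25
    noise_sd: float = 0.4
    seed: int = 0
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        if self.substituents_per_scaffold < 1:
            raise ValueError("substituents_per_scaffold must be >= 1")
        for name in ("overlap", "inactive_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {val}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


#: Separable preset for label-recovery checks: no inactive sentinel records,
#: low noise — classes are determined by structure up to mild noise.
SEPARABLE = GeneratorSpec(inactive_fraction=0.0, noise_sd=0.2)

PCHEMBL_CLIP = (0.0, 11.0)
BASE_RANGE = (3.5, 9.5)  # scaffold base effects span the seven classes
WEIGHT_SD = 0.15  # latent weight scale per fingerprint bit
WEIGHT_DENSITY = 0.05  # fraction of bits with non-zero latent weight
SELECTIVITY_SD = 0.5  # base-effect jitter of shared scaffolds across subtypes


def substituent_list(count: int) -> list[str]:
    """First ``count`` substituent fragments from the deterministic grammar."""
    seen: dict[str, None] = {}
    for chain_len in itertools.count():
        for terminal in TERMINAL_GROUPS:
            frag = "C" * chain_len + terminal
            seen.setdefault(frag, None)
            if len(seen) >= count:
                return list(seen)[:count]
    raise AssertionError("unreachable")


def scaffold_pool(family: str) -> list[str]:
    """All scaffolds (template × decoration) of a template family."""
    templates = {"A": TEMPLATES_A, "B": TEMPLATES_B}[family]
    return [t.replace("{D}", d) for t in templates for d in DECORATIONS]


def _draw_scaffolds(rng: np.random.Generator, family: str, n: int,
                    exclude: set[str] = frozenset()) -> list[str]:
    pool = [s for s in scaffold_pool(family) if s not in exclude]
    if n > len(pool):
        raise ValueError(
            f"requested {n} scaffolds but family {family} offers {len(pool)}"
        )
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def _latent_weights(rng: np.random.Generator, n_bits: int) -> np.ndarray:
    w = np.zeros(n_bits)
    mask = rng.random(n_bits) < WEIGHT_DENSITY
    w[mask] = rng.normal(0.0, WEIGHT_SD, size=int(mask.sum()))
    return w


def _build_records(
    scaffolds: Sequence[str],
    bases: Sequence[float],
    spec: GeneratorSpec,
    rng: np.random.Generator,
    receptor: str,
    id_prefix: str,
) -> ActivityDataset:
    subs = substituent_list(spec.substituents_per_scaffold)
    smiles = [
        scaff.replace("{R}", sub) for scaff in scaffolds for sub in subs
    ]
    base_per_cmpd = np.repeat(np.asarray(bases, dtype=float), len(subs))
    X = fingerprint_matrix(smiles, n_bits=spec.n_bits)
    w = _latent_weights(rng, spec.n_bits)
    noise = rng.normal(0.0, spec.noise_sd, size=len(smiles))
    pchembl = np.clip(base_per_cmpd + X @ w + noise, *PCHEMBL_CLIP)
    inactive = rng.random(len(smiles)) < spec.inactive_fraction
    pchembl[inactive] = 0.0

    records = [
        CompoundRecord(
            compound_id=f"{id_prefix}{i:05d}",
            smiles=smi,
            pchembl=float(p),
            activity_class=assign_activity_class(float(p)),
            receptor=receptor,
        )
        for i, (smi, p) in enumerate(zip(smiles, pchembl))
    ]
    return ActivityDataset(
        receptor=receptor,
        records=records,
        provenance=f"synthetic(seed={spec.seed})",
    )


def generate_receptor_library(
    spec: GeneratorSpec, receptor: str = "SYN1", family: str = "A"
) -> ActivityDataset:
    """One receptor's activity dataset: n_scaffolds × substituents_per_scaffold
    congeneric compounds with latent-model pChEMBL labels. Reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    scaffolds = _draw_scaffolds(rng, family, spec.n_scaffolds)
    bases = rng.uniform(*BASE_RANGE, size=spec.n_scaffolds)
    return _build_records(scaffolds, bases, spec, rng, receptor, f"{receptor}-")


def generate_subtype_pair(
    spec: GeneratorSpec, receptors: tuple[str, str] = ("SYNA", "SYNB")
) -> tuple[ActivityDataset, ActivityDataset]:
    """Two receptor-subtype datasets sharing ``round(overlap·n_scaffolds)``
    scaffolds.

    Shared scaffolds come from family A and keep their base effect in both
    datasets up to a selectivity jitter; the remaining scaffolds are drawn
    from family A for the first receptor and from the chemically distinct
    family B for the second, so cross-set similarity falls with decreasing
    overlap. Each dataset has independent latent bit weights and noise.
    """
    rng = np.random.default_rng(spec.seed)
    n_shared = int(round(spec.overlap * spec.n_scaffolds))
    n_unique = spec.n_scaffolds - n_shared

    shared = _draw_scaffolds(rng, "A", n_shared)
    unique_a = _draw_scaffolds(rng, "A", n_unique, exclude=set(shared))
    unique_b = _draw_scaffolds(rng, "B", n_unique)

    shared_bases = rng.uniform(*BASE_RANGE, size=n_shared)
    bases_a = np.concatenate(
        [shared_bases + rng.normal(0.0, SELECTIVITY_SD, n_shared),
         rng.uniform(*BASE_RANGE, size=n_unique)]
    )
    bases_b = np.concatenate(
        [shared_bases + rng.normal(0.0, SELECTIVITY_SD, n_shared),
         rng.uniform(*BASE_RANGE, size=n_unique)]
    )
    ds_a = _build_records(
        list(shared) + unique_a, bases_a, spec, rng, receptors[0],
        f"{receptors[0]}-",
    )
    ds_b = _build_records(
        list(shared) + unique_b, bases_b, spec, rng, receptors[1],
        f"{receptors[1]}-",
    )
    return ds_a, ds_b


def generate_screening_library(
    n_compounds: int, seed: int = 0, family: str = "B"
) -> list[tuple[str, str]]:
    """An unlabeled (id, SMILES) screening library from the template grammar."""
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    rng = np.random.default_rng(seed)
    pool = scaffold_pool(family)
    # oversample substituents so libraries can exceed the scaffold pool size
    subs = substituent_list(max(n_compounds // len(pool) + 1, 8))
    combos = [(s, r) for s in pool for r in subs]
    idx = rng.choice(len(combos), size=min(n_compounds, len(combos)), replace=False)
    return [
        (f"LIB{j:05d}", combos[i][0].replace("{R}", combos[i][1]))
        for j, i in enumerate(sorted(idx))
    ]


def generate_dock_scores(
    ids: Sequence[str],
    seed: int = 0,
    mean: float = -8.0,
    sd: float = 1.5,
    n_poses: int = 10,
) -> list[DockScore]:
    """Toy docking results: Gaussian affinities (kcal/mol), n_poses per compound."""
    if len(ids) == 0:
        raise ValueError("ids must be non-empty")
    rng = np.random.default_rng(seed)
    scores = []
    for cid in ids:
        affinities = mean + sd * rng.standard_normal(n_poses)
        for pose, aff in enumerate(np.sort(affinities), start=1):
            scores.append(
                DockScore(
                    compound_id=str(cid),
                    affinity=float(aff),
                    pose_index=pose,
                    source="synthetic",
                )
            )
    return scores
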