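# Methods

## Activity labels and binning

Bioactivity is encoded as pChEMBL (−log₁₀ of molar IC50/Ki-type activity);
0 is reserved as the sentinel for compounds annotated inactive. The seven
ordinal classes use left-closed/right-open intervals — [0,4)→1, [4,5)→2, …,
[8,9)→6, [9,∞)→7. Published descriptions of such schemes often write the
bin labels with overlapping endpoints ("4–5", "5–6"); the half-open
convention resolves the boundary deterministically and keeps the map
monotone and total. Negative inputs are rejected rather than clamped.
Activity-range strings use ASCII hyphens ("4-5", "9-above") so CSV output
stays encoding-agnostic.

Curation canonicalizes SMILES with RDKit, drops unparseable structures,
removes rows with no pChEMBL value, and collapses duplicate compound ids by
keeping the first occurrence — order-stable and idempotent. Splitting is a
plain uniform random 80/20 partition (train count = round(0.8·N)) from a
single explicit seed; a stratified-by-class variant exists behind a flag
and is off by default because the reference protocol specifies plain random
selection.

## Fingerprints and similarity

ECFP4 = Morgan radius 2 (bond diameter 4), folded to 2048 bits by default
(the width is configurable and recorded in model metadata; it is a
convention choice, not a tuned value). Tanimoto similarity is |a∩b|/|a∪b|,
defined as 0 for two empty vectors to avoid 0/0. Cross-set diagnostics
report the average and the mode over all |A|×|B| pairs; the mode is taken
after rounding to a 0.01 grid (count ties resolve to the lower bin) because
such modes are conventionally reported at two decimals. An alternative
per-compound-maximum reading (each A-member's best match in B) is
implemented behind `method="max"`; all-pairs is the default as the simpler,
symmetric statistic.

## The classifier

A sequential dense network: input 2048 → hidden 512 → 128 (ReLU) → softmax
over 7 classes, categorical cross-entropy loss, minibatch Adam
(lr 1e-3, β₁ 0.9, β₂ 0.999, batch 32). Hidden topology, batch size and
learning rate are configurable; the defaults are ordinary choices for
fingerprint-width inputs, not the result of a search (hyperparameter search
is out of scope). Epoch defaults: 1000 for a full fit — loss and accuracy
typically stabilize well before that (~200 epochs) — and 100 inside the
repeated-run averaging protocol.

The implementation is pure NumPy. That keeps initialization (seeded
He-uniform), epoch shuffling and the Adam update in one transparent place
and makes single-threaded runs bit-reproducible: build + train with one
seed yields identical weights and history every time. scikit-learn's MLP
serves as an independent cross-check in the test suite, never as the
implementation. Reported loss is the mean per-sample cross-entropy (a
per-set sum is the other defensible convention; the mean is documented here
and used everywhere, giving the closed-form value ln 7 ≈ 1.9459 for a
uniform predictor). Accuracy is top-1 agreement with argmax ties broken
toward the lower class index — the conservative activity call. Inputs are
fingerprint bits only; the pChEMBL value and its class are labels, never
features (feeding the class in would be target leakage).

## Selectivity cross-evaluation

For receptors r₁…r_m with fixed train/validation splits, a model (or an
ensemble of `n_runs` models with seeds base_seed+i, metrics arithmetically
averaged) is trained per receptor and evaluated on every validation set,
giving an m×m matrix of loss/accuracy cells. Each cell also carries the
all-pairs average and mode Tanimoto between the training set and that
validation set. Accuracy change is other-minus-matched, with the matched
reference taken from the same ensemble (avoids seed asymmetry), so diagonal
cells are exactly 0. The accuracy–similarity association uses Spearman rank
correlation: accuracy is bounded in [0,1] and no linearity is claimed, so
ranks are the robust choice.

The packaged benchmark (`selectivity_benchmark`) runs receptor-subtype
pairs at scaffold overlaps {0, 0.25, 0.5, 0.75, 1.0} for seeds
(101, 202, 303), with 12 scaffolds × 50 substituents (600 compounds per
receptor), 1024-bit fingerprints, hidden layers (256, 64), 100 epochs and a
single run per cell. These sizes are the package's single-CPU benchmark
scale: large enough for the matched-vs-mismatched gap (~0.1–0.25 at zero
overlap) and the positive accuracy–similarity correlation to be stable per
seed, small enough to run in a few minutes.

## Screening and percent ranks

The statistic behind "in X% of top predictions" is defined here as
100·rank/N with rank 1 best, ranking by the expected class ordinal
Σₖ pₖ·k (equal to k for a one-hot prediction of class k). Ties are broken
by the probability of the highest class and then by library order, so
percent ranks over a library are always a permutation of {100·i/N}. The
within-range percent rank repeats the computation among the compounds
sharing the target's predicted class. The expected-class ordinal is one
defensible reading of an underspecified convention (top-class probability
and raw argmax are alternatives); it is smooth, respects class order, and
is documented as the package's definition.

## Docking consensus

Vina PDBQT output is parsed for `REMARK VINA RESULT` lines (pose index from
MODEL numbering, compound id from the file stem); delimited tables with
id/affinity columns are accepted equivalently. The energy cutoff defaults
to −10.5 kcal/mol and is inclusive — a pose exactly at the cutoff passes.
Per-compound summarization is the minimum (best) affinity over poses. A
count-based top-N selection is available alongside the cutoff. Consensus
hits are the intersection, by whitespace-normalized compound id, of the
classifier's class-≥7 selection with the docking survivors, ordered by
ranking score descending then best affinity ascending. No structure-based
identity resolution is attempted.

## Synthetic data

The generator emulates the *shape* of curated ChEMBL exports, not their
pharmacology. SMILES are built by text substitution on vetted ring-system
templates: each scaffold is a template (two families — (hetero)aromatic A
and aliphatic B) carrying a fixed decoration, substituted at one marked
point with fragments from a deterministic alkyl-linker × terminal-group
grammar. Validity is guaranteed by construction and re-verified in tests.

Activity: pChEMBL = clip(base(scaffold) + w·bits + ε, 0, 11) with scaffold
bases Uniform(3.5, 9.5), sparse latent weights (5% of bits, N(0, 0.15²)),
and ε ~ N(0, noise_sd). Defaults: noise_sd 0.4 pChEMBL units and an
inactive fraction of 0.25 — set to the sentinel 0 irrespective of structure,
in line with the 25–40% inactive fractions seen in curated receptor sets.
A `SEPARABLE` preset (inactive fraction 0, noise_sd 0.2) defines the
label-recovery benchmark, where class labels are recoverable from structure
up to mild noise. Subtype pairs share round(overlap·n_scaffolds) scaffolds;
shared scaffolds keep their base effect across the pair up to a selectivity
jitter (SD 0.5), unshared scaffolds come from the two distinct families.
This makes cross-set Tanimoto and label transferability both increase with
overlap — the mechanism behind the benchmark's accuracy–similarity
correlation.

What passing tests on this substrate shows: the pipeline's contracts
(binning, splitting, ranking, intersection), the classifier's ability to
recover structure-determined labels, and the qualitative selectivity
pattern. What it does not show: performance on real congeneric series with
activity cliffs, assay noise structure, scaffold diversity beyond the
template grammar, or any absolute accuracy transferable to real receptors.

## Numerical and degenerate-input choices

Empty↔empty Tanimoto = 0; empty training/validation sets are errors;
unparseable SMILES are skipped with logged counts during screening but
fatal in featurization of curated data; epochs ≥ 1 enforced; argmax ties →
lower class; all randomness flows through explicit integer seeds
(`default_rng`), and repeated single-threaded runs are byte-identical.
Multi-threaded BLAS can break bit-identity of training; metrics then agree
to ~1e-3, which is why reproducibility guarantees are stated for
single-threaded mode.

## Known limitations

Binary folded fingerprints only (no count vectors, no other families); no
pIC50→pChEMBL standardization (inputs are assumed already standardized); no
assay-type arbitration; no live ChEMBL access; docking and MD engines are
never executed, only their score outputs consumed. The command-line layer
is a thin convenience over the library and adds no functionality of its
own.
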