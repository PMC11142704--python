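# Methods

## Model

The core model treats a protein–molecule pair as one token sequence. Inputs
are *frozen* per-token embeddings from upstream language models (or the
synthetic provider): proteins as a matrix of per-token vectors of width
`d_p`, molecules as SMILES-token vectors of width `d_s`. Two single-layer
ReLU pooling networks map each modality into the shared hidden width `H`;
their parameters train with the rest of the model. The assembled sequence is
`[cls] + protein + [sep] + molecule`, with the `cls` input row fixed to all
ones and `sep` to all zeros in the hidden space. A post-norm BERT-style
encoder (multi-head self-attention, GELU feed-forward of width `4H`,
residual connections and LayerNorm) updates all rows; the final `cls` row
feeds a one-hidden-layer head (width 32, ReLU; identity output for
regression, sigmoid for binary classification).

Full-size constants: `H` = 768 = 6 heads × 128, 6 layers, learning rate
1e-5 (1.5e-5 with batch 192 for large-corpus warm-starting), batch 12 (24
for the larger enzyme–substrate task), 100 epochs with parameters
snapshotted per epoch and the best-validation-loss epoch selected.
Sequences are truncated to the first 1024 protein tokens and the first 256
SMILES tokens.

Downstream, three XGBoost models are trained on (i) the `cls` vector, (ii)
the concatenation of mean-pooled protein and molecule embeddings, and (iii)
all three blocks concatenated in the fixed order cls | protein | molecule.
Hyperparameters (learning rate, depth, L1/L2 regularisation, max delta
step, min child weight, boosting rounds, and a negative-class weight for
imbalanced classification) are tuned by pure independent random sampling —
2 000 iterations at full scale — selecting on validation MSE (regression)
or MCC (classification). Ensemble weights are chosen by exhaustive search
on the simplex grid of step 0.05 (231 candidates; ties keep the earliest
point in lexicographic order). Finalists are retrained on train +
validation with the selected hyperparameters; weights carry over unchanged.

## Implementation of the encoder

The transformer is written directly on NumPy (float32 by default) with
hand-derived backpropagation for every block, verified against central
finite differences in float64 to relative error < 1e-5 in the test suite.
Numerical choices:

- GELU uses the tanh approximation `0.5x(1 + tanh(√(2/π)(x + 0.044715x³)))`
  with the tanh cached so the backward pass needs no transcendentals.
- Padding uses an additive attention mask (−1e9 on padded key positions →
  exactly zero attention weight after softmax); a batched-vs-unbatched
  oracle test pins masking correctness, and masked rows change predictions
  by < 1e-5.
- The optimiser is Adam (β = 0.9/0.999) with global gradient-norm clipping
  at 1.0; the source papers name only the learning rate, so the optimiser
  family and clipping are package choices.
- No dropout or weight decay (values unpublished; both default off).
- No positional embeddings by default: upstream token embeddings are
  contextual. A sinusoidal-position flag exists for ablation.
- Epoch selection uses validation loss; the selection criterion is
  configurable.

For datasets whose token matrices exceed memory, entities are chunked
(default 1000 per chunk, matching the batch-processing scheme of the
original training setup) into a single-file HDF5 store; each epoch iterates
over all (protein-chunk × molecule-chunk) blocks so that every training pair
is visited exactly once per epoch with at most one chunk per modality
resident.

## Scaled-down configuration

`JointEncoderConfig.scaled_down()` is the desk-scale profile used by the
tests and the acceptance script: 2 layers, hidden 64 (2 heads × 32),
30 epochs, batch 24, Adam learning rate 1e-3. The raised learning rate is
deliberate: 1e-5 is calibrated to 100-epoch runs on tens of thousands of
pairs with a 110M-parameter model and leaves a ~100k-parameter model badly
underfit after 30 epochs on 1200 pairs. The scaled GBM search space caps
tree depth at 8 and boosting rounds at 300, and XGBoost uses `hist` with 64
histogram bins — ample resolution for ~10³ training rows. Pipeline problem
sizes (1500 pairs, 100 proteins × 60 molecules, 50 random-search trials)
were chosen as the smallest sizes at which the planted signal is reliably
recoverable.

## Synthetic data and embeddings

The generator plants a bilinear interaction: M = 6 factors pair an
amino-acid 3-mer motif with a SMILES fragment token, with fixed signed
weights (1.0, 0.8, −0.6, 0.7, −0.9, 0.5). The latent score of a pair is
`effect_size · Σ_m w_m · f_m · g_m` where `f_m` counts motif occurrences
(0–3 copies planted per protein at non-overlapping positions; counts are
re-measured on the final sequence so collisions cannot desynchronise labels)
and `g_m` indicates fragment presence in the tokenized SMILES. Proteins are
uniform random sequences of length 40–80; molecules are drawn from a bundled
list of 200 rdkit-valid structures spanning the fragment vocabulary.
Regression labels add Gaussian noise (σ = 0.3, ≈ 19% of the label standard
deviation, putting the noise ceiling near R² ≈ 0.95); classification labels
threshold the score at the quantile matching the requested positive
fraction (default 0.25, the 1:3 positive-to-negative ratio of public
enzyme–substrate benchmarks), with infinitesimal jitter to break atoms in
the score distribution.

The synthetic embedding provider gives every (modality, token, seed) a fixed
unit-variance pseudo-random vector, plus a small indicator block (scale 4.0)
flagging the signal tokens, so planted signals remain linearly decodable
after mean pooling. Proteins are tokenized as overlapping 3-mers — a
deliberate departure from per-residue tokenization of real protein language
models: provider embeddings may depend only on the token string, so 3-mer
motif content is representable at the token level at all. This is recorded
in the provider metadata. Upstream begin/end special tokens are excluded
from all per-token matrices.

What passing tests on this generator do **not** show: real affinity
distributions, sequence-family structure, chemistry beyond small
heteroatom-substituted scaffolds, or the information content of real
language-model embeddings. The synthetic results demonstrate that the
pipeline's machinery (joint attention, representation extraction, ensemble
selection, splits, metrics) is correct and can recover a known signal — not
that it matches published benchmark numbers, which require GPU-scale
training on external datasets.

## Metrics

- Concordance index: fraction of label-comparable pairs ordered correctly;
  prediction ties credit ½, label ties are excluded (the standard
  convention in affinity-prediction benchmarking).
- rm² = r²·(1 − √(r² − r₀²)) with r² the squared Pearson correlation (fit
  with intercept) and r₀² the coefficient of determination of the
  through-origin fit of observed on predicted (slope k = Σyŷ / Σŷ²). The
  radical form follows the QSAR validation literature that downstream
  benchmarks use; a non-radical variant is available behind a flag. A
  negative radicand (possible only through rounding) is clipped at 0.
- R² is 1 − SSres/SStot, distinct from squared Pearson.
- MCC comes from the 2×2 confusion table at threshold 0.5 and is reported
  as undefined when the table degenerates; the convenience panel degrades
  to accuracy-only in that case.
- All metric implementations are pinned to independent brute-force oracles
  (O(n²) enumeration, first-principles least squares, confusion-table
  arithmetic) at 1e-10 relative tolerance.

## Splits

Cold splits partition *entities* first (proteins, molecules, or both) and
then assign records, so record-level fractions approximate 80/10/10 as the
entity partition allows; the three entity groups are mutually disjoint. In
cold-both, records whose protein and molecule land in different groups are
discarded (and counted in the manifest) — a record with a training protein
and a test molecule belongs in neither part. Occurrence-controlled splits
give each of 15 selected molecules exactly k training records with distinct
proteins (k ∈ {1, 3, 10, 30, 100}) and route all remaining records of the
selected molecules to the test set; records of non-selected molecules are
split randomly. Stratified reports use left-closed right-open bins.

## Similarity

Molecule similarity is 1 − Jaccard distance over 1024-bit radius-2 ECFPs
(already in [0, 1]; an optional min–max rescaling flag exists). Protein
identity is matches / alignment-length under global alignment with match
+1, mismatch 0, gap −1 — a deterministic, dependency-light scoring scheme
chosen by this package; published pipelines rarely name their identity
tool, so absolute identities may differ slightly from other software.

## Known limitations

- The encoder is CPU-bound NumPy: fine for desk-scale studies (seconds per
  epoch at hidden 64), not for the full-size architecture on 10⁵–10⁶ pairs.
- Adapters for real protein/chemical language models are out of scope of
  the test suite; only the provider contract is exercised.
- Replicate-measurement handling (averaging vs keeping duplicates) is left
  to the user; duplicates load with a warning and the pair-excluded split
  keeps them from straddling train/test.
- Classification probabilities are raw sigmoid/ensemble outputs; no
  calibration is performed.
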