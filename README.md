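# protmol

Machine-learning toolkit for predicting protein–small-molecule interactions
— drug–target binding affinities (pKd), enzyme–substrate pairs, Michaelis
constants — from a protein amino-acid sequence and a molecule SMILES string.

## The method

Most interaction predictors encode the protein and the molecule separately
and only combine the two vectors at the output layer, which limits how much
the two representations can inform each other. Here the two modalities are
processed **jointly**: per-token embeddings from pre-trained protein and
chemical language models (per-residue vectors of width *d_p* = 1280, SMILES
token vectors of width *d_s* = 600) are mapped by ReLU pooling layers into a
shared hidden space (*H* = 768) and concatenated into a single attention
sequence

```
[cls]  t_1 … t_Lp  [sep]  s_1 … s_Ls
```

where the `cls` input row is all ones and the `sep` row all zeros. A
BERT-style transformer (6 layers × 6 heads × head dimension 128, GELU
feed-forward blocks) updates every token with full cross-modal attention;
the updated `cls` vector is the learned joint representation, and a small
head (one hidden layer of 32, ReLU; linear output for regression, sigmoid
for classification) trains the whole stack end to end (MSE or binary
cross-entropy, Adam at learning rate 1e-5, 100 epochs with per-epoch
snapshots and best-validation selection).

The final predictor is not the transformer head but a **weighted ensemble of
three gradient-boosting models** (XGBoost) over three feature views per
record: the `cls` vector (768), the concatenated mean-pooled protein and
molecule embeddings (1280 + 600 = 1880), and all three blocks (2648).
Hyperparameters are tuned per model by pure random search (2 000 iterations
at full scale) on a validation set; the ensemble weights (w₁, w₂, w₃),
wᵢ ≥ 0, Σwᵢ = 1, are selected on a simplex grid of step 0.05; finalists are
retrained on train + validation.

Evaluation machinery includes the concordance index (CI, ties credited ½),
the QSAR metric rm² = r²·(1 − √(r² − r₀²)), MSE/R², MCC/ROC-AUC, cold
train/test splits (cold target, cold drug, cold both, pair-excluded),
occurrence-frequency-controlled splits, ECFP/Jaccard molecule similarity and
global-alignment protein sequence identity for stratified reporting.

The transformer is implemented directly on NumPy with hand-written
backpropagation (finite-difference checked in the test suite); no deep
learning framework is required. Real language-model embeddings plug in
behind the `EmbeddingProvider` contract; a built-in deterministic synthetic
provider plus a synthetic-data generator with a planted, recoverable
protein × molecule signal make the entire pipeline testable offline.

## Worked example

```python
from protmol import (
    JointEncoderConfig, MultimodalInteractionPredictor, SyntheticConfig,
    SplitSpec, generate_dataset, make_split, evaluate,
)
from protmol.pipeline import default_provider

cfg = SyntheticConfig(seed=1)           # 1500 pairs, planted bilinear signal
data, truth = generate_dataset(cfg)
provider = default_provider(cfg)        # deterministic synthetic embeddings
split = make_split(data, SplitSpec(scenario="random", n_repeats=1, seed=1))[0]
train, val, test = (data.subset(split.train), data.subset(split.val),
                    data.subset(split.test))

model = MultimodalInteractionPredictor(
    encoder_config=JointEncoderConfig.scaled_down(seed=1), gbm_n_iter=50, seed=1,
).fit(train, provider, val)
pred = model.predict(test, provider)
print(evaluate(test.labels, pred, "regression").to_dict())
```

Output (seed 1):

```
{'mse': 0.172468132162083, 'r_squared': 0.9388265147882376,
 'pearson_r': 0.9725145570168253, 'concordance_index': 0.9265324384787472,
 'rm_squared': 0.8734949554447281, 'rm_r2': 0.945784563609632,
 'rm_r0_2': 0.9399424863183522}
```

The planted signal explains ~95% of the label variance at the default noise
level; the pipeline recovers an R² of 0.94 on held-out pairs (MSE 0.17
against a label variance of ~2.6), while a boosted model on either single
modality alone reaches at most ~0.45 — the joint model has learned the
protein × molecule interaction, not just marginal effects.

A command-line interface mirrors the workflow
(`protmol simulate | split | embed | run`); `protmol run --config cfg.yaml`
executes the whole pipeline from a YAML config and prints per-repeat metrics
with mean/SD aggregation.

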