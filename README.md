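# kinemoe

Multitask mixture-of-experts prediction of enzyme kinetic parameters —
turnover number (kcat, s⁻¹) and Michaelis constant (Km, mM) — from enzyme
sequence, substrate SMILES and assay conditions (pH, temperature,
organism), together with the full data-curation, splitting and evaluation
pipeline around the model and a seeded synthetic-data generator that makes
every stage runnable and testable offline.

It is aimed at computational enzymologists and enzyme engineers who want
to rank enzymes or variants by catalytic efficiency
(kcat/Km, compared as log10 kcat − log10 Km) and at methods developers who
need a transparent, dependency-light reference implementation of gated
multitask regression on kinetic data.

## The model

Both parameters are predicted simultaneously from one fused feature vector
`x = [enzyme ‖ substrate ‖ auxiliary]`. The core is a customized-gate-
control (CGC) architecture: task k owns m_k specific expert networks and
shares m_s experts with the other task, a per-task softmax gate

    w^k(x) = Softmax(W_g^k x)
    g^k(x) = w^k(x) S^k(x)

weights the stacked expert outputs S^k(x) (specific experts first, then
shared), and a per-task tower maps g^k(x) to the scalar log10 prediction.
Gating lets each task draw on shared information exactly as much as helps
it, mitigating the negative transfer that fully shared backbones suffer on
loosely coupled tasks. Training minimizes a masked L2 loss, so entries
carrying only one of the two labels still contribute to their task.
pH and temperature are encoded by Gaussian radial basis functions
(`exp(-γ(x-μ_m)²)`, γ = 10, centers at stride 0.1 over the training span);
organisms by a trainable embedding table. The network and its
backpropagation are pure NumPy; gradients are verified against finite
differences in the test suite.

Enzyme and substrate embedders are a pluggable contract. The shipped
defaults are deterministic hash embedders (offline, reproducible, no
biochemical content); adapters for pretrained protein / molecule language
models can be dropped in behind the same interface.

## Worked example

```python
from kinemoe import (SynthSpec, gen_dataset, curate_pipeline, accounting,
                     SplitSpec, stratified_split, fit_aux_spec,
                     featurize_entries, CGCConfig, train, predict_entries,
                     metric_report, HashEmbedder)
from kinemoe.synthetic import noise_sd_for_bayes_r2

spec = SynthSpec(n_entries=1000, seed=7, shared_signal_fraction=0.9,
                 noise_sd=noise_sd_for_bayes_r2(0.9, 0.8))
records, truth = gen_dataset(spec)          # raw rows, database schema
entries, report = curate_pipeline(records)  # clean, normalize, aggregate
acc = accounting(entries)

train_e, val_e, test_e = stratified_split(entries, SplitSpec(seed=7))
enz = HashEmbedder("hash-enzyme", spec.enzyme_dim, salt=1)
sub = HashEmbedder("hash-substrate", spec.substrate_dim, salt=2)
aux = fit_aux_spec(train_e, aux_dim=spec.aux_dim)
ftr, fva, fte = (featurize_entries(s, enz, sub, aux)
                 for s in (train_e, val_e, test_e))

cfg = CGCConfig(input_dim=ftr.input_dim, n_shared_experts=2,
                n_specific_experts=2, expert_dim=64, tower_dims=(32, 1),
                batch_size=32, epochs=30, learning_rate=3e-3,
                expert_dropout=0.1, seed=7)
model, history = train(ftr, fva, cfg)
```

Output of the run above:

```
curated 1463 records -> 1000 entries (463 both, 150 kcat-only, 387 Km-only)
best epoch 6, validation loss 0.266
kcat: n=61 PCC=0.817 R2=0.655 RMSE=0.566 p=1.02e-15
km:   n=85 PCC=0.811 R2=0.630 RMSE=0.591 p=5.50e-21
```

The 1463 raw rows collapse to 1000 joint entries because entries with both
labels arrive as two rows (and the generator's label-pattern mix is about
50/13/37). The synthetic labels were drawn with a Bayes-optimal R² of 0.8
(shared-signal fraction ρ = 0.9), so held-out R² around 0.63–0.66 means the
model recovered most of the learnable signal; the p-values are two-sided
t-tests on the Pearson correlation. `predict_entries(model, fte)` returns
per-entry predicted log10 kcat, log10 Km, their linear-scale values and the
efficiency `log10 kcat − log10 Km` used to rank variants:

```
   pred_log10_kcat  pred_log10_km  pred_log10_efficiency
0            1.537         -0.664                  2.201
1           -0.015         -1.603                  1.588
2            0.662         -1.297                  1.959
```

## Command line

The same stages are exposed as subcommands — `simulate`, `curate`,
`featurize`, `split`, `train`, `predict`, `evaluate`, `casestudy` and
`pipeline` (all stages end to end):

```bash
kinemoe pipeline --out-dir runs/demo --config config.yaml --seed 5
kinemoe casestudy variants.csv          # hit ratio of a reference-flagged CSV
```

Configs are YAML or JSON; unknown keys are rejected with their location
before anything runs, and every artifact carries a sidecar with the seed
and config hash. Raw-record CSV columns and the curated-entry schema are
documented in `kinemoe.io`; sequences may come from a FASTA file keyed by
the `record_id` column.

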