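# Methods

## Problem and model

Enzyme turnover number (kcat, s⁻¹) and Michaelis constant (Km, mM) are the
two standard kinetic parameters of an enzymatic reaction. They are
intrinsically related — both reflect how an enzyme engages a substrate — so
`kinemoe` treats their prediction as a two-task regression problem on the
log10 scale and couples the tasks through a customized-gate-control (CGC)
mixture-of-experts architecture rather than through fully shared weights,
which is known to cause negative transfer ("seesaw") between loosely
related tasks.

Each entry is described by a fused vector
`x = [enzyme ‖ substrate ‖ auxiliary]`. Task k owns `m_k` specific expert
networks and shares `m_s` experts with the other task; each expert is an
affine map with ReLU (one layer by default) and dropout on its output. A
per-task gate

    w^k(x) = Softmax(W_g^k x),  W_g^k ∈ R^{(m_k+m_s)×d}

weights the stacked expert outputs `S^k(x)` (rows ordered specific-first,
shared-last), and the fused representation `g^k(x) = w^k(x) S^k(x)` feeds a
per-task tower (affine stack, ReLU between hidden layers) ending in one
scalar. The output activation is the identity: log10 Km is frequently
negative, so any clamp at zero would be wrong on its face. Setting
`n_cgc_layers > 1` switches to the stacked (progressive-layered-extraction
style) variant, where intermediate layers also expose a gated shared output
feeding the next layer; the default stays at one layer, which is also the
better-performing configuration for this problem class.

Training minimizes a masked mean-squared error over the observed labels:
an entry carrying only one of the two labels contributes only to that
task's residual, and the loss normalizes by the total count of observed
labels. Optimization is Adam. The network, including backpropagation, is
implemented directly in NumPy with a flat parameter dictionary; gradients
are verified against central finite differences in the test suite (both the
single-layer and stacked variants, and the trainable auxiliary encoder).

## Features

* **Enzyme / substrate embedders** are a pluggable contract (deterministic
  `text → R^dim`). The shipped default is a hash embedder: a stable hash of
  (salt, text) seeds a pseudo-random map to an L2-normalized vector.  It
  carries no biochemical information; its role is to give every distinct
  sequence or SMILES a reproducible, well-separated representation so the
  pipeline and the learning machinery can be exercised and tested offline.
  Adapters for pretrained protein/molecule language models (1024-d and
  300-d conventions respectively) can be plugged in behind the same
  contract.
* **pH and temperature** are expanded over a grid of Gaussian radial basis
  functions, `e_m(x) = exp(-γ‖x-μ_m‖²)` with γ = 10 and centers from the
  training minimum to maximum at stride 0.1, then mapped linearly (no bias)
  to the auxiliary dimension. Values outside the training span fall on the
  Gaussian tails and are never an error.
* **Organism** is a one-hot lookup into a trainable embedding table with a
  reserved row for unknown organisms.
* The three auxiliary projections are summed; a missing covariate
  contributes the zero vector (which is why the linear maps carry no bias).
  The RBF projections and the organism table are trained jointly with the
  rest of the model; fixed random projections would also be defensible, but
  joint training is the natural reading of an "embedding" and costs
  nothing here.

Default dimensions are 1024 (enzyme) + 300 (substrate) + 300 (auxiliary)
= 1624. Tests and the worked examples use reduced dimensions
(32 + 16 + 16); the architecture is unchanged.

## Curation pipeline

Raw records (one kinetic value per row, the schema of the standard kinetic
databases) pass through, in order: completeness filter → unit
normalization → mutation application → SMILES canonicalization →
structural filter → value filter → duplicate aggregation → log10 →
outer join of the two parameter tables. Details:

* **Units.** Canonical units are s⁻¹ (kcat) and mM (Km), matching the scale
  on which results are reported. The conversion table is closed (s⁻¹,
  min⁻¹, h⁻¹; M, mM, µM, nM) with exact rational factors; an unknown unit
  rejects the record with a reason code rather than guessing. Temperature
  stays in °C (the RBF encoding is shift-invariant up to center placement).
* **Mutations.** Mutant rows arrive as a wild-type sequence plus 1-based
  substitution codes (`A123V`). Only substitutions are supported; a
  reference-residue mismatch or out-of-range position drops the record with
  a logged reason. After application the stored sequence *is* the mutant
  sequence and the codes become provenance.
* **Structure filter.** Substrates must parse, contain no `.` fragment
  separator, and have a heavy-atom count h with 2 < h ≤ 128 (all
  non-hydrogen atoms, after RDKit's implicit-hydrogen normalization).
* **Duplicates.** Byte-identical measurements (same key and value) collapse
  silently; same-key groups with differing values are resolved by keeping
  the maximum kcat and the minimum Km on the linear scale, before the log
  transform. This is the only reading that reconciles "remove all
  duplicates" with an extremum rule, and aggregation never invents a value.
* **Key.** (canonical SMILES, sequence, pH, temperature, organism), with pH
  and temperature participating exactly as given (no rounding).

The pipeline never aborts on a bad record; every drop is logged with a
reason code and the report's stage counts balance exactly against the
input size (checked by an internal invariant). Re-curating curated output
changes nothing.

## Splitting and evaluation

Entries are stratified by label pattern (both / kcat-only / Km-only) and
each stratum is split 8:1:1 (floor + largest-remainder rounding) so the
pattern mix is preserved; strata with fewer than three entries go to
training. Metrics are PCC, R² (1 − SSres/SStot, can be negative) and RMSE
on the log10 scale, computed from their explicit formulas and
cross-checked against scipy/scikit-learn in tests. The PCC p-value uses
the two-sided Student t transform on n−2 degrees of freedom; group
comparisons use a two-sided Wilcoxon rank-sum test with exact enumeration
when the smaller sample has ≤ 8 observations and a tie-corrected normal
approximation otherwise.

Subtest partitions mirror the evaluation protocol: wild-type vs mutant;
promiscuity (among wild-type enzymes with ≥ 2 substrates, the substrate
with the highest kcat or lowest Km is "preferred", the rest "alternative";
extremum ties make all tied substrates preferred); mutant fold-change
categories (linear ratio to the matched wild-type: 0.5–2.0 wild-type-like,
> 2.0 increased, < 0.5 decreased), where the wild-type reference shares
(EC number, organism, substrate) and has the closest (pH, temperature) —
unmatched mutants are excluded; and a strict subset of test entries whose
sequence *and* substrate are both absent from training.

For enzyme mining and directed evolution, the hit ratio HR is the fraction
of variants whose predicted change in catalytic efficiency
(log10 kcat − log10 Km, monotone-equivalent to the linear ratio kcat/Km)
has the same sign as the experimental change relative to a reference
variant; exact ties with the reference are excluded and logged.

## Synthetic data generator

The generator emulates the shape of a curated kinetic corpus, not its
biochemistry:

* label-pattern mix defaults to the curated-corpus proportions (≈ 50.4%
  both, 12.9% kcat-only, 36.6% Km-only);
* sequences are uniform over the 20-letter alphabet (30–60 residues);
  ~30% of entries are mutants emitted as wild sequence + substitution
  codes; substrates are valence-safe linear/branched C/N/O chains (3–20
  heavy atoms); 10 organisms; pH on a 0.1 grid in [5, 9], temperature on a
  0.5 grid in [20, 45] — ranges a bench kineticist would call ordinary;
* values are emitted in randomly chosen equivalent units, and optional
  duplicate groups add decoys (smaller kcat / larger Km) that the
  aggregation rule must discard;
* per-filter violations (missing fields, tiny/huge substrates, dotted
  SMILES, non-positive values, unknown units, inconsistent mutation codes)
  are planted in exact requested counts.

Labels are linear in the fused feature vector: with a shared latent
`u = a·x` and task latents `v_t = b_t·x` (projections standardized across
the dataset), `label_t = center_t + ρ·u + (1−ρ)·v_t + ε_t` with Gaussian
noise. Centers are 0.9 (log10 kcat) and −0.9 (log10 Km), the magnitudes
typical of curated corpora. Because the truth is linear with known noise,
the Bayes-optimal R² is analytic — `s²/(s²+σ²)` with `s² = ρ²+(1−ρ)²` — and
`noise_sd_for_bayes_r2` inverts it. The generator's auxiliary features use
a *fixed* randomly drawn encoder of the same functional form as the model's
trainable one, so the hypothesis class contains the truth.

What passing tests therefore show: the curation rules, bookkeeping,
splitting, metrics and the learning machinery behave correctly, and the
multitask core extracts most of the extractable signal from data with the
stated correlation structure. What they do not show: performance on real
kinetic data, which depends on the pretrained embedders and the real
corpus, neither of which this package ships.

## Training protocol and problem sizes

Learning checks run at n = 2000 entries, ρ = 0.9, noise set for Bayes
R² ≈ 0.8, reduced dimensions (32+16+16 input, 2 specific + 2 shared
experts of width 64, towers 32→1), batch size 32, 30 epochs at learning
rate 3e−3, five independent seeds — sizes chosen so a full run is a
desk-scale exercise while leaving the conclusions qualitative: held-out R²
≥ 0.5 per task and multitask within 0.02 of matched single-task baselines.
The production defaults (batch size 1, 50 epochs, learning rate 1e−4,
4+4 experts of width 768) remain the configured defaults; model selection
always keeps the epoch with the lowest validation loss, earliest on ties.

## Numerical choices and degenerate inputs

* Softmax is computed with max-subtraction; gates therefore never overflow.
* Initialization is symmetric uniform with fan-in scaling (`±1/√fan_in`);
  biases start at zero; a single seeded generator drives initialization,
  shuffling and dropout, so identical seeds give bit-identical histories.
* Dropout is inverted (scaled at train time), disabled at evaluation.
* PCC/R² raise on zero-variance inputs; the masked loss raises on a batch
  with no observed labels; RBF center construction raises on empty inputs.
* |PCC| = 1 maps to p = 0 by convention; a rank-sum test on a fully tied
  pool returns p = 1.
* Unit conversion uses `fractions.Fraction`, so round trips are exact to
  floating-point resolution.

## Known limitations

* The hash embedders carry no homology or chemistry: nearby sequences are
  no closer in feature space than distant ones, so generalization to
  *unseen* sequences is not meaningfully testable offline — only the
  plumbing of the strict-unseen subset is.
* The generative labels are linear; the experts' capacity advantage over a
  linear model is therefore not exercised by the acceptance checks.
* cd-hit-style sequence-identity binning is not reimplemented; a
  precomputed identity column can drive the same style of report.
* Only substitution mutations are supported, matching the curation
  contract.
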