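# Methods

`mfpep` predicts the functional categories of short therapeutic peptides
(5–50 residues, 21 categories by default, any subset per peptide) from
sequence alone. This note describes the model, the loss, the evaluation
metrics, the synthetic data used for testing, and the numerical choices
behind the implementation.

## Model

Eight feature streams are computed per sequence, aligned to a shared
dimension `d`, and fused.

1. **Embedding** — learned 21×d token embedding; token j is the
   alphabetical rank of residue j (A=1 … Y=20), 0 is padding.
2. **Self-attention** — masked multi-head attention over the embeddings
   plus the sinusoidal positional encoding
   `PE(pos, 2i) = sin(pos / 10000^(2i/d))`,
   `PE(pos, 2i+1) = cos(pos / 10000^(2i/d))`.
3–7. **Biological encodings** — per-residue lookups in an AAindex-style
   property table, a 3-column classic physicochemical table
   (hydropathy, hydrophilicity, side-chain mass), a 6-column table adding
   pK1, pK2 and pI, the 23-column BLOSUM62 substitution rows, and the
   sequence-level amino-acid composition tiled across positions. Each is
   column-standardized (BLOSUM62: standardized at encoding time, the
   table itself ships verbatim) and passed through a Gaussian membership
   fuzzifier `f(x) = exp(-(x-c)²/2σ²)` with per-dimension trainable
   center and width (init c=0, σ=1); widths are parameterized as
   `σ = exp(s)` so they stay positive during training.
8. **Graph attention** — the residue chain graph (path graph over valid
   positions, bidirectional neighbor edges) processed by multi-head
   additive graph attention with self-loops; node features are the token
   embeddings.

Each stream has its own affine projection to `d`. Fusion multiplies
stream i elementwise by the logistic gate `σ(g_i)` (one trainable
d-vector per stream, init uniform [-0.1, 0.1] so gates start near the
neutral 0.5) and averages:
`fused = (1/N) Σ_i F_i ⊙ σ(g_i)`.

The fused sequence passes through a masked BiLSTM, parallel 1-D
convolutions of widths {3,5,7} with ReLU and max-pooling over valid
positions, a feed-forward block with residual connection and layer
normalization, and a two-layer classifier with one sigmoid output per
category. A label is assigned when its probability exceeds the threshold
(default 0.5, i.e. the strict sign rule on logits).

Masking: padded positions carry zeros in every stream, receive −∞
attention scores, are skipped by the LSTM state update, and are excluded
from pooling. As a result the predictions are invariant to whatever
values are stored at padded positions (verified to 1e-6 in the tests).

**Default architecture** — d=32, 4 attention heads, LSTM hidden 32 per
direction, 32 channels per convolution, FFN width 128, 2 graph-attention
heads, dropout 0.2. These are CPU-scale defaults: the package runs on a
compact numpy autodiff core (`mfpep.autodiff`), and this size trains on a
few thousand peptides in minutes on one core while keeping the
architecture's shape (the original design explored larger, searched
configurations; that search is out of scope here and all sizes are
plain config fields).

Every module (graph attention, BiLSTM, fuzzifier, gate fusion, CNN, FFN)
and every stream can be ablated from the config. Module ablation removes
the component — gate fusion degrades to a plain unweighted mean of the
aligned streams — while stream ablation feeds zeros in place of the
feature, so ablated runs keep identical shapes and differ only in the
targeted element.

## Marginal focal dice loss

For class c over a batch, with `n_pos`/`n_neg` the training-set counts
and `w = n^(-1/2)`:

* **Class weights** (optional, default on):
  `w_c = M_max · n_c^(-1/2) / max_c' n_c'^(-1/2)` — the rarest class
  receives exactly `M_max`, others proportionally less. With weighting
  off, `w_c = 1`.
* **Margins**: the minority side of the class gets the full margin
  `M_max`; the majority side gets `M_max · w_maj/w_min ≤ M_max`. The
  margin is subtracted from the logit before the sigmoid during
  training; evaluation uses raw logits (a switch exists).
* **Clipped focal probabilities**: `p⁺ = min(p+clip⁺, 1)·p` where
  `p = σ(z - m)` for positives; mirrored with `1-p` for negatives.
* **Dice components**, aggregated per class over the batch:
  `L⁺ = 1 - 2·Σ p⁺ / (Σ (p⁺)^{e⁺} + n⁺ + ε)`, likewise `L⁻`;
  a side with no instances in the batch contributes 0, and ε = 1e-8
  guards empty denominators.
* **Composition and reduction**:
  `L_c = α·L⁺ + (1-α)·L⁻`, weighted by `w_c`, then reduced over classes
  (mean / sum / none).

Defaults: `α = 0.5`, `M_max = 0.5`, exponents `e⁺ = e⁻ = 2`, clips 0.05,
class weights on, mean reduction.

**Sensitivity of α.** α trades the positive-side (recall) component
against the negative-side (precision) component, and the trade is not
symmetric in instances: the dice sums scale with the side sizes, so the
per-instance cost of a false positive is roughly `(1-α)/n_neg` against
`α/n_pos` for a false negative. Lowering α strengthens the precision
pressure but the window is narrow — around α ≤ 0.2 the objective tips
into the all-negative local optimum. With the optimization measures
below, the symmetric α = 0.5 trains reliably and is the default.

**Optimization.** Dice-family losses have a structural hazard that
instance-level losses lack: the gradient on a confidently wrong entry
vanishes (the focal product and the sigmoid derivative both go to zero),
so errors that saturate early freeze permanently. Three standard
measures keep training out of that regime, all defaults and all
switchable: decoupled weight decay (1e-3) to stop logit run-away, a
global gradient-norm clip (5.0), and classifier bias initialization at
the empirical class-prior log-odds, which removes the early flat phase
in which sigmoid outputs drift from 0.5 to the base rates. Adam at
lr 1e-3, batch 64; a cosine schedule is available but off by default
(it slowed the mid-training take-off in our runs). Class statistics
(counts, weights, margins) are computed once from the full training
fold, not per batch.

Reference losses for comparison harnesses: binary cross-entropy, focal
loss (γ = 2), the margin-free unweighted focal-dice configuration
(equivalently MFDL with `M_max = 0` and uniform weights — an exact
identity covered by tests), cross-entropy on margin-adjusted logits
(the label-distribution-aware-margin analogue), and the asymmetric loss
(γ⁺ = 1, γ⁻ = 4, probability shift 0.05).

## Evaluation metrics

For true/predicted label sets `L_i`, `L_i*` over M categories:
precision `mean |L∩L*|/|L*|`, coverage `mean |L∩L*|/|L|`, accuracy
`mean |L∩L*|/|L∪L*|`, absolute true (exact-match rate), absolute false
`mean (|L∪L*|-|L∩L*|)/M`. Zero-denominator terms contribute 0, except
when both sets are empty — exact agreement — which counts 1; this keeps
the invariant `absolute_true ≤ accuracy ≤ min(precision, coverage)`.
The absolute-false sum is averaged over samples, so 0 means perfect and
the value is bounded by 1. F1 and MCC are micro-averaged over all
label-instance pairs; a zero MCC denominator yields 0 by convention.
Per-class AUC uses the concordance (Mann–Whitney) form — the probability
that a random positive outscores a random negative, ties at half — which
equals trapezoidal ROC integration and makes tie handling explicit;
single-class columns are reported as undefined (NaN), not errors.

## Synthetic data

The generator ties each class to a distinct random motif (default 4
residues, none a substring of another) and defines labels by motif
containment over an i.i.d.-uniform background, so ground truth is exact
and learnable. Per-class prevalences are hit by exact-count insertion
(`round(prevalence·n)` records per class); a donor-swap repair pass then
moves one motif from multi-label records to unlabeled ones, which (i)
eliminates unlabeled records whenever total label slots ≥ n and (ii)
pins the multi-label fraction near the requested rate, because the
default prevalence ladder (geometric, ~20:1 span) is normalized to sum
to `1 + multi_label_rate`. When user prevalences sum below 1 (as in the
50:1 imbalance study) the remaining unlabeled records are emitted as
valid all-negative examples. Optional label noise flips each
(record, class) membership independently after containment.

What it does **not** emulate: homology between records, compositional
biases of real peptide families, length–function correlations, or
annotation sparsity (real "negative" labels are often merely
unmeasured). Passing the recovery study therefore shows the pipeline
can extract deterministic sequence signals under the stated imbalance
structure — not that it attains any particular accuracy on curated
benchmarks.

## Studies sized for one CPU core

* **Label recovery** (`mfpep.studies.label_recovery_study`): 2000
  records, 8 balanced classes (common prevalence 1.15/8), 80/20 split,
  default model and loss, at most 20 epochs with early stopping once
  held-out absolute-true ≥ 0.6 and micro-F1 ≥ 0.8; median over 3 seeds.
* **Imbalance benefit** (`mfpep.studies.imbalance_study`): 3000 records,
  two classes at prevalences (0.5, 0.01) — 50:1, about 30 minority
  positives — lengths 5–30 (model sized to match), 12 epochs at batch
  size 256, identical models under MFDL and BCE; the compared quantity
  is held-out minority-class coverage (recall), median over 3 seeds.
  The large batches matter: with ~1 minority positive per 64-record
  batch the minority dice component would be undefined in most steps.

## Known limitations

* The numpy autodiff core is single-threaded and eager; it is sized for
  datasets of 10³–10⁴ short sequences, not for GPU-scale training.
* The shipped AAindex-style table is a reduced 12-scale stand-in; the
  loader accepts any TSV with the same layout, and the stream dimension
  follows the loaded table.
* The dice components are batch-level set statistics; very small batches
  make them noisy, and classes absent from a batch contribute nothing
  for that step.
* Margins are applied during training only; applying them at prediction
  would shift the 0.5 threshold per class and per (unknown) label, so
  the evaluation path uses raw logits.
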