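# Methods

## Problem and model

`pssmrnn` classifies proteins into adaptor (positive) vs. non-adaptor
(negative) from their PSSM profiles alone. A PSSM profile for a query of
length *N* is an *N*×20 integer matrix of log-odds scores *P<sub>ij</sub>*
produced by iterative database search (PSI-BLAST, two iterations against
NR in the original protocol); row *i* scores each amino acid at position
*i*, and large values mark evolutionarily conserved positions. Columns
follow the PSI-BLAST header order `A R N D C Q E G H I L K M F P S T W Y V`,
fixed package-wide in `pssmrnn.alphabet`.

The classical route to fixed-size inputs sums all rows sharing the same
query residue, collapsing *N*×20 to 20×20 (a 400-dimensional vector).
That representation is invariant to any permutation of the profile rows
— positional information is gone by construction. The package's central
model avoids that collapse:

1. **Convolutional front-end.** Two stages of 1-D convolution (ReLU)
   along the position axis with the 20 PSSM columns as input channels,
   each stage followed by non-overlapping pooling with kernel = stride
   = 3. Convolutions are zero-padded to preserve length, so a length-*N*
   profile yields a feature sequence of length ⌊⌊N/3⌋/3⌋ — the designed
   9-fold reduction (900 → 100). Two equal pooling stages of stride 3
   are the only factorization that realizes exactly N/9.
2. **Recurrent module.** A gated recurrent unit reads the feature
   sequence. Per step, with update gate *z*, reset gate *r*:

       z_t = σ(W_iz x_t + b_iz + W_hz h_{t−1} + b_hz)
       r_t = σ(W_ir x_t + b_ir + W_hr h_{t−1} + b_hr)
       n_t = tanh(W_in x_t + b_in + r_t ∘ (W_hn h_{t−1} + b_hn))
       h_t = (1 − z_t) ∘ n_t + z_t ∘ h_{t−1}

3. **Head.** The final hidden state passes through a fully connected
   layer (ReLU), dropout, and a single sigmoid output: the probability
   the profile is an adaptor.

The network is implemented in numpy with hand-written backward passes
for every layer (convolution, pooling, GRU backpropagation-through-time,
dense, dropout) and an Adam optimizer. Gradient correctness is enforced
by a finite-difference check in the test suite; the GRU forward pass is
additionally checked against an independent scalar-by-scalar oracle.

## Training protocol

Adam with a fixed learning rate (default 1×10⁻⁴), 30 epochs, weighted
binary cross-entropy with inverse-class-frequency weights
w<sub>c</sub> = n<sub>total</sub>/(2 n<sub>c</sub>) (the protocol fixes
only the ratio w₊/w₋ = n₋/n₊; the ½ normalization keeps loss magnitude
comparable across imbalance levels), and stratified 5-fold
cross-validation. No early stopping or LR schedule. Default seed 7.

Variable-length profiles are handled without padding: minibatch
gradients (default batch 32 full-scale, 16 in the desk preset) are
accumulated per sample from the mean batch loss, which is exactly the
padded-batch gradient and makes inference trivially batch-size
invariant. Probabilities are clipped to [1e-7, 1−1e-7] inside the loss;
the gradient uses the fused sigmoid-BCE form w·(p − y).

Determinism: parameter initialization (Glorot for conv/dense, uniform
±1/√H for the GRU), shuffling, and dropout masks all derive from the
training seed, so two runs are bitwise identical.

## Architecture parameters

| parameter | default | origin |
|---|---|---|
| GRU hidden units | 256 | tuned full-scale value |
| FC layer width | 512 | tuned full-scale value |
| conv filters | (64, 128) | package choice (unspecified upstream) |
| conv kernel | 7 positions | package choice |
| pooling | max (switchable to avg) | both readings of the design exist; max is the architecture description, avg the feature-extraction text |
| GRU layers | 1 | smallest consistent with "multi-layer"; configurable |
| dropout | 0.5 after FC | conventional; configurable |
| input scaling | raw integer scores | optional elementwise logistic squash |
| profiles with N < 9 | rejected | opt-in zero-padding (`pad_short`), since padding semantics are this package's invention |

The "512 filters" annotation on the comparison table is read as the FC
width, which the architecture study states explicitly.

### Desk-scale preset

`presets.desk_model_config()` / `desk_train_config()` — conv filters
(16, 32), GRU 32, FC 64, dropout 0.2, lr 1×10⁻³, 10 epochs, batch 16 —
are the configuration used by the cross-validation tests and
`scripts/acceptance.py`. On the synthetic signals below, the narrow
network separates the classes as cleanly as the full one while training
on one CPU in minutes; the higher learning rate suits the smaller
parameter count. Problem sizes used by the acceptance script: 600
profiles (100 positive / 500 negative, lengths 90–270) in order mode,
240 profiles (60/180, lengths 45–90) in composition mode, 5-fold CV.

## Synthetic data: what it emulates and what it does not

`synthetic.generate_dataset` emulates the *shape* of the real problem —
variable-length integer N×20 profiles, class imbalance (default 1:5),
scores in the PSI-BLAST dynamic range (discretized normal, mean 0,
s.d. 2, clipped to [−10, 10]) — and plants a class signal whose nature
is controlled:

- **order mode**: every profile carries one conserved block
  (+effect_size on all 20 columns, default +4 over 15 positions) and one
  equally long depleted block (−effect_size); positives order them
  (conserved, depleted), negatives (depleted, conserved), block offsets
  uniform within each half. The multiset of rows is identically
  distributed between classes, so *any* row-order-invariant
  representation — the 400-dim summed features in particular — carries
  exactly zero class signal, while an order-aware model sees a clean
  early-vs-late contrast.
- **composition mode**: positives get a +effect_size shift on the E, F,
  G, V columns at every position. The signal survives summation, so
  classical baselines succeed too.
- **none**: both classes share one law (negative control).

What it does **not** emulate: realistic residue composition (residues
are uniform over the 20 letters), correlation between neighboring
positions, length–class dependence, homology structure between
sequences, or the actual motif grammar of adaptor domains (SH2/SH3/PTB
etc.). Passing the order-separation test therefore demonstrates that the
pipeline *can* exploit positional signal that summation destroys — the
mechanism claim — not that it attains any particular accuracy on real
adaptor data, which requires the curated benchmark and NR-database
PSSMs.

## Metrics

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), from confusion
counts with the tie rule "p ≥ threshold ⇒ positive" (threshold 0.5 by
default). Degenerate denominators: sensitivity/specificity are 0 when
their class is absent; MCC is 0 when any denominator factor is 0. ROC is
swept over all distinct scores (no intermediate dropping) and AUC is the
trapezoidal area, which equals the pairwise Mann–Whitney statistic with
ties counted ½ — the identity the tests assert to 1e-12.

## Comparator models

k-NN (k = 10), Random Forest (500 trees), RBF-SVM (C = 8, γ = 0.5) on
the 400-dim summed features, and a 2-D CNN (128 filters, 3×3; one
conv-ReLU-maxpool block, then FC-sigmoid, same loss/optimizer) on the
20×20 summed matrix. Features for the distance/kernel methods are
standardized on the training fold only and scaled by 1/√d: with plain
z-scoring of 400 dimensions, expected pairwise squared distances are
≈ 800 and an RBF with γ = 0.5 is numerically zero everywhere (the SVM
cannot rank at all, even on separable data); the 1/√d factor brings
pairwise distances to O(1), where the printed γ lies in the kernel's
responsive range, and leaves k-NN neighborhoods unchanged. SVM scores
are mapped to (0,1) by the logistic link on decision values — a fixed
monotone transform, so ROC/AUC are unaffected.

## Numerical choices and edge cases

- Sigmoid is evaluated in the overflow-safe split form.
- Max-pooling gradient routes to the argmax (first occurrence on exact
  ties along the pooling axis; the 2-D CNN splits gradient across exact
  ties, which for continuous activations almost never occur).
- Pooling drops trailing positions that do not fill a window (floor
  semantics), matching the ⌊⌊N/3⌋/3⌋ length contract.
- PSSM parsing keeps the first 20 numeric columns per row and accepts
  rows with 20, 40 or 42 numeric fields (score-only, scores+percentages,
  full dialect); anything else is a parse error naming the line.
  Non-canonical residues (B, Z, U, O, J) are kept with their score rows
  but mapped to `X`, which is excluded from composition counts and from
  summed-feature row assignment — discarding the rows would silently
  change N.
- The PSSM writer emits the full dialect with zeroed percentage/footer
  fields; round-trip identity is property-tested.

## Known limitations

- Single-threaded numpy training: full-scale configuration (256 GRU,
  30 epochs) on hundreds of profiles takes hours on one CPU; the desk
  preset exists for exactly this reason.
- `gru_layers > 1` is supported but the defaults use one layer.
- No confidence intervals on AUC, no calibration of probabilities (the
  SVM link and sigmoid outputs are scores, not calibrated posteriors).
- Real-data performance (the published cross-validation/independent
  numbers) is out of scope here: it depends on the curated UniProt/GO
  dataset and NR-database PSSM generation, both external services.
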