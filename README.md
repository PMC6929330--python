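# pssmrnn

Order-preserving classification of adaptor proteins from PSSM profiles
with a 1-D CNN + GRU architecture, together with the order-destroying
summed-PSSM baselines it is designed to beat.

Adaptor proteins are modular carrier proteins of signal transduction;
recognizing them from sequence is a binary protein-function-prediction
task. The strongest sequence feature for such tasks is the PSSM
(position-specific scoring matrix): an *N*×20 matrix of log-odds scores
*P<sub>ij</sub>* from iterative database search, one row per position.
Most classical pipelines collapse the PSSM to a 400-dimensional vector
by summing rows with the same query residue — which throws away *where*
along the sequence the conserved positions sit. This package implements
the alternative: keep the matrix ordered, extract local features with
two stages of 1-D convolution + pooling (length *N* → *N*/9), read the
feature sequence with a gated recurrent unit

    z_t = σ(W_iz x_t + b_iz + W_hz h_{t−1} + b_hz)
    r_t = σ(W_ir x_t + b_ir + W_hr h_{t−1} + b_hr)
    n_t = tanh(W_in x_t + b_in + r_t ∘ (W_hn h_{t−1} + b_hn))
    h_t = (1 − z_t) ∘ n_t + z_t ∘ h_{t−1}

and classify from the final hidden state through a fully connected layer
and a sigmoid. Training uses Adam with weighted binary cross-entropy
(inverse class frequency) and stratified 5-fold cross-validation;
evaluation reports sensitivity, specificity, accuracy, MCC and ROC/AUC.
The network and its backpropagation are implemented in numpy and are
bitwise reproducible under a fixed seed.

The package is aimed at bioinformaticians who want to (a) reproduce the
mechanism — positional signal survives the CNN+GRU but not summation —
on fully synthetic data, and (b) run the same pipeline on their own
PSI-BLAST ASCII PSSMs via a manifest file.

## Worked example

Generate a synthetic dataset in which the two classes contain the same
score material in opposite positional order (so summed features carry no
signal), then compare the recurrent model against k-NN on summed
features:

```python
import pssmrnn as pr

cfg = pr.SyntheticConfig(n_positive=40, n_negative=120,
                         length_range=(90, 180), signal_mode="order",
                         effect_size=4.0, seed=5)
dataset = pr.generate_dataset(cfg)

reports, rnn = pr.cross_validate(dataset, pr.desk_model_config(),
                                 pr.desk_train_config(epochs=5, seed=5))
X = pr.dataset_features(dataset)          # 400-dim summed-PSSM features
_, knn = pr.cross_validate_baseline(X, dataset.labels,
                                    pr.BaselineConfig(method="knn"), seed=5)
print(f"RNN  CV AUC {rnn['auc']:.3f}  MCC {rnn['mcc']:.3f}")
print(f"kNN  CV AUC {knn['auc']:.3f}  MCC {knn['mcc']:.3f}")
```

Output:

```
RNN  CV AUC 0.978  MCC 0.789
kNN  CV AUC 0.432  MCC -0.051
```

The recurrent model recovers the positional signal almost perfectly
(AUC 0.98), while k-NN on the order-collapsed representation is at chance
(AUC ≈ 0.5, MCC ≈ 0) — the 400-dim features of the two classes are
identically distributed by construction. In `signal_mode="composition"`
(a per-column mean shift), both routes succeed.

The same pipeline runs from the shell:

```bash
pssmrnn simulate --n-pos 100 --n-neg 500 --seed 7 --out data/
pssmrnn crossval --manifest data/manifest.tsv --out runs/rnn/
pssmrnn baseline --manifest data/manifest.tsv --method svm --out runs/svm/
pssmrnn featurize --manifest data/manifest.tsv --out features.tsv
```

Real PSSMs work the same way: point the manifest (TSV: `path`, `label`)
at PSI-BLAST `-out_ascii_pssm` files.

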