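# Methods

## The model family

A standard LSTM cell updates, for input `x_t`, hidden state `h_{t-1}` and
cell state `c_{t-1}`:

```
f_t = σ(W_fh h_{t-1} + W_fx x_t + b_f)
i_t = σ(W_ih h_{t-1} + W_ix x_t + b_i)
g_t = tanh(W_gh h_{t-1} + W_gx x_t + b_g)
c_t = f_t ⊙ c_{t-1} + i_t ⊙ g_t
o_t = σ(W_oh h_{t-1} + W_ox x_t + b_o)
h_t = o_t ⊙ tanh(c_t)
```

The strengthened-skip family augments this recurrence with the hidden
state from `skip` steps in the past, `h_{t-skip}`, along two axes:

* **where** the history enters — added directly to the output
  (`h_t ← h_t + h_{t-skip}`) or injected into every gate pre-activation
  through a learned matrix (`+ W_gskip h_{t-skip}`);
* **when** it enters — at every step ("continuous") or only at *trigger*
  steps `t = 1 + i·skip`, `i ∈ N+` ("discontinuous").

That gives variants A (discontinuous, direct), B (discontinuous,
weighted), C (continuous, direct) and D (continuous, weighted), plus two
multi-lag forms: E replaces the recurrent term at triggers with
`Σ_{l=1..skip} W_l h_{t-l}`, and F adds `Σ_{s=2..skip} h_{t-s}` directly
at triggers. The cell state `c_t` never receives skip information; only
the gates and `h` do. Time is 1-based and states at `t ≤ 0` are zero
vectors, so every variant is well defined from the first step.

Two intentional asymmetries follow the equations as written: variant B
*augments* the usual `W_gh h_{t-1}` term at triggers, while variant E
*replaces* it with the per-lag sum. Variant E is written out only for its
trigger form; off-trigger it runs a standard step with the lag-1 matrix
as the recurrent weight, and it generalises to `skip` lag matrices for
any order. The trigger-gated reading of E follows its "discontinuous"
description even though the equation itself carries no conditional; this
is a documented interpretation, not an asserted intent.

Why this should help with long-range structure: at a trigger, the
Jacobian `∂h_t/∂h_{t-skip}` of the direct-addition variants contains an
exact identity component, so backpropagation through time has a gradient
route that no gate can attenuate. The test suite verifies the identity
exactly and measures gradient-norm-vs-lag profiles (at T = 60 the plain
LSTM delivers ~1e-17 of gradient norm to `h_1`; the continuous-addition
variant delivers order 1).

## Network architecture

The classifier is three recurrent layers (hidden sizes 18, 8, 5 by
default) run in series — layer l's hidden sequence is layer l+1's input —
with a dense softmax readout from the final timestep's hidden state of
the last layer. The skip specification applies to every recurrent layer
by default and is configurable per layer.

Tabular records (e.g. a 16-feature questionnaire) first pass through a
dense tanh stack of widths 128/64/32/16. The published architecture
reshapes "the extractor output" to a 32×4 pseudo-sequence, but its last
layer is 16-wide; the only stack width divisible into 32×4 is the first
(128), so the first layer's activations feed the reshape (row-major).
The later stack layers are evaluated as part of the forward pass but do
not feed the classifier; this resolution of the contradiction is a
design choice documented here, not asserted as the original intent.

The readout head (dense layer from the 5-dim final hidden state to K
logits, then softmax) is likewise a choice the source architecture left
unspecified. Sequence classification uses the final timestep's state, not
pooling. Ties in argmax prediction break toward the lowest class index.

## Training

Plain stochastic gradient descent, learning rate 0.01, 50 epochs, batch
size 32, shuffled each epoch from an explicit seed. No momentum, weight
decay, schedules or early stopping. Initialisation is uniform in
±1/√(fan-in or hidden dim) with an explicit seed.

The optimised objective is the *summed* cross-entropy
`Loss = −Σ_i y_i log ŷ_i` over the batch (probabilities clamped at 1e-12
before the log). The sum rather than the batch mean matters at this
learning rate: with the batch-averaged loss the effective step is 32×
smaller and the network stays at chance within 50 epochs on every task we
generate, while the summed form reaches ~100% on delayed recall and
~94% on separation-3 tabular data (the Bayes ceiling there is Φ(1.5) ≈
93.3%). Reported loss curves show the per-sample mean for readability.
`cross_entropy` exposes both reductions; closed forms (0 for a perfect
prediction, ln 2 for a uniform binary one) hold for single samples under
either.

All gradients come from a small tape-based reverse-mode autodiff engine
over NumPy arrays written for this package (`ssrnn.autodiff`). Its
contract is enforced by tests: analytic gradients of every cell variant
and of the full network agree with central finite differences (ε = 1e-5)
to relative error below 1e-4 on tiny instances (observed ~1e-11), where
relative error uses the denominator max(|a|+|n|, 1).

## The comparison grid

The default grid is the plain-LSTM baseline plus every (variant, skip)
pair for skip ∈ {2, 3, 4, 5} — 25 configurations. All configurations
share one train/test split; each trains with a per-configuration seed
derived stably as `base_seed + CRC32("variant-skip") mod 2^31`. A failed
configuration is recorded and the grid continues.

## Metrics

Binary problems use the textbook confusion-matrix forms with class 1 as
positive: accuracy (TP+TN)/n, precision TP/(TP+FP), recall TP/(TP+FN),
F1 the harmonic mean. Multi-class problems compute one-vs-rest per-class
scores aggregated support-weighted (default) or unweighted. The
support-weighted averaging is chosen because its recall is algebraically
identical to overall accuracy — the signature visible in the published
result tables, where the Recall column equals Accuracy. A class never
predicted has precision 0 with a warning. The implementation rests on
scikit-learn's confusion matrix; tests check the whole path against an
explicit counting oracle.

## Preprocessing and splits

Mean imputation for numeric columns, mode imputation for binary (0/1)
columns; a column with no observed values is an error. Outlier records
are removed when any numeric feature exceeds |z| > 3 (the published
pipeline names only "anomaly detection"; the z-score rule is this
package's concrete choice). The rule is applied to convergence, because
removals shift column statistics and a single pass is not idempotent;
the converged filter is a true fixed point. Zero-variance columns never
flag.

The standard split is 80/20 with |train| = round-half-up(0.8·n), which
reproduces all five published train/test sizes exactly (109,338→87,470;
11,500→9,200; 361,377→289,102; 520→416; 116→93). The split is a seeded
shuffle, stratified by label for tabular data and unstratified for
sequence data; whether the original splits were stratified or
chronological is unknown, so the seeded shuffle is the documented
default.

## Synthetic benchmarks

`gen_delayed_recall` emits sequences of one-hot symbols drawn uniformly
from a vocabulary of V (default 4), length T = 20, with the label equal
to the symbol at 1-based position T − lag (default lag 3). Optional
isotropic Gaussian noise on the codes (default 0) keeps the Bayes
accuracy analytic: exactly 1 at zero noise. `gen_tabular` draws a
16-feature binary-label table from two class-conditional Gaussians whose
means differ by `separation` in Mahalanobis distance (default 3, Bayes
accuracy Φ(separation/2)); missing cells and 8σ outlier records are
injected at configurable rates with ground truth retained.

What these do *not* emulate: real ECG/EEG morphology, class imbalance,
label noise, non-stationarity, or correlated features. Passing tests
demonstrate the mechanics of the cells, training loop and preprocessing
under controlled conditions — not clinical performance.

### The ceiling effect in the long-memory comparison

The delayed-recall comparison at T = 20, lag = 3 (2,000 train / 500
test, 50 epochs) is run for variant A (skip = 3) against the plain LSTM
over 5 seeds. Variant A reaches ≥ 99.8% test accuracy on every seed.
However, a lag of 3 counted from the sequence *end* requires only three
steps of memory, which a plain LSTM also masters: the baseline reaches
96–100% and both models sit at the accuracy ceiling, so strict per-seed
wins degenerate into near-ties (observed 3 strict wins out of 5, with
one exact 1.000/1.000 tie). The strict-win count is reported as measured
rather than engineered around, and the matched-skip accuracy criterion
itself is comfortably met. A task whose dependency sits a long *and*
variable distance from the readout would discriminate better; that is
left as a known limitation of the benchmark design, not patched
post hoc.

## Problem sizes used by tests and the acceptance script

Reduction and gradient checks run at input dim 2–3, hidden 3–4, T = 3–9
(100 random instances per variant for reductions). The pipeline smoke
test uses 260 records at separation 6 for 50 epochs per variant. The
long-memory comparison uses the full stated conditions (2,500 sequences,
50 epochs, 5 seeds, both models), which dominates the runtime at roughly
a minute per trained model on one CPU. These sizes are the package's
chosen defaults for its own verification.

## Known limitations

* The engine is NumPy-based and single-threaded; it is built for
  correctness and small research-scale problems, not GPU-scale training.
* Variant E's trigger-gated reading and the 128-unit reshape resolution
  are documented interpretations of ambiguous source material.
* Real-data adapters (ECG/EEG databases) are out of scope; readers for
  the delimited formats are provided instead.
* No early stopping or adaptive optimisers, by design: the training
  recipe is deliberately the published one.
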