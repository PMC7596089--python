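# Methods

This note documents the models implemented in `deidseq`, the synthetic
data they are exercised on, the numerical and design choices that were
genuinely open, and what the package's tests do and do not establish.

## Problem setting

De-identification of free-text health records is cast as sequence
labeling: each sentence `s = {s_1, …, s_n}` is tokenized, and each token
receives a tag from the BIOES scheme crossed with a PHI category
(`B-DOCTOR`, `I-DOCTOR`, `E-DOCTOR`, `S-DATE`, …, or `O`). BIOES rather
than BIO2 because it distinguishes the *end* of a multi-token PHI
instance from a single-token instance, which sharpens span boundaries.
With `C` categories the label set has `k = 4C + 1` elements.

Privacy is asymmetric: a false negative (a missed name) can re-identify
a whole record, while a false positive only deletes one harmless token.
The package therefore treats recall as the privacy metric and precision
as a utility concern, and its evaluation and loss machinery follow that
asymmetry.

## Model stack

**Embedding layer.** On the recurrent paths each token is embedded as
`e_i = V_T(s_i) ⊕ b_i`. `V_T` is a word-vector table — either loaded
frozen from a GloVe-format text file (100-dimensional by default) or,
when no pretrained file is supplied (the usual case for the synthetic
corpora, whose vocabulary is coined), a trainable table of width
`d_word` (default 50). `b_i` is the character-level representation: a
bidirectional GRU runs over the token's character embeddings
(`d_char = 25`) and `b_i` concatenates the backward GRU's state at the
first character with the forward GRU's state at the last character
(`2 × d_char_hidden = 50` dims). Character dimensions are the package's
own defaults; they are config-exposed. The character path is what lets
the tagger generalize to out-of-vocabulary surface forms (held-out
names, unseen dates), and it can be disabled to reproduce the
words-only ablation.

The self-attention path instead uses a *dynamic* embedding: a trainable
token embedding of width `d_model` plus a fixed sinusoidal positional
encoding. Sinusoidal (not learned) positions keep the encoder
deterministic given its seed and make the positional structure
testable in closed form.

**Context layer.** Four interchangeable encoders map `e_{1:n}` to
context vectors `r_{1:n}` behind one interface:

* `gru` — one bidirectional GRU; `r_i = g_i^f ⊕ g_i^b` per *time step*
  (contrast with the character encoder, which keeps only final states).
* `gru_gru`, `lstm_gru` — two stacked bidirectional layers wired
  direction-wise: the first layer's forward outputs feed the second
  layer's forward GRU, backward feeds backward; `r_i` comes from the
  second layer. The first layer is a GRU or an LSTM respectively. The
  wiring follows the stacked-RNN description in which the first-layer
  hidden state is relayed to the second-layer unit of the same
  direction; the `gru_gru` variant covers the two-GRU reading of that
  architecture.
* `self_attention` — a bidirectional Transformer encoder (no causal
  mask): per head `a_ij = (e_i W^Q)(e_j W^K)ᵀ/√d_z`, `γ_ij` the row
  softmax, `z_i = Σ_j γ_ij (e_j W^V)`; heads are concatenated and
  linearly mixed, followed by residual connection + layer norm and a
  position-wise feed-forward block, per layer. Defaults here are small
  on purpose (`d_model = 64`, 4 heads, 2 layers, FFN 256 in the
  estimator) so the model trains in minutes on one CPU; a
  Wikipedia-scale pretrained encoder is out of scope.

Dropout is inverted (survivors scaled by `1/(1−rate)`, identity at
evaluation) and applied to embeddings and between stacked layers;
defaults are 0.5 on recurrent paths and 0.25 on the attention path.

**Decoding layer.** Context vectors pass through one fully connected
projection to per-label emission scores `r ∈ ℝ^{n×k}` and then either

* softmax: `q_j(r_i) = exp r_ij / Σ_k exp r_ik`, trained with
  cross-entropy, decoded by per-token argmax (ties to the lowest label
  id); or
* a linear-chain CRF: path score
  `b_start[y_1] + Σ_t r[t, y_t] + Σ_t W[y_{t−1}, y_t] + b_end[y_n]`,
  trained by maximum conditional likelihood with the partition computed
  by the forward algorithm entirely in log space, decoded by Viterbi.
  A hard BIOES constraint mask (on by default) assigns a large negative
  score (−10⁴, kept finite so gradients never NaN) to grammar-invalid
  transitions, so decoded paths are always valid span sets. The softmax
  path has no such guarantee and relies on the repair policy below.

Both paths project with a single linear layer; the attention encoder
already contains its own feed-forward sublayer, so no extra hidden
layer is inserted anywhere.

**BIOES repair policy.** Model output that violates the grammar is
never discarded — a dropped PHI token is a privacy failure — but
repaired deterministically: an `I`/`E` with no compatible open span is
treated as `B`/`S` respectively, and an unclosed span is closed at its
last contiguous same-category token. Repairs are counted and reported.

**Recall-weighted loss.** The batch false-negative rate is
`FNR = FN/(1 + FN + TP)` (the `1+` keeps it finite on empty batches)
and the penalty is `ρ = FNR × [(δ_p − 1) + 1]`, so `ρ ∈ [0, δ_p]` and
`δ_p = 1` reduces `ρ` to the FNR. FN/TP are counted on the binary
PHI/non-PHI reduction of the batch's own decoded predictions against
gold — per mini-batch, because a per-epoch count would give one stale
scalar per epoch and no usable signal. Two weighting modes ship:
`literal` (`L = L_regular × ρ`) implements the formula exactly as
stated, but it zeroes the loss whenever a batch has no false negatives,
which stalls all learning of precision; `one_plus_rho`
(`L = L_regular × (1 + ρ)`) preserves the base gradient and is the mode
used in the recall experiments. Weighting is off by default: the
baseline models train on the unmodified likelihood.

## Training

Adam on mini-batches bucketed by exact sentence length — equal-length
batches mean no padding, no masks, and no masked-position edge cases
anywhere in the recurrent or CRF code. Gradients are globally
norm-clipped at 25. Learning rates default to 5e-3 (recurrent) and
3e-3 (attention); these were chosen by pilot runs on synthetic corpora
as the fastest stable settings for this float64 NumPy stack, and are
config-exposed. Early stopping monitors validation binary-PHI F1 with
patience 3 and restores the best checkpoint. Every random draw
(initialization, shuffling, dropout) flows from the estimator's single
`seed`; two fits with the same seed and data are bit-identical.

## Evaluation

The primary metric is the binary HIPAA token-based evaluation: each
token is PHI (any non-`O` tag) or not, `P = TP/(TP+FP)`,
`R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`, with the convention that a ratio
with zero denominator is 0 (and F1 = 0 when P + R = 0). Per-category
and exact-span scores are reported secondarily. Predictions pass
through the repair policy before counting. Every report can be
recomputed from the per-token prediction dump (token, gold, predicted),
and `evaluate_corpus` performs that recount as a built-in self-check.

## Utility metrics

De-identified text for BLEU and topic modeling uses removal (not
placeholders), because both false positives and false negatives then
change the token stream that downstream consumers see.

* **BLEU-n** (n = 1, 2, 3): modified n-gram precision with clipping,
  geometric mean over orders, brevity penalty `exp(1 − ref/cand)` for
  short candidates; per document and macro-averaged. The ground-truth
  arm (gold PHI removed) is the utility attainable at perfect privacy.
  Removing strictly more tokens from a document never increases BLEU-1;
  no ordering between BLEU orders is assumed.
* **Topic match**: LDA (scikit-learn, batch EM, fixed seed) with T = 5
  topics and 30 top words per topic by default, fitted separately on
  the original and de-identified corpora after lowercasing and English
  stopword removal. Topics are aligned across the two fits by greedy
  maximum word overlap (Hungarian assignment available via a flag);
  the report gives per-topic and overall match percentages.
* **Paired classification**: one bag-of-words + logistic-regression
  classifier per corpus arm, identical train/test document ids across
  arms, accuracy on a document-level label restricted to the
  `n_labels ∈ {3, 5, 7}` most frequent classes. Differences between
  arms are attributable only to the texts.

## Synthetic corpus

Restricted corpora are replaced by a generator that emits documents of
template sentences: background clinical prose drawn from a fixed
vocabulary (a clinical word stock padded with coined lowercase words),
interleaved with PHI slots filled from per-category lexicons — coined
capitalized names, digit-pattern dates/phones/IDs, ages, coined
hospitals/locations with realistic suffixes, and a fixed profession
list. Every filler is annotated with its exact character span.

Defaults define the study conditions: 0.8 expected PHI instances per
sentence (integer part + one Bernoulli draw, so the expectation is
exact), 30% multi-token PHI so B/I/E tags are exercised, 9 categories,
8–12 sentences per document, and a resulting non-PHI:PHI token ratio of
roughly 14:1 (real corpora run nearer 35:1; the generator guarantees at
least 10:1). Documents are split 80:20 into (train+validation):test and
the former re-split 80:20. A fifth of each lexicon is held out and
appears only in test documents, forcing out-of-vocabulary
generalization. Each document also carries a synthetic class label
planted as class-specific background keywords, giving the
classification utility metric something real to predict. No PHI
surface string occurs in the background vocabulary, so gold labels are
unambiguous.

What the generator does *not* emulate: the statistical texture of real
clinical language (misspellings, abbreviations, section headers,
copy-paste noise), annotation disagreement, and category frequencies of
any particular corpus. Passing tests therefore demonstrate that the
architecture, losses, decoding and metrics are implemented correctly
and can learn a learnable signal — not that any particular F1 would be
attained on i2b2-class data.

## Numerical choices and degenerate inputs

Float64 throughout; the autodiff engine is plain NumPy reverse-mode
with a topological backward pass. Log-space forward algorithm and
log-sum-exp with max-shift everywhere a partition or softmax appears.
Viterbi and argmax ties resolve to the lowest label id,
deterministically. Empty sentences are rejected by context models;
empty tokens by the character encoder; `δ_p < 1`, dropout rate ≥ 1,
negative counts and non-finite emissions raise immediately. A fully
masked CRF (no legal path) is a decoding error, not a silent fallback.
Unknown words map to a reserved id (trainable path) or to one seeded
unknown vector drawn once per table (frozen path); unknown characters
to a reserved char id.

## Scale of the shipped experiments

The test suite trains on corpora of 60–525 documents (~600–5,000
sentences) with hidden sizes 16–48 — sizes chosen so the full suite
and the acceptance script each run in minutes on a single CPU while
still crossing the learning thresholds they assert (binary F1 ≥ 0.95 on
the 5,000-sentence fixture; recall ordering of δ_p = 10 vs δ_p = 1
over three seeds). `scripts/acceptance.py` uses a 150-document corpus
for the same reason.

## Known limitations

* No subword/WordPiece vocabulary and no pretraining; the attention
  model here is orders of magnitude smaller than production encoders.
* The tokenizer is rule-based (whitespace, punctuation split-off,
  digit-pattern and abbreviation protection); it is deliberately simple
  and config-exposed, not a clinical tokenizer.
* ρ is computed per mini-batch; batch composition therefore influences
  the recall penalty's variance.
* Topic-match percentages on small synthetic corpora are noisy — LDA
  fits on coined vocabularies are only weakly identified; the metric is
  most meaningful comparatively (same corpora, different arms).
* Checkpoints are Python pickles: convenient and complete, but not a
  cross-version interchange format.
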