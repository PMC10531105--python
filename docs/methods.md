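# Methods

## Problem

Follow-up CT reports of cancer patients carry, in their free-text
"Conclusion" section, the information an oncologist needs to call the
disease response relative to the prior scan: **NED** (no evidence of
disease), **PR** (partial response), **SD** (stable disease) or **PD**
(progressive disease).  `radresponse` implements, at a scale that trains
and tests on one CPU, the full method stack for inferring that 4-class
label from the conclusion text: classical bag-of-words baselines, small
neural sequence classifiers, sentence-permutation data augmentation with a
consistency objective, and cloze-prompt few-shot fine-tuning of a masked
language model — together with the evaluation protocol (patient-level
splits, multi-seed averaging, paired tests, agreement statistics) needed
to compare them.

Real clinical corpora of this kind are private, so the package ships a
synthetic-corpus generator that reproduces the statistical structure the
methods rely on; every experiment in the test-suite and in
`scripts/acceptance.py` runs end-to-end on generated data.

## Data model and splitting

A `ReportRecord` holds one conclusion text, a patient id and a label; a
`Corpus` indexes records by patient and enforces unique report ids and
patient-consistent split tags.  Splitting is done at the **patient** level
(all reports of a patient land in one fold), because deployed models face
new patients, and report-level splits would leak patient-specific phrasing
across folds.  Patient counts per fold follow largest-remainder
apportionment of the (0.8, 0.1, 0.1) fractions over the sorted, seeded-
shuffled patient list; remainder ties break toward the lower fold index.
This rule is one deterministic choice among several defensible ones — the
exact randomization used to produce the reference 80/10/10 design is not
fully constrained — and is fixed here for reproducibility.

## Synthetic corpus generator

Each conclusion is a sequence of template sentences, each tagged with a
role: `ned_statement`, `shrink`, `stable`, `growth`, `new_lesion`,
`benign`, or `distractor`.  A deterministic, order-free **oracle** maps
the multiset of roles to the label with the precedence a RECIST-style
guideline would use: any growth or new lesion ⇒ PD; else any shrinkage ⇒
PR; else any stable finding ⇒ SD; else NED.  Mixed findings (shrinkage
plus growth) therefore read as progression.

Generation samples the target label first from the configured class
marginals — default (0.390, 0.114, 0.144, 0.352) for NED/PR/SD/PD, the
class mix of a large real-world report corpus — then composes a role
multiset consistent with that label, adds 0–3 label-neutral distractor
sentences (plus an occasional hedging sentence, probability 0.1), fills
template slots (anatomical site, lesion type, sizes), and shuffles
sentence order.  Because the label is sampled first and composition is
rejection-free, empirical class proportions converge to the marginals at
the usual 1/sqrt(n) rate.  Reports per patient follow 1 + Poisson(mean−1)
with mean 6, matching the average report count per patient in the
reference cohort while guaranteeing at least one report.  If a
composition yields a single sentence, one distractor is appended:
multi-region CT conclusions essentially always contain several
statements, and a second sentence guarantees permutation augmentation
applies to every record.

Sizes inside shrink/growth/stable templates are numerically consistent
(current < prior for shrinkage, and so on), but the oracle reads only
roles; numeric reasoning is deliberately out of scope.

What the generator does **not** emulate: real radiology syntax and
discourse (anaphora across sentences, hedged impressions that change the
label, negation scope subtleties), indeterminate responses (excluded from
the reference corpus by design), label noise in the gold standard, and
class-conditional report-length effects.  Passing tests on this corpus
therefore demonstrate that the training and evaluation machinery behaves
as specified — not that any model here reaches clinical-grade accuracy on
real reports.

A separate utility injects annotation noise (per-record flip probability
plus a row-stochastic confusion matrix) to exercise the agreement
statistics on corpora with a simulated second annotator.

## Sentence permutation and the consistency objective

Sentences in a conclusion are close to order-exchangeable, so permuting
them yields a new, label-preserving text.  `split_sentences` is a
hand-written splitter (terminal punctuation, with an abbreviation list,
numbered-list markers and single-letter initials protected) whose output
joined with single spaces reproduces the whitespace-normalized input.
`permute_conclusion` returns exactly min(P, n!−1) distinct non-identity
orders for an n-sentence text (default P = 10); for small n all orders
are enumerated and sampled without replacement, otherwise orders are
rejection-sampled with a bounded attempt budget.  Distinctness is
enforced on order vectors; textually colliding variants (possible when a
text contains duplicate sentences) are dropped afterwards.

Training minimizes

    L = α · L_CE + β · L_MSE,    L_MSE = (1/C) Σ_c (ŷ_c − ŷP_c)²

with C = 4, α = 1, β = 10: the mean squared difference between the
model's label distributions on the original (ŷ) and on one uniformly
sampled permuted variant (ŷP) per step.  The MSE is computed on
probabilities, not logits, and gradients flow through both branches (no
stop-gradient; a fixed-teacher variant is a one-line change but is not
the default).  Permuted variants also enter the cross-entropy term as
additional labeled examples by default (`include_variants_in_ce`), since
augmentation is also meant to enlarge the labeled set; both choices are
configurable.  With β = 0 and variants excluded from the CE term the
consistency trainer reduces bit-for-bit to the plain trainer under the
same seed, which the tests verify.

## Classical baselines

TF-IDF features feed a linear SVM (with Platt-calibrated probabilities,
needed for soft voting), a multinomial logistic regression, gradient
boosted trees, and their unweighted soft-vote ensemble (scikit-learn and
xgboost underneath).  N-grams (default range (1,2), min document
frequency 2) are computed **within** sentence boundaries; cross-sentence
bigrams would otherwise make the features weakly order-sensitive, and
exact sentence-order invariance is precisely the property that lets these
models serve as an oracle for the augmentation module: for any trained
classical model, predictions on a conclusion and on any sentence
permutation of it are bit-identical.  Gradient-boosted-tree settings (200
rounds, depth 6, learning rate 0.1) are conventional defaults; argmax
ties break toward the lower class code everywhere in the package.

## Neural classifiers

Because the training loops must expose and combine per-branch loss terms,
the sequence models are built on a small reverse-mode autodiff engine
over numpy arrays (`_autograd`), checked against finite differences in
the test-suite.  Three encoders share one classification head
(dense 64 → dense 4, softmax):

- **tiny_transformer** — 2 pre-LN blocks, model dim 64, 4 heads,
  feed-forward 128, learned positional embeddings, a learned
  classification token whose final state is pooled; final-layer attention
  from that token provides saliency weights.
- **bilstm** — embedding dim 64, hidden 64 per direction; padded steps
  carry state through unchanged, and the pooled output concatenates the
  final states of the two directions (head shape 64 → 4 as printed in the
  reference architecture description).
- **cnn** — embedding dim 64, one 1-D convolution (64 filters, kernel 3)
  and masked max-pooling over time.

Tokenization is whitespace-plus-punctuation with a frequency-capped
vocabulary (padding and out-of-vocabulary tokens reserved; vocabulary
order is frequency-then-lexicographic, so identical corpora give
identical tokenizers).  Optimization is Adam (learning rate 1e-3 unless
stated), right-padding with attention masking, truncation from the tail
at `max_seq_len`, no dropout and no class reweighting.  Training records
per-step loss components and per-epoch dev accuracy, returns the
best-dev-accuracy snapshot, and is bit-reproducible given the seed.  The
architectures are sized for CPU training; a `pretrained_adapter` seam
accepts any externally supplied encoder with the same interface, so
checkpoint-scale experiments remain possible without any test depending
on them.

## Cloze-prompt few-shot fine-tuning

Classification is reframed as masked-token prediction.  The prompt is

    [INPUT_TEXT] [SEP] In summary, this is a [MASK]

with the verbalizer {0: "no evidence of disease", 1: "partial response",
2: "stable disease", 3: "progressive disease"}.  The mask span holds k
tokens; by default k is the longest tokenized verbalization (4 with the
built-in tokenizer), because the reference hyperparameter
max_num_lbl_tok = 2 would truncate the four-token NED phrase — the value
2 remains selectable, with truncation.  Each class is scored by the mean
per-token log-probability of its verbalization at the span (length
normalization, so shorter phrases are not favored), and the four scores
are softmax-normalized into a label distribution.

Fine-tuning minimizes the sum of:

- a **decoupled label loss**: per-token binary cross-entropy over the
  candidate verbalizations' tokens at the mask span — true-label tokens
  pushed toward probability 1, the other candidates' tokens toward 0,
  averaged over the involved (position, token) pairs.  Negatives are the
  competing candidates' tokens by default; a full-vocabulary variant is
  available behind a flag.
- a **label-conditioned MLM loss**: the span is filled with a candidate's
  verbalization, input tokens are masked independently at ratio 0.15, and
  the model must reconstruct them (target 1) when the candidate is the
  true label or not reconstruct them (target 0) otherwise.  One candidate
  per example per step is sampled uniformly from the four classes.

Two prompt-construction details matter at this scale.  First, the input
segment is padded to a fixed budget (56 tokens; padding is excluded from
attention), so the prompt suffix and mask span occupy the same positions
for every input.  With a briefly pretrained tiny LM, a length-dependent
mask position does not generalize across unseen input lengths; fixing the
position removes that failure mode without changing the template text.
Second, overlong inputs are truncated from the tail — never the suffix.

The default configuration keeps the reference values (2000 batches,
learning rate 1e-5, eval every 100), which target checkpoint-scale
models; the desk-scale experiments use 200 batches of size 16 at 1e-3
with dev evaluation every 20 batches and best-dev selection, settings
matched to the tiny model's from-scratch classifier training regime.  The
comparison baseline is **head-only fine-tuning of the same encoder**: the
standard dense(64)→4 head trained on frozen mean-pooled hidden states
with the same optimizer, batch budget and best-dev selection.  The
few-shot corpus is a class-stratified subsample (largest-remainder
apportionment of the empirical class proportions, seeded).

## Evaluation harness

`evaluate` returns accuracy, micro/macro precision-recall-F1, per-class
metrics and the 4×4 confusion matrix (rows gold, columns predicted); in
single-label multiclass classification accuracy equals micro-F1,
micro-precision and micro-recall, and the tests assert that identity on
randomized instances.  Multi-seed results aggregate to mean and sample
standard deviation.  The paired t-test pairs per-seed accuracies (n =
number of seeds; per-example pairing is available behind a flag in
spirit via passing per-example indicators); zero-variance differences are
flagged as degenerate, with the identical-input case returning t = 0,
p = 1 by convention.  Cohen's κ and Spearman's ρ (mid-rank ties) come
from scikit-learn and scipy, cross-checked against hand formulas in the
tests; the reference study's κ = 0.83 and ρ = 0.85 depend on its private
annotations and are not reproduction targets.  Learning curves drive any
trainer closure over stratified subsamples of increasing size with fixed
seeds.  Saliency for transformer classifiers is the mean over heads of
final-layer attention from the classification token, min-max normalized
to [0, 1] and rendered as red-shaded HTML; non-attention architectures
are directed to a gradient-based alternative rather than silently
approximated.

## Numerical and degenerate-input conventions

Probabilities inside BCE terms are clamped to [1e-7, 1 − 1e-7]; label
distributions are validated to sum to 1 within 1e-6; argmax ties break
toward the lower class code; min-max normalization of an all-equal
saliency vector returns all ones; `spearman_rho` rejects constant
vectors; `label_conditioned_mlm_loss` resamples its masking once and then
raises if no input token was selected (the training loop skips such
examples).  All randomness flows through `numpy.random.default_rng`
seeded from explicit configuration fields.

## Desk-scale experiment sizes

The two directional experiments (consistency training and prompt
few-shot) run on a generated corpus of 150 patients (~900 reports,
patient-level 80/10/10 split), subsample 100 labeled training reports,
and average 3 seeds — sizes at which each arm trains in under a minute on
one CPU core and the contrasts are stable across seeds.  They mirror the
low-data regime of the reference results directionally, not numerically:
absolute accuracies here describe the synthetic corpus only.

## Known limitations

- The synthetic corpus is lexically much easier than real radiology text;
  classical baselines can approach ceiling on it.
- The tiny masked LM is pretrained for a few hundred batches on the
  synthetic corpus itself; it is a stand-in for a clinical PLM, not a
  miniature of one.
- The permutation oracle ignores sentence-level numeric content, and the
  role-to-label precedence is one plausible reading of consensus
  guidelines whose exact content is not public.
- Saliency is reported from attention weights, which are an
  interpretability heuristic, not an attribution guarantee.
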