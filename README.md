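# radresponse

Inferring 4-class cancer disease response — **NED** (no evidence of
disease), **PR** (partial response), **SD** (stable disease), **PD**
(progressive disease) — from the free-text *Conclusion* section of
follow-up CT radiology reports.

Oncology researchers derive progression-free survival from exactly this
kind of per-report response call, and clinicians can use an automated
call as a second opinion.  This package implements the full method stack
for the task at a scale that trains and evaluates on a single CPU:

- a labeled-corpus data model with **patient-level** 80/10/10 splitting
  (no patient's reports leak across folds) and JSON-lines serialization;
- a **synthetic corpus generator** — template sentences with semantic
  roles, a deterministic order-free label oracle (growth/new lesion ⇒ PD,
  else shrinkage ⇒ PR, else stable ⇒ SD, else NED), class marginals
  0.390/0.114/0.144/0.352 and ~6 reports per patient — so every method is
  testable without private clinical data;
- **sentence-permutation augmentation** with a consistency objective

  L = α·L_CE + β·L_MSE,  L_MSE = (1/C) Σ_c (ŷ_c − ŷP_c)²,  C = 4

  (defaults α = 1, β = 10, P = 10 permuted variants per training text);
- **classical baselines**: TF-IDF with linear SVM, logistic regression,
  gradient-boosted trees, and their soft-vote ensemble — exactly
  invariant to sentence order, which makes them an oracle for the
  augmentation's label-preservation claim;
- **neural classifiers** (tiny transformer, Bi-LSTM, CNN) with plain and
  consistency-regularized training loops, built on a small in-package
  autodiff engine and an adapter seam for external pretrained encoders;
- **cloze-prompt few-shot fine-tuning** of a masked language model with
  the prompt `"[INPUT_TEXT] [SEP] In summary, this is a [MASK]"`, a
  verbalizer mapping the four classes to label phrases, and the sum of a
  decoupled label loss and a label-conditioned MLM loss;
- an **evaluation harness**: accuracy (≡ micro-F1 in single-label
  multiclass), per-class breakdowns, confusion matrices, multi-seed
  aggregation, paired t-tests, learning curves, Cohen's κ, Spearman's ρ,
  and attention-based token saliency rendered as HTML.

## Worked example

```python
import numpy as np
import radresponse as rr

corpus = rr.generate_corpus(rr.GeneratorConfig(n_patients=200, seed=7))
split = rr.split_by_patient(corpus, rr.SplitSpec(seed=1))
train, test = split.subset("train"), split.subset("test")

model = rr.train_classical("soft_vote_ensemble",
                           train.texts(), train.labels(), seed=0)
result = rr.evaluate(model.predict(test.texts()), test.labels())
print(f"ensemble accuracy: {result.accuracy:.4f}")

rec = test[0]
variant = rr.permute_conclusion(rec, rr.AugmentationConfig(P=1, seed=0))[0]
print(np.array_equal(model.predict_proba(rec.conclusion_text),
                     model.predict_proba(variant.text)))
```

prints

```
ensemble accuracy: 0.9908
True
```

The corpus here is 1209 synthetic reports over 200 patients with class
mix NED 38.6 / PR 10.9 / SD 14.2 / PD 36.2 percent.  The ensemble's
0.9908 test accuracy says the generated corpus is lexically easy for
bag-of-words models — the generator is a statistical stand-in, not a
difficulty benchmark — and `True` confirms the prediction is bit-identical
on a sentence-permuted conclusion, the invariance that justifies
permutation augmentation.  The same corpus drives the neural experiments:
consistency training (`rr.train_with_consistency`) lowers the held-out
original-vs-permuted prediction divergence and preserves accuracy, and
prompt-based fine-tuning (`rr.train_prompt`) beats head-only training of
the same encoder when only 100 labeled reports are available.

A command-line interface covers the corpus workflow:

```bash
radresponse generate --n-patients 200 --seed 7 --out corpus.jsonl
radresponse split --in corpus.jsonl --out split.jsonl --fractions 0.8,0.1,0.1 --seed 1
radresponse stats --in split.jsonl
radresponse augment --in split.jsonl --out augmented.jsonl --p 10 --seed 0
radresponse train-classical --kind ensemble --train split.jsonl --model-out model.joblib
radresponse predict-classical --model model.joblib --in split.jsonl --out pred.csv
radresponse evaluate --pred pred.csv --gold split.jsonl --out metrics.json
```

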