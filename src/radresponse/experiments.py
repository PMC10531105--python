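"""Desk-scale training experiments shared by the test-suite and the
reproduction script.

Both experiments run on the synthetic corpus in the low-data regime
(100 labeled training reports) and average over 3 random seeds:

- ``consistency_comparison``: plain cross-entropy training of the tiny
  transformer versus training with sentence-permutation augmentation and
  consistency loss (alpha=1, beta=10, P=10), reporting mean test accuracy
  and the mean original-vs-permuted prediction divergence of each arm.
- ``prompt_comparison``: cloze-prompt fine-tuning of a briefly pretrained
  tiny masked LM on the 100 labeled reports versus head-only fitting of a
  classifier on the same frozen encoder.

Problem sizes (150 generator patients -> roughly a thousand reports, 8
training epochs, a few hundred prompt batches) are chosen so each arm
trains in well under a minute on one CPU core while the qualitative
contrasts remain stable across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augmentation import AugmentationConfig, ConsistencyWeights
from .corpus import Corpus, SplitSpec, split_by_patient
from .evaluation import evaluate
from .neural import (
    EncoderSpec,
    TrainConfig,
    permutation_divergence,
    train_supervised,
    train_with_consistency,
)
from .prompt import (
    PromptSpec,
    PromptTrainConfig,
    TinyMaskedLM,
    _prompt_accuracy,
    default_label_span,
    few_shot_sample,
    pretrain_mlm,
    train_head_only,
    train_prompt,
)
from .synthetic import GeneratorConfig, generate_corpus

__all__ = [
    "experiment_corpus",
    "consistency_comparison",
    "prompt_comparison",
]


def experiment_corpus(seed: int, n_patients: int = 150) -> tuple[Corpus, ...]:
    """Generate and split the corpus used by the training experiments."""
    corpus = generate_corpus(GeneratorConfig(n_patients=n_patients, seed=seed))
    sp = split_by_patient(corpus, SplitSpec(seed=seed + 1))
    return sp.subset("train"), sp.subset("dev"), sp.subset("test")


@dataclass(frozen=True)
class ConsistencyOutcome:
    acc_plain: tuple[float, ...]
    acc_consistency: tuple[float, ...]
    divergence_plain: tuple[float, ...]
    divergence_consistency: tuple[float, ...]

    @property
    def mean_acc_plain(self) -> float:
        return float(np.mean(self.acc_plain))

    @property
    def mean_acc_consistency(self) -> float:
        return float(np.mean(self.acc_consistency))

    @property
    def mean_divergence_plain(self) -> float:
        return float(np.mean(self.divergence_plain))

    @property
    def mean_divergence_consistency(self) -> float:
        return float(np.mean(self.divergence_consistency))


def consistency_comparison(
    base_seed: int = 0,
    seeds: tuple[int, ...] = (0, 1, 2),
    n_train: int = 100,
    epochs: int = 8,
) -> ConsistencyOutcome:
    """Plain vs consistency-regularized training of the tiny transformer.

    Both arms share the corpus, the 100-report training subsample, the
    model initialization and the batch order per seed; only the objective
    differs (alpha=1, beta=10, P=10 in the consistency arm).
    """
    train, dev, test = experiment_corpus(base_seed + 3)
    spec = EncoderSpec(kind="tiny_transformer")
    cfg = TrainConfig(epochs=epochs, learning_rate=1e-3, train_batch_size=16)
    ap, ac, dp, dc = [], [], [], []
    for seed in seeds:
        sub = few_shot_sample(train, n_train, seed=seed)
        plain, _ = train_supervised(spec, sub, dev, cfg, seed=seed)
        cons, _ = train_with_consistency(
            spec, sub, dev,
            AugmentationConfig(P=10, seed=seed),
            ConsistencyWeights(alpha=1.0, beta=10.0),
            cfg, seed=seed,
        )
        ap.append(plain.accuracy(test))
        ac.append(cons.accuracy(test))
        dp.append(permutation_divergence(plain, test, seed=seed))
        dc.append(permutation_divergence(cons, test, seed=seed))
    return ConsistencyOutcome(tuple(ap), tuple(ac), tuple(dp), tuple(dc))


@dataclass(frozen=True)
class PromptOutcome:
    acc_prompt: tuple[float, ...]
    acc_head_only: tuple[float, ...]

    @property
    def mean_acc_prompt(self) -> float:
        return float(np.mean(self.acc_prompt))

    @property
    def mean_acc_head_only(self) -> float:
        return float(np.mean(self.acc_head_only))


def prompt_comparison(
    base_seed: int = 0,
    seeds: tuple[int, ...] = (0, 1, 2),
    n_shots: int = 100,
    pretrain_batches: int = 300,
    prompt_batches: int = 200,
) -> PromptOutcome:
    """Prompt fine-tuning vs a head-only fit of the same frozen encoder.

    Per seed, one tiny masked LM is briefly pretrained on the unlabeled
    training conclusions; a snapshot of that state serves both arms, so
    the comparison isolates the effect of the training method on the same
    encoder and the same labeled 100-report sample.
    """
    train, dev, test = experiment_corpus(base_seed + 3)
    spec = PromptSpec()
    accs_p, accs_h = [], []
    for seed in seeds:
        mlm = TinyMaskedLM.build(train.texts(), vocab_cap=2000, seed=seed)
        k = default_label_span(spec, mlm.tokenizer)
        pretrain_mlm(mlm, train.texts(), n_batches=pretrain_batches, seed=seed)
        pretrained_state = mlm.state()
        sub = few_shot_sample(train, n_shots, seed=seed)

        cfg = PromptTrainConfig(num_batches=prompt_batches, learning_rate=1e-3,
                                eval_every=20, batch_size=16, seed=seed)
        mlm, _ = train_prompt(mlm, sub, dev, spec, cfg)
        accs_p.append(_prompt_accuracy(mlm, test, spec, k))

        mlm.load_state(pretrained_state)
        predict = train_head_only(mlm, sub, dev, cfg, seed=seed)
        accs_h.append(evaluate(predict(test.texts()), test.labels()).accuracy)
    return PromptOutcome(tuple(accs_p), tuple(accs_h))
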