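"""Conventional machine-learning baselines over TF-IDF features.

Bag-of-words featurization makes every model here exactly invariant to
sentence order, which is what lets these baselines double as an oracle for
the label-preservation claim behind permutation augmentation.  Kinds:

- ``linear_max_margin``: linear SVM with Platt-calibrated probabilities,
- ``logistic``: multinomial logistic regression,
- ``gradient_boosted_trees``: XGBoost,
- ``soft_vote_ensemble``: unweighted probability average of the three.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .corpus import N_CLASSES, ResponseLabel

__all__ = [
    "BowFeaturizerConfig",
    "ClassicalModel",
    "CLASSICAL_KINDS",
    "fit_featurizer",
    "train_classical",
    "soft_vote",
]

CLASSICAL_KINDS = (
    "linear_max_margin",
    "logistic",
    "gradient_boosted_trees",
    "soft_vote_ensemble",
)


@dataclass(frozen=True)
class BowFeaturizerConfig:
    ngram_range: tuple[int, int] = (1, 2)
    min_document_frequency: int = 2
    lowercase: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.ngram_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid ngram_range {self.ngram_range}")
        if self.min_document_frequency < 1:
            raise ValueError("min_document_frequency must be >= 1")


class SentenceBoundedNgramAnalyzer:
    """Emit word n-grams within sentences only.

    Keeping n-grams from crossing sentence boundaries makes the bag of
    features exactly invariant to sentence order, which is the property the
    classical models contribute as an oracle for permutation augmentation.
    """

    def __init__(self, config: BowFeaturizerConfig):
        self.config = config

    def __call__(self, text: str) -> list[str]:
        from .augmentation import split_sentences
        from .tokenizer import word_tokenize

        lo, hi = self.config.ngram_range
        grams: list[str] = []
        for sentence in split_sentences(text):
            toks = word_tokenize(sentence, lowercase=self.config.lowercase)
            toks = [t for t in toks if any(c.isalnum() for c in t)]
            for n in range(lo, hi + 1):
                grams.extend(
                    " ".join(toks[i: i + n]) for i in range(len(toks) - n + 1)
                )
        return grams


def fit_featurizer(
    texts: Sequence[str], config: BowFeaturizerConfig = BowFeaturizerConfig()
) -> TfidfVectorizer:
    """Fit a TF-IDF featurizer; transforms are sentence-order invariant."""
    if len(texts) < 2:
        raise ValueError("need at least 2 training documents")
    vec = TfidfVectorizer(
        analyzer=SentenceBoundedNgramAnalyzer(config),
        min_df=config.min_document_frequency,
    )
    vec.fit(texts)
    return vec


def _base_estimator(kind: str, seed: int):
    if kind == "linear_max_margin":
        # Platt-style sigmoid calibration on internal folds turns margin
        # scores into the probabilities the soft vote needs.
        return CalibratedClassifierCV(
            LinearSVC(random_state=seed), method="sigmoid", cv=3
        )
    if kind == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if kind == "gradient_boosted_trees":
        return XGBClassifier(
            n_estimators=200,
            max_depth=6,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
    raise ValueError(f"unknown classical kind {kind!r}")


class ClassicalModel:
    """A fitted featurizer plus one or three fitted estimators."""

    def __init__(self, kind: str, featurizer: TfidfVectorizer, estimators: list):
        if kind not in CLASSICAL_KINDS:
            raise ValueError(f"unknown classical kind {kind!r}")
        self.kind = kind
        self.featurizer = featurizer
        self.estimators = estimators

    def _member_proba(self, est, X) -> np.ndarray:
        raw = est.predict_proba(X)
        # map onto the full 4-class simplex even if a class was absent
        out = np.zeros((raw.shape[0], N_CLASSES))
        for j, cls in enumerate(est.classes_):
            out[:, int(cls)] = raw[:, j]
        return out

    def predict_proba(self, texts: "str | Sequence[str]") -> np.ndarray:
        single = isinstance(texts, str)
        if single:
            texts = [texts]
        X = self.featurizer.transform(texts)
        probas = np.mean([self._member_proba(e, X) for e in self.estimators], axis=0)
        probas = probas / probas.sum(axis=1, keepdims=True)
        return probas[0] if single else probas

    def predict(self, texts: "str | Sequence[str]"):
        p = self.predict_proba(texts)
        if p.ndim == 1:
            return ResponseLabel(int(np.argmax(p)))
        return [ResponseLabel(int(i)) for i in np.argmax(p, axis=1)]

    def save(self, path: "str | Path") -> None:
        joblib.dump({"version": 1, "kind": self.kind,
                     "featurizer": self.featurizer,
                     "estimators": self.estimators}, path)

    @classmethod
    def load(cls, path: "str | Path") -> "ClassicalModel":
        obj = joblib.load(path)
        return cls(obj["kind"], obj["featurizer"], obj["estimators"])


def train_classical(
    kind: str,
    texts: Sequence[str],
    labels: Sequence[ResponseLabel],
    seed: int = 0,
    featurizer_config: BowFeaturizerConfig = BowFeaturizerConfig(),
) -> ClassicalModel:
    """Fit one classical model (or the three-member soft-vote ensemble)."""
    if len(set(int(l) for l in labels)) < 2:
        raise ValueError("training set contains a single class")
    featurizer = fit_featurizer(texts, featurizer_config)
    X = featurizer.transform(texts)
    y = np.asarray([int(l) for l in labels])
    kinds = (
        ["logistic", "gradient_boosted_trees", "linear_max_margin"]
        if kind == "soft_vote_ensemble"
        else [kind]
    )
    estimators = []
    for k in kinds:
        est = _base_estimator(k, seed)
        est.fit(X, y)
        estimators.append(est)
    return ClassicalModel(kind, featurizer, estimators)


def soft_vote(models: Sequence[ClassicalModel], text: str) -> np.ndarray:
    """Unweighted mean of member label distributions for one text."""
    if len(models) == 0:
        raise ValueError("soft_vote: empty model list")
    return np.mean([m.predict_proba(text) for m in models], axis=0)
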