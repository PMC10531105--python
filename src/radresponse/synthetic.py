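"""Synthetic radiology-conclusion corpus generator.

Emulates the statistical structure the downstream methods rely on: multi-
sentence conclusion texts whose sentences are order-exchangeable, about six
reports per patient, four-class marginals close to the real-data class
distribution (39.0 / 11.4 / 14.4 / 35.2 percent for NED / PR / SD / PD), and
class-determining lexical cues mixed with label-neutral distractor sentences.

Each sentence is drawn from a role-tagged template bank; the record's label
is produced by a deterministic, order-free oracle over the multiset of
sentence roles, standing in for the consensus annotation guidelines used by
human curators.  The oracle precedence is: any growth or new lesion -> PD;
else any shrinkage -> PR; else any stable finding -> SD; else NED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus import Corpus, ReportRecord, ResponseLabel

__all__ = [
    "GeneratorConfig",
    "ROLE_VOCABULARY",
    "oracle_label",
    "generate_corpus",
    "generate_corpus_with_roles",
    "inject_annotation_noise",
]

ROLE_VOCABULARY = (
    "ned_statement",
    "shrink",
    "stable",
    "growth",
    "new_lesion",
    "benign",
    "distractor",
)

DEFAULT_MARGINALS = (0.390, 0.114, 0.144, 0.352)

SITES = (
    "liver", "right lung", "left lower lobe", "right upper lobe", "pelvis",
    "mediastinum", "peritoneum", "retroperitoneum", "thoracic spine",
    "left adrenal gland", "pancreas", "cervical region", "omentum",
    "right iliac fossa", "para-aortic region", "lung bases",
)

LESIONS = (
    "nodule", "mass", "lesion", "lymph node", "metastasis",
    "deposit", "opacity", "soft tissue lesion",
)

# Template bank: >= 8 patterns per role so bag-of-words baselines cannot
# memorize a single string per class.  Slots: {site}, {lesion}, {cur}, {prior}.
TEMPLATES: dict[str, tuple[str, ...]] = {
    "ned_statement": (
        "No evidence of disease recurrence.",
        "No suspicious {lesion} identified in the {site}.",
        "No radiological evidence of residual tumour.",
        "No measurable disease is demonstrated on the current study.",
        "No new or residual {lesion} seen in the {site}.",
        "The previously treated site shows no evidence of viable tumour.",
        "No metastatic disease is identified.",
        "Scan shows complete resolution of the previously noted {lesion}.",
        "No abnormal enhancement to suggest recurrent disease.",
    ),
    "shrink": (
        "The {site} {lesion} has decreased in size from {prior} cm to {cur} cm.",
        "Interval reduction of the {lesion} in the {site}, now measuring {cur} cm (previously {prior} cm).",
        "The dominant {lesion} in the {site} is smaller, {cur} cm versus {prior} cm before.",
        "Partial regression of the {site} {lesion}, currently {cur} cm compared with {prior} cm.",
        "There is interval shrinkage of the {lesion} within the {site} from {prior} cm to {cur} cm.",
        "The {lesion} at the {site} shows treatment response, decreasing to {cur} cm from {prior} cm.",
        "Marked interval decrease of the {site} {lesion}, measuring {cur} cm, previously {prior} cm.",
        "Reduced size of the known {lesion} in the {site}: {cur} cm, prior {prior} cm.",
    ),
    "stable": (
        "The {site} {lesion} is stable, measuring {cur} cm as before.",
        "Stable appearance of the {lesion} in the {site} at {cur} cm.",
        "No significant interval change in the {site} {lesion} ({cur} cm).",
        "The known {lesion} within the {site} is unchanged, {cur} cm.",
        "Stable {cur} cm {lesion} at the {site}.",
        "The {site} {lesion} remains similar in size at {cur} cm.",
        "Unchanged {lesion} in the {site}, again measuring {cur} cm.",
        "The previously described {site} {lesion} shows no interval change, {cur} cm.",
    ),
    "growth": (
        "The {site} {lesion} has increased in size from {prior} cm to {cur} cm.",
        "Interval enlargement of the {lesion} in the {site}, now {cur} cm (previously {prior} cm).",
        "Progression of the dominant {lesion} at the {site}, measuring {cur} cm versus {prior} cm.",
        "The {lesion} in the {site} has grown to {cur} cm from {prior} cm.",
        "Worsening of the {site} {lesion}, which now measures {cur} cm, prior {prior} cm.",
        "There is interval increase of the {lesion} within the {site} from {prior} cm to {cur} cm.",
        "Enlarging {lesion} at the {site}: {cur} cm, previously {prior} cm.",
        "The known {site} {lesion} demonstrates interval growth to {cur} cm from {prior} cm.",
    ),
    "new_lesion": (
        "New {cur} cm {lesion} in the {site}, suspicious for metastasis.",
        "A new {lesion} has appeared in the {site}, measuring {cur} cm.",
        "Interval development of a {cur} cm {lesion} at the {site}.",
        "New focus of disease in the {site}: a {cur} cm {lesion}.",
        "There is a newly apparent {lesion} within the {site} ({cur} cm).",
        "New metastatic {lesion} involving the {site}, {cur} cm.",
        "Development of a new {cur} cm {lesion} in the {site} since the prior study.",
        "A previously unseen {lesion} is now present in the {site}, measuring {cur} cm.",
    ),
    "benign": (
        "Simple renal cyst, unchanged.",
        "Cholelithiasis without cholecystitis.",
        "Degenerative changes of the lumbar spine.",
        "Small hiatal hernia, incidental.",
        "Atherosclerotic calcification of the abdominal aorta.",
        "Benign-appearing hepatic haemangioma in the {site}.",
        "Diverticulosis of the sigmoid colon without diverticulitis.",
        "Incidental {cur} cm simple cyst in the {site}.",
        "Prostatic enlargement, incidental note.",
    ),
    "distractor": (
        "The visualised bones show no aggressive osseous change.",
        "No pleural effusion or pneumothorax.",
        "The adrenal glands are unremarkable.",
        "No free fluid or free gas in the abdomen.",
        "Surgical clips are noted in the {site}.",
        "Mild dependent atelectasis at the lung bases.",
        "The visualised bowel loops are within normal limits.",
        "No hydronephrosis bilaterally.",
        "Comparison is made with the prior study.",
        "Port-a-cath in situ with tip in the superior vena cava.",
    ),
}

# Hedging phrasing is label-neutral by construction: it is attached only to
# distractor sentences, never to the class-determining ones.
HEDGES = (
    "Findings are likely benign.",
    "Appearances are suspicious for post-treatment change rather than disease.",
    "This is probably of no clinical significance.",
    "Correlation with clinical findings is suggested.",
    "Appearances likely represent post-surgical change.",
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 200
    mean_reports_per_patient: float = 6.0
    class_marginals: tuple[float, float, float, float] = DEFAULT_MARGINALS
    distractor_range: tuple[int, int] = (0, 3)
    hedging_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.mean_reports_per_patient < 1:
            raise ValueError("mean_reports_per_patient must be >= 1")
        m = self.class_marginals
        if len(m) != 4 or any(x < 0 for x in m) or abs(sum(m) - 1.0) > 1e-6:
            raise ValueError(f"class_marginals must be a probability 4-vector, got {m}")
        lo, hi = self.distractor_range
        if not (0 <= lo <= hi):
            raise ValueError(f"invalid distractor_range {self.distractor_range}")
        if not (0.0 <= self.hedging_prob <= 1.0):
            raise ValueError(f"hedging_prob must be in [0,1], got {self.hedging_prob}")


def oracle_label(roles: Iterable[str]) -> ResponseLabel:
    """Order-free label oracle over the multiset of sentence roles.

    Precedence: growth/new lesion -> PD; else shrink -> PR; else stable -> SD;
    else NED.  Depends only on the multiset, so it is permutation-invariant.
    """
    roles = list(roles)
    unknown = [r for r in roles if r not in ROLE_VOCABULARY]
    if unknown:
        raise ValueError(f"unknown sentence role(s): {unknown}")
    role_set = set(roles)
    if role_set & {"growth", "new_lesion"}:
        return ResponseLabel.PD
    if "shrink" in role_set:
        return ResponseLabel.PR
    if "stable" in role_set:
        return ResponseLabel.SD
    return ResponseLabel.NED


def _fill(rng: np.random.Generator, pattern: str, role: str) -> str:
    site = SITES[rng.integers(len(SITES))]
    lesion = LESIONS[rng.integers(len(LESIONS))]
    prior = round(float(rng.uniform(1.2, 6.0)), 1)
    if role == "shrink":
        cur = round(prior * float(rng.uniform(0.35, 0.7)), 1)
    elif role == "growth":
        cur = round(prior * float(rng.uniform(1.3, 2.2)), 1)
    else:
        cur = round(prior + float(rng.uniform(-0.1, 0.1)), 1)
    cur = max(cur, 0.3)
    return pattern.format(site=site, lesion=lesion, cur=cur, prior=prior)


def _sentence(rng: np.random.Generator, role: str) -> str:
    bank = TEMPLATES[role]
    return _fill(rng, bank[rng.integers(len(bank))], role)


def _roles_for_label(rng: np.random.Generator, label: ResponseLabel) -> list[str]:
    """Compose a role multiset whose oracle label is exactly `label`."""
    roles: list[str] = []
    if label == ResponseLabel.PD:
        roles += list(rng.choice(["growth", "new_lesion"],
                                 size=int(rng.integers(1, 3)), replace=True))
        if rng.random() < 0.30:
            roles.append("stable")
        if rng.random() < 0.15:  # mixed response still reads as progression
            roles.append("shrink")
    elif label == ResponseLabel.PR:
        roles += ["shrink"] * int(rng.integers(1, 3))
        if rng.random() < 0.40:
            roles.append("stable")
    elif label == ResponseLabel.SD:
        roles += ["stable"] * int(rng.integers(1, 3))
    else:  # NED: no measurable-disease roles at all
        roles += ["ned_statement"] * int(rng.integers(1, 3))
        if rng.random() < 0.5:
            roles.append("benign")
    return roles


def generate_corpus_with_roles(
    config: GeneratorConfig,
) -> tuple[Corpus, dict[str, list[str]]]:
    """Generate a corpus plus the role multiset behind each record.

    The target label is sampled first from the configured marginals and a
    consistent role multiset is composed for it (rejection-free), so the
    empirical class proportions converge to the marginals as the corpus
    grows.  Reports per patient follow 1 + Poisson(mean - 1).
    """
    rng = np.random.default_rng(config.seed)
    records: list[ReportRecord] = []
    roles_by_id: dict[str, list[str]] = {}
    marginals = np.asarray(config.class_marginals, dtype=float)
    marginals = marginals / marginals.sum()
    rid = 0
    for p in range(config.n_patients):
        patient_id = f"P{p:05d}"
        n_reports = 1 + int(rng.poisson(config.mean_reports_per_patient - 1.0))
        for _ in range(n_reports):
            label = ResponseLabel(int(rng.choice(4, p=marginals)))
            roles = _roles_for_label(rng, label)
            lo, hi = config.distractor_range
            roles += ["distractor"] * int(rng.integers(lo, hi + 1))
            if len(roles) == 1:
                # multi-region CT conclusions essentially always contain
                # several statements; a second sentence also guarantees that
                # permutation augmentation applies to every record
                roles.append("distractor")
            rng.shuffle(roles)
            sentences = [_sentence(rng, role) for role in roles]
            if rng.random() < config.hedging_prob:
                k = int(rng.integers(0, len(sentences) + 1))
                sentences.insert(k, HEDGES[rng.integers(len(HEDGES))])
                roles.insert(k, "distractor")
            report_id = f"R{rid:06d}"
            rid += 1
            records.append(
                ReportRecord(
                    report_id=report_id,
                    patient_id=patient_id,
                    conclusion_text=" ".join(sentences),
                    label=oracle_label(roles),
                    provenance="synthetic",
                )
            )
            roles_by_id[report_id] = roles
    return Corpus(records), roles_by_id


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a labeled synthetic corpus (see generate_corpus_with_roles)."""
    corpus, _ = generate_corpus_with_roles(config)
    return corpus


def inject_annotation_noise(
    corpus: Corpus,
    flip_prob: float,
    confusion: "np.ndarray | Sequence[Sequence[float]]",
    seed: int = 0,
) -> tuple[list[ResponseLabel], list[ResponseLabel]]:
    """Simulate a second annotator by perturbing gold labels.

    With probability ``flip_prob`` a record's label is redrawn from the
    row of the (row-stochastic) confusion matrix indexed by its gold label;
    otherwise it is kept.  Returns (gold, noisy) label lists for downstream
    agreement statistics.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (4, 4) or np.any(confusion < 0):
        raise ValueError(f"confusion must be a non-negative 4x4 matrix")
    if not np.allclose(confusion.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("confusion matrix rows must sum to 1")
    if not (0.0 <= flip_prob <= 1.0):
        raise ValueError(f"flip_prob must be in [0,1], got {flip_prob}")
    rng = np.random.default_rng(seed)
    gold = [r.label for r in corpus]
    noisy: list[ResponseLabel] = []
    for lab in gold:
        if rng.random() < flip_prob:
            noisy.append(ResponseLabel(int(rng.choice(4, p=confusion[int(lab)]))))
        else:
            noisy.append(lab)
    return gold, noisy
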