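"""Semiautomated literature triage for penetrance/prevalence abstracts.

Uncertain gene-disease associations are checked against the literature.  The
stage has two parts:

* **Query building** — deterministic boolean PubMed-style query strings from
  gene and disease term lists, emitted offline (no retrieval is performed).
* **Abstract classification** — a linear support-vector classifier over
  bag-of-token features (unigrams + bigrams, sublinear tf-idf weighting,
  one-vs-rest) assigning each abstract to one of four classes: relevant to
  PENETRANCE, PREVALENCE, BOTH, or NEITHER.  Abstracts classified as
  relevant (by default any of the first three classes) form the candidate
  study set handed to adjudication.

Tokenization is deliberately simple and dependency-light: lowercase, split
on non-alphanumerics, drop single-character tokens, no stemming.  An
abstract whose text is entirely out-of-vocabulary yields a zero feature
vector and falls to the NEITHER class by convention.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.svm import LinearSVC

__all__ = [
    "TriageLabel",
    "AbstractRecord",
    "QuerySpec",
    "TriageModel",
    "TriageMetrics",
    "RELEVANT_LABELS",
    "build_query",
    "tokenize",
    "train_triage",
    "triage_abstracts",
    "evaluate_triage",
    "read_abstracts_jsonl",
    "write_abstracts_jsonl",
    "read_abstracts_csv",
]


class TriageLabel(enum.Enum):
    PENETRANCE = "PENETRANCE"
    PREVALENCE = "PREVALENCE"
    BOTH = "BOTH"
    NEITHER = "NEITHER"


#: Classes treated as relevant for downstream penetrance review.  The class
#: scheme includes prevalence, so the inclusive reading is the default;
#: pass ``relevant=(TriageLabel.PENETRANCE, TriageLabel.BOTH)`` to
#: :func:`triage_abstracts` for the strict reading.
RELEVANT_LABELS: tuple[TriageLabel, ...] = (
    TriageLabel.PENETRANCE,
    TriageLabel.PREVALENCE,
    TriageLabel.BOTH,
)


@dataclass(frozen=True)
class AbstractRecord:
    """One citation: identifier, title, abstract body, optional gold label."""

    id: str
    title: str = ""
    text: str = ""
    label: TriageLabel | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("abstract id must be non-empty")
        if self.label is not None and not (self.title or self.text):
            raise ValueError(f"labelled record {self.id!r} has neither title nor text")

    @property
    def content(self) -> str:
        return f"{self.title} {self.text}".strip()


@dataclass(frozen=True)
class QuerySpec:
    """Gene and disease term lists for a boolean literature query."""

    gene_terms: tuple[str, ...]
    disease_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_terms", tuple(self.gene_terms))
        object.__setattr__(self, "disease_terms", tuple(self.disease_terms))
        if not self.gene_terms or not self.disease_terms:
            raise ValueError("gene_terms and disease_terms must both be non-empty")
        if any(not t.strip() for t in self.gene_terms + self.disease_terms):
            raise ValueError("query terms must be non-blank")


def _render_term(term: str) -> str:
    term = term.strip()
    return f'"{term}"' if " " in term else term


def build_query(spec: QuerySpec) -> str:
    """Render ``(g1 OR g2 ...) AND (d1 OR d2 ...)``, quoting multi-word terms."""
    genes = " OR ".join(_render_term(t) for t in spec.gene_terms)
    diseases = " OR ".join(_render_term(t) for t in spec.disease_terms)
    return f"({genes}) AND ({diseases})"


_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop length-1 tokens."""
    return [tok for tok in _TOKEN_RE.split(text.lower()) if len(tok) > 1]


@dataclass
class TriageModel:
    """A trained abstract classifier.

    Wraps the fitted vectorizer and one-vs-rest linear SVM together with the
    hyperparameters and seed used for training.  Prediction is deterministic
    given fixed weights.
    """

    vectorizer: TfidfVectorizer
    classifier: LinearSVC
    hyperparameters: dict
    seed: int

    @property
    def vocabulary(self) -> Mapping[str, int]:
        return self.vectorizer.vocabulary_

    @property
    def weights(self) -> np.ndarray:
        """Per-class linear coefficients, rows aligned with ``classes``."""
        return self.classifier.coef_

    @property
    def classes(self) -> list[TriageLabel]:
        return [TriageLabel(c) for c in self.classifier.classes_]

    def predict(self, records: Sequence[AbstractRecord]) -> list[TriageLabel]:
        if not records:
            return []
        X = self.vectorizer.transform([r.content for r in records])
        nonzero = np.asarray((X != 0).sum(axis=1)).ravel() > 0
        labels = [TriageLabel.NEITHER] * len(records)
        if nonzero.any():
            predicted = self.classifier.predict(X[nonzero])
            for idx, raw in zip(np.flatnonzero(nonzero), predicted):
                labels[idx] = TriageLabel(raw)
        return labels


def train_triage(
    corpus: Sequence[AbstractRecord],
    *,
    C: float = 1.0,
    ngram_range: tuple[int, int] = (1, 2),
    seed: int = 0,
) -> TriageModel:
    """Train the one-vs-rest linear SVM abstract classifier.

    Features are sublinear tf-idf counts of unigrams and bigrams from the
    concatenated title and abstract text.  All records must be labelled and
    the corpus must contain at least two classes.
    """
    unlabelled = [r.id for r in corpus if r.label is None]
    if unlabelled:
        raise ValueError(f"training corpus contains unlabelled records: {unlabelled[:5]}")
    labels = [r.label.value for r in corpus]
    if len(set(labels)) < 2:
        raise ValueError("training corpus must contain at least two classes")
    vectorizer = TfidfVectorizer(
        tokenizer=tokenize,
        preprocessor=lambda s: s,
        token_pattern=None,
        lowercase=False,
        ngram_range=ngram_range,
        sublinear_tf=True,
    )
    X = vectorizer.fit_transform([r.content for r in corpus])
    classifier = LinearSVC(C=C, random_state=seed)
    classifier.fit(X, labels)
    return TriageModel(
        vectorizer=vectorizer,
        classifier=classifier,
        hyperparameters={"C": C, "ngram_range": ngram_range},
        seed=seed,
    )


def triage_abstracts(
    model: TriageModel,
    records: Sequence[AbstractRecord],
    relevant: Sequence[TriageLabel] = RELEVANT_LABELS,
) -> tuple[list[TriageLabel], list[AbstractRecord]]:
    """Label records and extract the relevant subset, order-preserving."""
    labels = model.predict(records)
    relevant_set = set(relevant)
    subset = [rec for rec, lab in zip(records, labels) if lab in relevant_set]
    return labels, subset


@dataclass(frozen=True)
class TriageMetrics:
    """Per-class one-vs-rest metrics plus the raw 4x4 confusion matrix.

    ``sensitivity[c]`` is TP/(TP+FN) and ``specificity[c]`` is TN/(TN+FP);
    a metric whose denominator is zero (class absent from the held-out set)
    is ``None`` — undefined, not zero.
    """

    confusion: pd.DataFrame
    sensitivity: Mapping[TriageLabel, float | None]
    specificity: Mapping[TriageLabel, float | None]
    accuracy: float


def evaluate_triage(
    model: TriageModel, heldout: Sequence[AbstractRecord]
) -> TriageMetrics:
    """Evaluate on labelled held-out records."""
    if not heldout:
        raise ValueError("held-out set is empty")
    if any(r.label is None for r in heldout):
        raise ValueError("held-out records must be labelled")
    truth = [r.label for r in heldout]
    predicted = model.predict(heldout)
    order = list(TriageLabel)
    confusion = pd.DataFrame(
        0, index=[l.value for l in order], columns=[l.value for l in order], dtype=int
    )
    for t, p in zip(truth, predicted):
        confusion.loc[t.value, p.value] += 1

    sensitivity: dict[TriageLabel, float | None] = {}
    specificity: dict[TriageLabel, float | None] = {}
    total = len(heldout)
    for label in order:
        tp = int(confusion.loc[label.value, label.value])
        fn = int(confusion.loc[label.value].sum()) - tp
        fp = int(confusion[label.value].sum()) - tp
        tn = total - tp - fn - fp
        sensitivity[label] = tp / (tp + fn) if (tp + fn) else None
        specificity[label] = tn / (tn + fp) if (tn + fp) else None
    accuracy = sum(t is p for t, p in zip(truth, predicted)) / total
    return TriageMetrics(confusion, sensitivity, specificity, accuracy)


# ---------------------------------------------------------------------------
# Corpus I/O: JSON lines (one record per line) or CSV
# ---------------------------------------------------------------------------

def _record_from_mapping(data: dict) -> AbstractRecord:
    label = data.get("label")
    return AbstractRecord(
        id=str(data["id"]),
        title=str(data.get("title", "") or ""),
        text=str(data.get("text", "") or ""),
        label=TriageLabel(str(label).upper()) if label else None,
    )


def read_abstracts_jsonl(path: str | Path) -> list[AbstractRecord]:
    records = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line:
                records.append(_record_from_mapping(json.loads(line)))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate abstract ids in {path}")
    return records


def write_abstracts_jsonl(records: Iterable[AbstractRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for record in records:
            handle.write(
                json.dumps(
                    {
                        "id": record.id,
                        "title": record.title,
                        "text": record.text,
                        "label": record.label.value if record.label else None,
                    }
                )
                + "\n"
            )


def read_abstracts_csv(path: str | Path) -> list[AbstractRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"id", "title", "text"} - set(frame.columns)
    if missing:
        raise ValueError(f"abstract table {path} missing columns: {sorted(missing)}")
    return [_record_from_mapping(dict(row)) for _, row in frame.iterrows()]
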