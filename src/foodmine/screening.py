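"""Corpus screening: vocabulary text-matching and supervised relevance ranking.

The first stage scans each entry's MeSH terms and abstract for terms from
three controlled vocabularies (biochemicals, foods, measurement
methodologies) and keeps entries satisfying a configurable boolean rule. The
packaged vocabularies are reconstructions assembled for this implementation,
not the original supplementary lists.

The second stage trains a supervised model on curated three-way labels
(not_useful / quantified / unquantified, collapsed to useful-vs-not) over
n-gram count features, balancing the minority class with SMOTE before
fitting, and ranks unseen papers by predicted relevance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, precision_score, recall_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .corpus import BibEntry, Corpus

__all__ = [
    "Vocabulary",
    "MatchRule",
    "FilterDecision",
    "CurationLabel",
    "NGramSpec",
    "RelevanceModel",
    "apply_filter",
    "featurize",
    "smote_balance",
    "train_and_eval",
    "rank",
]

LabelName = Literal["not_useful", "quantified", "unquantified"]
USEFUL_LABELS = frozenset({"quantified", "unquantified"})

_TOKEN = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens; word boundaries prevent substring matches
    (e.g. the food term "tea" never matches inside "instead")."""
    return [t.lower() for t in _TOKEN.findall(text)]


@dataclass(frozen=True)
class Vocabulary:
    """Three term sets used by the text-matching filter; all terms lowercase.

    Multi-word terms are matched as contiguous token sequences.
    """

    chemical_terms: frozenset[str]
    food_terms: frozenset[str]
    method_terms: frozenset[str]

    @classmethod
    def load(cls, directory: str | Path | None = None) -> "Vocabulary":
        """Load from three one-term-per-line files, or the packaged defaults."""
        def read(name: str) -> frozenset[str]:
            if directory is None:
                text = (resources.files("foodmine.data") / name).read_text("utf-8")
            else:
                text = (Path(directory) / name).read_text("utf-8")
            return frozenset(
                line.strip().lower() for line in text.splitlines() if line.strip()
            )

        return cls(
            chemical_terms=read("vocab_chemical.txt"),
            food_terms=read("vocab_food.txt"),
            method_terms=read("vocab_method.txt"),
        )

    def category(self, name: str) -> frozenset[str]:
        return {
            "chemical": self.chemical_terms,
            "food": self.food_terms,
            "method": self.method_terms,
        }[name]


@dataclass(frozen=True)
class MatchRule:
    """Boolean pass rule over matched vocabulary categories.

    The default — at least one food term AND at least one chemical-or-method
    term, searched in MeSH terms and abstract — approximates the original
    filter; the exact boolean lived in supplementary material and is
    configurable here.
    """

    require_food: bool = True
    require_chemical_or_method: bool = True
    fields: tuple[str, ...] = ("mesh", "abstract")

    def passes(self, matched: dict[str, list[str]]) -> bool:
        ok = True
        if self.require_food:
            ok = ok and bool(matched.get("food"))
        if self.require_chemical_or_method:
            ok = ok and bool(matched.get("chemical") or matched.get("method"))
        return ok


@dataclass
class FilterDecision:
    entry_id: str
    matched: dict[str, list[str]]
    passed: bool


@dataclass(frozen=True)
class CurationLabel:
    """Human curation outcome for one paper; exactly one label per entry."""

    entry_id: str
    label: LabelName

    @property
    def useful(self) -> bool:
        return self.label in USEFUL_LABELS


def _entry_tokens(entry: BibEntry, fields: Sequence[str]) -> list[str]:
    tokens: list[str] = []
    for f in fields:
        if f == "abstract":
            tokens.extend(tokenize(entry.abstract))
        elif f == "title":
            tokens.extend(tokenize(entry.title))
        elif f == "mesh":
            for term in entry.mesh_terms:
                tokens.extend(tokenize(term))
        else:
            raise ValueError(f"unknown match field {f!r}")
    return tokens


def _match_terms(tokens: list[str], terms: Iterable[str]) -> list[str]:
    token_set = set(tokens)
    hits = []
    for term in sorted(terms):
        term_tokens = tuple(tokenize(term))
        if not term_tokens:
            continue
        if len(term_tokens) == 1:
            if term_tokens[0] in token_set:
                hits.append(term)
            continue
        n = len(term_tokens)
        if any(tuple(tokens[i:i + n]) == term_tokens
               for i in range(len(tokens) - n + 1)):
            hits.append(term)
    return hits


def apply_filter(corpus: Corpus, vocab: Vocabulary,
                 rule: MatchRule | None = None) -> list[FilterDecision]:
    """One decision per entry; case-insensitive, token-boundary-aware matching.

    Decisions depend only on the entry and the rule, never on corpus order.
    """
    rule = rule or MatchRule()
    if not (vocab.chemical_terms and vocab.food_terms and vocab.method_terms):
        raise ValueError("filter enabled with an empty vocabulary category")
    decisions = []
    for entry in corpus.entries:
        tokens = _entry_tokens(entry, rule.fields)
        matched = {
            cat: _match_terms(tokens, vocab.category(cat))
            for cat in ("chemical", "food", "method")
        }
        matched = {k: v for k, v in matched.items() if v}
        decisions.append(
            FilterDecision(entry_id=entry.entry_id, matched=matched,
                           passed=rule.passes(matched))
        )
    return decisions


@dataclass(frozen=True)
class NGramSpec:
    """n-gram featurization over the concatenated title, abstract and MeSH."""

    ngram_range: tuple[int, int] = (1, 2)
    min_df: int = 2
    fields: tuple[str, ...] = ("title", "abstract", "mesh")


def _entry_text(entry: BibEntry, fields: Sequence[str]) -> str:
    parts = []
    for f in fields:
        if f == "title":
            parts.append(entry.title)
        elif f == "abstract":
            parts.append(entry.abstract)
        elif f == "mesh":
            parts.append(" ".join(entry.mesh_terms))
    return " ".join(p for p in parts if p)


def featurize(entries: Sequence[BibEntry], spec: NGramSpec = NGramSpec(),
              vectorizer: CountVectorizer | None = None):
    """n-gram count matrix with rows aligned to ``entries``.

    When ``vectorizer`` is None a new one is fitted on these entries — callers
    responsible for train/test hygiene fit on the training split only and
    pass the fitted vectorizer back in for transform-only use.
    """
    if len(entries) == 0:
        raise ValueError("cannot featurize an empty corpus")
    texts = [_entry_text(e, spec.fields) for e in entries]
    if vectorizer is None:
        vectorizer = CountVectorizer(ngram_range=spec.ngram_range,
                                     min_df=spec.min_df,
                                     token_pattern=r"(?u)\b\w+\b")
        X = vectorizer.fit_transform(texts)
    else:
        X = vectorizer.transform(texts)
    return X, vectorizer


def smote_balance(X, y, k: int = 5, seed: int = 0):
    """Synthetic Minority Over-sampling: balance binary classes exactly.

    Each synthetic point is ``x + u * (x_nn - x)`` for a random minority point
    ``x``, one of its ``k`` nearest minority neighbours ``x_nn``, and
    ``u ~ U(0, 1)`` — i.e. it lies on the segment between two real minority
    samples. Originals are preserved; output classes have equal counts.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_balance expects exactly two classes")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_needed = int(counts.max() - counts.min())
    minority_mask = y == minority
    X_min = X[minority_mask]
    X_min_dense = np.asarray(X_min.todense()) if sp.issparse(X_min) else np.asarray(X_min, dtype=float)
    n_min = X_min_dense.shape[0]
    if n_min <= k:
        raise ValueError(
            f"minority class has {n_min} samples but k={k} neighbours requested; "
            f"lower k to at most {n_min - 1}"
        )
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min_dense)
    # first neighbour is the point itself
    neighbours = nn.kneighbors(X_min_dense, return_distance=False)[:, 1:]
    base_idx = rng.integers(0, n_min, size=n_needed)
    nb_choice = rng.integers(0, k, size=n_needed)
    gaps = rng.random(n_needed)
    bases = X_min_dense[base_idx]
    nbs = X_min_dense[neighbours[base_idx, nb_choice]]
    synthetic = bases + gaps[:, None] * (nbs - bases)
    if sp.issparse(X):
        X_out = sp.vstack([X, sp.csr_matrix(synthetic)])
    else:
        X_out = np.vstack([np.asarray(X, dtype=float), synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    assert (y_out == minority).sum() == (y_out == majority).sum()
    return X_out, y_out


@dataclass
class RelevanceModel:
    """A fitted relevance classifier with held-out evaluation metrics.

    ``metrics`` (f1, precision, recall for the useful class) are computed on
    the untouched test split only; prediction is deterministic given the
    fitted state.
    """

    feature_spec: NGramSpec
    vectorizer: CountVectorizer
    classifier: LogisticRegression
    train_seed: int
    metrics: dict[str, float] = field(default_factory=dict)

    def scores(self, entries: Sequence[BibEntry]) -> np.ndarray:
        X, _ = featurize(entries, self.feature_spec, vectorizer=self.vectorizer)
        return self.classifier.predict_proba(X)[:, 1]


def train_and_eval(entries: Sequence[BibEntry],
                   labels: Sequence[CurationLabel],
                   spec: NGramSpec = NGramSpec(),
                   split: float = 0.25,
                   seed: int = 0,
                   smote_k: int = 5) -> RelevanceModel:
    """Stratified split, SMOTE on the training split only, fit, evaluate.

    The useful class is {quantified, unquantified}; f1 = 2PR/(P+R) on the
    held-out split. The n-gram vocabulary is fitted on training texts only,
    so no test-set information leaks into the features.
    """
    by_id = {lab.entry_id: lab for lab in labels}
    entries = [e for e in entries if e.entry_id in by_id]
    if not entries:
        raise ValueError("no labelled entries to train on")
    y = np.array([1 if by_id[e.entry_id].useful else 0 for e in entries])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train")
    idx = np.arange(len(entries))
    train_idx, test_idx = train_test_split(
        idx, test_size=split, random_state=seed, stratify=y
    )
    train_entries = [entries[i] for i in train_idx]
    test_entries = [entries[i] for i in test_idx]
    y_train, y_test = y[train_idx], y[test_idx]
    if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
        raise ValueError("a class is absent from one side of the split")
    X_train, vectorizer = featurize(train_entries, spec)
    k = min(smote_k, int(np.bincount(y_train).min()) - 1)
    if k >= 1 and np.bincount(y_train)[0] != np.bincount(y_train)[1]:
        X_train, y_train = smote_balance(X_train, y_train, k=k, seed=seed)
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(X_train, y_train)
    X_test, _ = featurize(test_entries, spec, vectorizer=vectorizer)
    y_pred = clf.predict(X_test)
    metrics = {
        "f1": float(f1_score(y_test, y_pred, zero_division=0)),
        "precision": float(precision_score(y_test, y_pred, zero_division=0)),
        "recall": float(recall_score(y_test, y_pred, zero_division=0)),
    }
    return RelevanceModel(feature_spec=spec, vectorizer=vectorizer,
                          classifier=clf, train_seed=seed, metrics=metrics)


def rank(model: RelevanceModel,
         entries: Sequence[BibEntry]) -> list[tuple[str, float]]:
    """Entries ordered by descending relevance score, ties broken by entry_id."""
    if not isinstance(model, RelevanceModel) or model.classifier is None:
        raise ValueError("model must be a fitted RelevanceModel")
    if not entries:
        return []
    scores = model.scores(entries)
    pairs = [(e.entry_id, float(s)) for e, s in zip(entries, scores)]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))
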