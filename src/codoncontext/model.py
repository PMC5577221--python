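"""Per-amino-acid random-forest codon classifiers and the (w, c) cascade.

For each of the 18 degenerate amino acids, a multi-class random forest (1000
trees by default) maps the feature vector of a peptide window — the
similarity-weighted middle-codon distribution plus per-position average
codon usage of all CSI records matching at cutoff c — to the synonymous
codon observed at the middle position. Models are evaluated by stratified
10-fold cross-validation (pooled out-of-fold accuracy and macro one-vs-rest
AUC) against the high-frequency-codon baseline, and arranged into a priority
cascade: larger windows and higher cutoffs first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .csi import CSIIndex, extract_fragments
from .match import aggregate_features, search
from .profile import CodonFrequencyClass
from .seqio import CodingSequence

logger = logging.getLogger(__name__)

CASCADE_WINDOWS = (7, 5)
CASCADE_CUTOFFS = (1.0, 0.95, 0.9, 0.85, 0.8)


@dataclass
class TrainingSet:
    """Feature rows and observed-codon labels for one amino acid at (w, c)."""

    amino_acid: str
    w: int
    c: float
    X: np.ndarray  # (n_rows, 6 + w)
    y: np.ndarray  # observed middle codons, dtype=str
    corpus_id: str = ""

    def __len__(self) -> int:
        return len(self.y)


class CodonClassifier(ClassifierMixin, BaseEstimator):
    """Multi-class random forest predicting the synonymous codon of one
    amino acid from a window feature vector.

    Parameters
    ----------
    amino_acid, w, c : metadata identifying the classifier's slot in the
        cascade; not used by ``fit``.
    n_trees : number of trees in the forest (default 1000).
    random_state : forest seed; predictions are deterministic under a fixed
        seed.

    Attributes
    ----------
    forest_ : the fitted :class:`~sklearn.ensemble.RandomForestClassifier`.
    classes_ : codon labels in alphabetical order.
    single_class_ : True when the training set contained one codon only
        (degenerate constant classifier; AUC undefined).
    """

    def __init__(
        self,
        amino_acid: str | None = None,
        w: int | None = None,
        c: float | None = None,
        n_trees: int = 1000,
        random_state: int | None = None,
    ):
        self.amino_acid = amino_acid
        self.w = w
        self.c = c
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y) or len(y) == 0:
            raise ValueError("X must be 2-D with one label per row")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state, n_jobs=1
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_  # np.unique order = alphabetical
        self.single_class_ = len(self.classes_) == 1
        if self.single_class_:
            logger.warning(
                "single-class training set for %s (w=%s, c=%s): constant classifier",
                self.amino_acid, self.w, self.c,
            )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))


def make_training_set(
    corpus: Iterable[CodingSequence],
    index: CSIIndex,
    c: float,
) -> dict[str, TrainingSet]:
    """Build per-amino-acid training sets by searching a held-out corpus
    against a CSI built without it.

    One row per window position whose peptide matches ≥1 index record at
    cutoff c; the label is the codon actually used at the middle position.
    Met/Trp positions are skipped. Amino acids without any matched window are
    absent from the result (untrainable at this (w, c)).
    """
    rows: dict[str, list[tuple[np.ndarray, str]]] = {}
    corpus_id = ""
    for cds in corpus:
        corpus_id = corpus_id or cds.id
        for frag in extract_fragments(cds, index.w):
            aa = frag.middle
            if index.code.degeneracy(aa) == 1:
                continue
            matches = search(index, frag.peptide, c)
            if not matches:
                continue
            fv = aggregate_features(matches, index.code)
            rows.setdefault(aa, []).append((np.array(fv.values), frag.middle_codon))
    out = {}
    for aa, pairs in rows.items():
        X = np.vstack([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        out[aa] = TrainingSet(amino_acid=aa, w=index.w, c=c, X=X, y=y,
                              corpus_id=corpus_id)
    return out


def make_training_sets_multi(
    corpus: Iterable[CodingSequence],
    index: CSIIndex,
    cutoffs: Sequence[float],
) -> dict[float, dict[str, TrainingSet]]:
    """Training sets for several cutoffs from a single search pass.

    Searching at the smallest cutoff and filtering matches upward gives
    results identical to calling :func:`make_training_set` per cutoff,
    because the match sets are nested in c.
    """
    c_min = min(cutoffs)
    rows: dict[float, dict[str, list[tuple[np.ndarray, str]]]] = {c: {} for c in cutoffs}
    corpus_id = ""
    for cds in corpus:
        corpus_id = corpus_id or cds.id
        for frag in extract_fragments(cds, index.w):
            aa = frag.middle
            if index.code.degeneracy(aa) == 1:
                continue
            matches = search(index, frag.peptide, c_min)
            if not matches:
                continue
            for c in cutoffs:
                sub = [m for m in matches if m.p >= c] if c > c_min else matches
                if not sub:
                    continue
                fv = aggregate_features(sub, index.code)
                rows[c].setdefault(aa, []).append(
                    (np.array(fv.values), frag.middle_codon)
                )
    out: dict[float, dict[str, TrainingSet]] = {}
    for c, per_aa in rows.items():
        out[c] = {}
        for aa, pairs in per_aa.items():
            out[c][aa] = TrainingSet(
                amino_acid=aa, w=index.w, c=c,
                X=np.vstack([p[0] for p in pairs]),
                y=np.array([p[1] for p in pairs]),
                corpus_id=corpus_id,
            )
    return out


def train(
    training_set: TrainingSet, seed: int | None = None, n_trees: int = 1000
) -> CodonClassifier:
    """Fit a codon classifier on one training set."""
    clf = CodonClassifier(
        amino_acid=training_set.amino_acid,
        w=training_set.w,
        c=training_set.c,
        n_trees=n_trees,
        random_state=seed,
    )
    return clf.fit(training_set.X, training_set.y)


def cross_validate(
    training_set: TrainingSet,
    folds: int = 10,
    seed: int | None = None,
    n_trees: int = 1000,
) -> dict:
    """Pooled out-of-fold accuracy and macro one-vs-rest AUC.

    Folds are stratified by codon label; when some class has fewer members
    than folds, stratification falls back to plain shuffled K-fold with a
    warning. AUC is None for single-class sets.
    """
    X, y = training_set.X, training_set.y
    classes = np.unique(y)
    if len(classes) == 1:
        return {"amino_acid": training_set.amino_acid, "n": len(y),
                "accuracy": 1.0, "auc": None, "folds": folds}
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        warnings.warn(
            f"class with fewer than {folds} members; falling back to plain K-fold"
        )
        splitter = KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=y.dtype)
    proba = np.zeros((len(y), len(classes)))
    col = {c: j for j, c in enumerate(classes)}
    for tr, te in splitter.split(X, y):
        clf = CodonClassifier(
            amino_acid=training_set.amino_acid, w=training_set.w, c=training_set.c,
            n_trees=n_trees, random_state=seed,
        ).fit(X[tr], y[tr])
        pred[te] = clf.predict(X[te])
        p = clf.predict_proba(X[te])
        for j, cls in enumerate(clf.classes_):
            proba[te, col[cls]] = p[:, j]
    accuracy = float(np.mean(pred == y))
    try:
        if len(classes) == 2:
            auc = float(roc_auc_score(y, proba[:, 1]))
        else:
            auc = float(roc_auc_score(y, proba, multi_class="ovr",
                                      average="macro", labels=classes))
    except ValueError:
        auc = None
    return {"amino_acid": training_set.amino_acid, "n": len(y),
            "accuracy": accuracy, "auc": auc, "folds": folds}


def baseline_accuracy(
    training_set: TrainingSet, freq_class: CodonFrequencyClass
) -> float | None:
    """Accuracy of always predicting the high-frequency codon; None if empty."""
    if len(training_set) == 0:
        return None
    high = freq_class.high_codon(training_set.amino_acid)
    return float(np.mean(training_set.y == high))


def coverage(index: CSIIndex, queries: Sequence[str], c: float) -> float:
    """Fraction of query peptides with at least one match at cutoff c."""
    if not queries:
        return 0.0
    hit = sum(1 for q in queries if search(index, q, c))
    return hit / len(queries)


def evaluate(
    training_sets: Mapping[str, TrainingSet],
    freq_class: CodonFrequencyClass,
    folds: int = 10,
    seed: int | None = None,
    n_trees: int = 1000,
) -> pd.DataFrame:
    """Cross-validate every amino acid's training set and tabulate accuracy,
    AUC and the high-frequency-codon baseline (one row per amino acid)."""
    rows = []
    for aa in sorted(training_sets):
        ts = training_sets[aa]
        res = cross_validate(ts, folds=folds, seed=seed, n_trees=n_trees)
        res["baseline"] = baseline_accuracy(ts, freq_class)
        res["w"], res["c"] = ts.w, ts.c
        rows.append(res)
    return pd.DataFrame(rows, columns=["amino_acid", "w", "c", "n",
                                       "accuracy", "auc", "baseline", "folds"])


@dataclass
class ModelCascade:
    """Priority-ordered (w, c) levels of per-amino-acid classifiers.

    Order: w=7 before w=5, and within a window size, cutoffs 1.0 → 0.8. A
    residue is predicted by the first level whose search yields a match —
    and by that level only.
    """

    levels: tuple[tuple[int, float, dict[str, CodonClassifier]], ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("empty model set")

    def __iter__(self):
        return iter(self.levels)

    def __len__(self) -> int:
        return len(self.levels)


def assemble_cascade(
    models: Mapping[tuple[int, float], Mapping[str, CodonClassifier]],
) -> ModelCascade:
    """Arrange trained models into the standard priority order, skipping
    absent (w, c) combinations."""
    levels = []
    for w in CASCADE_WINDOWS:
        for c in CASCADE_CUTOFFS:
            if (w, c) in models:
                levels.append((w, c, dict(models[(w, c)])))
    return ModelCascade(levels=tuple(levels))


def save_cascade(cascade: ModelCascade, path) -> None:
    """Persist a cascade (joblib) with per-model metadata for reproducibility."""
    payload = {
        "format": "codoncontext-cascade-v1",
        "levels": [
            (w, c, models, {aa: {"amino_acid": m.amino_acid, "w": m.w, "c": m.c,
                                 "n_trees": m.n_trees, "seed": m.random_state,
                                 "classes": list(getattr(m, "classes_", []))}
                            for aa, m in models.items()})
            for w, c, models in cascade.levels
        ],
    }
    joblib.dump(payload, path)


def load_cascade(path) -> ModelCascade:
    payload = joblib.load(path)
    if payload.get("format") != "codoncontext-cascade-v1":
        raise ValueError(f"{path}: not a cascade file")
    return ModelCascade(levels=tuple((w, c, models) for w, c, models, _ in payload["levels"]))
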