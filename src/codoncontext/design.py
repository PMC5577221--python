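"""Gene design: emit a nucleotide CDS for a protein using the model cascade.

The designed gene mixes low- and high-frequency codons: the first two codons
use the least frequent synonymous codon (slow translation initiation region),
the last two the high-frequency codon, and every interior position is
assigned by the first cascade level — longest window, highest cutoff first —
whose CSI search yields a match, with the level's classifier choosing the
codon. Positions no level covers fall back to the high-frequency codon (a
configurable policy). The all-high-frequency design is available as a
control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .csi import CSIIndex, build_index
from .match import aggregate_features, search
from .model import (
    CASCADE_CUTOFFS,
    CASCADE_WINDOWS,
    CodonClassifier,
    ModelCascade,
    assemble_cascade,
    make_training_sets_multi,
    train,
)
from .profile import CodonFrequencyClass, CodonUsageTable, classify_frequency, count_usage
from .seqio import STANDARD_AA, CodingSequence, genetic_code, make_cds

FALLBACK_POLICIES = ("high", "low", "sample")


@dataclass(frozen=True)
class PositionReport:
    """Provenance of one designed codon."""

    position: int  # 1-based
    amino_acid: str
    codon: str
    rule: str  # single-codon | first-two-low | last-two-high | cascade | fallback
    w: int | None = None
    c: float | None = None
    n_matches: int = 0
    max_p: float | None = None


@dataclass
class DesignResult:
    protein_id: str
    protein: str
    cds: str  # includes terminal stop codon
    positions: tuple[PositionReport, ...]

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(p.codon for p in self.positions)


def _low_codon(aa: str, usage: CodonUsageTable) -> str:
    """Least frequent synonymous codon; ties broken alphabetically."""
    codons = usage.code.codons_for(aa)
    return min(codons, key=lambda c: (usage.rel_freq.get(c, 0.0), c))


def _check_protein(protein: str, min_len: int = 1) -> None:
    if len(protein) < min_len:
        raise ValueError(f"protein too short to design ({len(protein)} < {min_len} residues)")
    bad = set(protein) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard amino acids in protein: {sorted(bad)}")


def baseline_design(
    protein: str,
    freq_class: CodonFrequencyClass,
    protein_id: str = "design",
    stop_codon: str = "TAA",
) -> CodingSequence:
    """All-high-frequency control design (the conventional optimization that
    replaces every codon with the host's preferred one)."""
    _check_protein(protein)
    nt = "".join(freq_class.high_codon(aa) for aa in protein) + stop_codon
    return make_cds(protein_id, nt, code=freq_class.code)


def design_gene(
    protein: str,
    cascade: ModelCascade | None,
    indexes: Mapping[int, CSIIndex],
    usage: CodonUsageTable,
    freq_class: CodonFrequencyClass,
    protein_id: str = "design",
    fallback: str = "high",
    stop_codon: str = "TAA",
    rng: np.random.Generator | None = None,
) -> DesignResult:
    """Design a CDS for ``protein`` with the trained cascade.

    ``fallback`` chooses the codon for interior positions no level matches:
    ``high`` (the modal codon, matching the control design), ``low`` (the
    least frequent), or ``sample`` (drawn with probability inversely
    proportional to usage; requires ``rng``). ``cascade=None`` sends every
    interior position to the fallback.
    """
    _check_protein(protein, min_len=5)
    if fallback not in FALLBACK_POLICIES:
        raise ValueError(f"fallback must be one of {FALLBACK_POLICIES}")
    if fallback == "sample" and rng is None:
        rng = np.random.default_rng()
    code = usage.code
    L = len(protein)
    reports: list[PositionReport] = []
    for i, aa in enumerate(protein):
        if code.degeneracy(aa) == 1:
            reports.append(PositionReport(i + 1, aa, code.codons_for(aa)[0], "single-codon"))
            continue
        if i < 2:
            reports.append(PositionReport(i + 1, aa, _low_codon(aa, usage), "first-two-low"))
            continue
        if i >= L - 2:
            reports.append(PositionReport(i + 1, aa, freq_class.high_codon(aa), "last-two-high"))
            continue
        assigned = False
        for w, c, models in cascade or ():
            half = w // 2
            if i - half < 0 or i + half >= L or w not in indexes or aa not in models:
                continue
            matches = search(indexes[w], protein[i - half : i + half + 1], c)
            if not matches:
                continue
            fv = aggregate_features(matches, code)
            codon = str(models[aa].predict([list(fv.values)])[0])
            reports.append(PositionReport(
                i + 1, aa, codon, "cascade", w=w, c=c,
                n_matches=len(matches), max_p=matches[0].p,
            ))
            assigned = True
            break
        if assigned:
            continue
        if fallback == "high":
            codon = freq_class.high_codon(aa)
        elif fallback == "low":
            codon = _low_codon(aa, usage)
        else:
            codons = code.codons_for(aa)
            inv = np.array([1.0 / max(usage.rel_freq.get(c_, 0.0), 1e-6) for c_ in codons])
            codon = codons[int(rng.choice(len(codons), p=inv / inv.sum()))]
        reports.append(PositionReport(i + 1, aa, codon, "fallback"))
    nt = "".join(r.codon for r in reports) + stop_codon
    cds = make_cds(protein_id, nt, code=code)
    assert cds.protein == protein
    return DesignResult(protein_id=protein_id, protein=protein, cds=cds.nucleotides,
                        positions=tuple(reports))


def design_report(
    result: DesignResult, freq_class: CodonFrequencyClass
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-position provenance table plus counts of low- vs high-class codons
    used (comparable to a codon-usage table of a designed vs control gene)."""
    rows = [
        {
            "position": p.position, "amino_acid": p.amino_acid, "codon": p.codon,
            "rule": p.rule, "w": p.w, "c": p.c,
            "n_matches": p.n_matches, "max_p": p.max_p,
            "class": "high" if freq_class.is_high(p.codon) else "low",
        }
        for p in result.positions
    ]
    df = pd.DataFrame(rows)
    summary = {
        "n_high": int((df["class"] == "high").sum()),
        "n_low": int((df["class"] == "low").sum()),
        "n_fallback": int((df["rule"] == "fallback").sum()),
        "n_cascade": int((df["rule"] == "cascade").sum()),
    }
    return df, summary


class GeneDesigner(BaseEstimator):
    """End-to-end estimator: learn context-dependent codon usage from a CDS
    corpus and design genes for new proteins.

    ``fit`` splits the corpus into an index part (CSI construction and codon
    usage) and a held-out training part (feature rows for the classifiers) —
    mirroring the train/index genome separation that avoids over-fit — then
    trains one random forest per degenerate amino acid per (w, c) level and
    assembles the priority cascade. ``predict`` designs one CDS per protein.

    Parameters
    ----------
    windows, cutoffs : the (w, c) grid of cascade levels.
    n_trees : trees per forest.
    train_fraction : fraction of genes held out from the index for training
        rows (ignored when ``fit`` receives an explicit ``train_corpus``).
    fallback : codon policy for unmatched interior positions.
    random_state : seed for the corpus split and the forests.
    """

    def __init__(
        self,
        windows: tuple[int, ...] = CASCADE_WINDOWS,
        cutoffs: tuple[float, ...] = CASCADE_CUTOFFS,
        n_trees: int = 1000,
        train_fraction: float = 0.2,
        fallback: str = "high",
        stop_codon: str = "TAA",
        random_state: int | None = None,
    ):
        self.windows = windows
        self.cutoffs = cutoffs
        self.n_trees = n_trees
        self.train_fraction = train_fraction
        self.fallback = fallback
        self.stop_codon = stop_codon
        self.random_state = random_state

    def fit(self, X: Sequence[CodingSequence], y=None,
            train_corpus: Sequence[CodingSequence] | None = None):
        corpus = list(X)
        if not corpus:
            raise ValueError("empty corpus")
        if train_corpus is None:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(corpus))
            n_train = max(1, int(round(self.train_fraction * len(corpus))))
            train_corpus = [corpus[i] for i in order[:n_train]]
            index_corpus = [corpus[i] for i in order[n_train:]]
        else:
            index_corpus = corpus
            train_corpus = list(train_corpus)
        code = genetic_code()
        self.usage_ = count_usage(index_corpus, corpus_id="index", code=code)
        self.freq_class_ = classify_frequency(self.usage_)
        self.indexes_ = {
            w: build_index(index_corpus, w, usage=self.usage_, code=code)
            for w in self.windows
        }
        models: dict[tuple[int, float], dict[str, CodonClassifier]] = {}
        for w in self.windows:
            per_cutoff = make_training_sets_multi(
                train_corpus, self.indexes_[w], self.cutoffs
            )
            for c, sets in per_cutoff.items():
                models[(w, c)] = {
                    aa: train(ts, seed=self.random_state, n_trees=self.n_trees)
                    for aa, ts in sets.items()
                }
        self.cascade_ = assemble_cascade(models)
        return self

    def design(self, protein: str, protein_id: str = "design") -> DesignResult:
        check_is_fitted(self, "cascade_")
        return design_gene(
            protein, self.cascade_, self.indexes_, self.usage_, self.freq_class_,
            protein_id=protein_id, fallback=self.fallback,
            stop_codon=self.stop_codon,
            rng=np.random.default_rng(self.random_state),
        )

    def predict(self, X: Sequence[str] | str) -> list[str] | str:
        """Designed CDS (with terminal stop) for each protein in X."""
        if isinstance(X, str):
            return self.design(X).cds
        return [self.design(p, protein_id=f"design{i}").cds for i, p in enumerate(X)]
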