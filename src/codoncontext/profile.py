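"""Codon-usage profiling: usage tables, entropy, frequency classes, RCBS,
and codon-usage Euclidean distance matrices with gene-bootstrap replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .seqio import CodingSequence, GeneticCode, genetic_code

logger = logging.getLogger(__name__)


@dataclass
class CodonUsageTable:
    """Per-corpus sense-codon counts and within-amino-acid relative frequencies.

    ``rel_freq[codon]`` is the frequency of a codon among the synonymous
    codons of its amino acid; for each observed amino acid these sum to 1.
    """

    corpus_id: str
    counts: dict[str, int]
    code: GeneticCode = field(default_factory=genetic_code)
    rel_freq: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.rel_freq = {}
        for aa, codons in self.code.synonymous.items():
            total = sum(self.counts.get(c, 0) for c in codons)
            if total > 0:
                for c in codons:
                    self.rel_freq[c] = self.counts.get(c, 0) / total

    def aa_distribution(self, aa: str) -> dict[str, float]:
        """Relative-frequency distribution over an amino acid's codons."""
        return {c: self.rel_freq[c] for c in self.code.codons_for(aa) if c in self.rel_freq}


def count_usage(
    corpus: Iterable[CodingSequence],
    corpus_id: str = "corpus",
    code: GeneticCode | None = None,
) -> CodonUsageTable:
    """Count sense-codon usage over a corpus and normalize within amino acids."""
    code = code or genetic_code()
    counts: dict[str, int] = {}
    n = 0
    for cds in corpus:
        n += 1
        for codon in cds.sense_codons:
            counts[codon] = counts.get(codon, 0) + 1
    if n == 0:
        raise ValueError("empty corpus")
    return CodonUsageTable(corpus_id=corpus_id, counts=counts, code=code)


def usage_entropy(dist: Mapping[str, float], n_codons: int) -> float:
    """Shannon entropy of a synonymous-codon distribution, normalized to [0, 1].

    1 means the codon is selected uniformly at random among the ``n_codons``
    synonymous codons; 0 means a single codon is always selected. Defined as 0
    for single-codon amino acids (Met, Trp).
    """
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {total}, not 1")
    if n_codons <= 1:
        return 0.0
    h = -sum(p * math.log2(p) for p in dist.values() if p > 0)
    return h / math.log2(n_codons)


@dataclass(frozen=True)
class CodonFrequencyClass:
    """Binary high/low class per codon: the modal codon of each amino acid is
    "high", all other synonymous codons are "low"."""

    high: dict[str, str]  # amino acid -> modal codon
    code: GeneticCode = field(default_factory=genetic_code)

    def is_high(self, codon: str) -> bool:
        aa = self.code.translate_codon(codon)
        return self.high.get(aa) == codon

    def high_codon(self, aa: str) -> str:
        return self.high[aa]

    def low_codons(self, aa: str) -> tuple[str, ...]:
        return tuple(c for c in self.code.codons_for(aa) if c != self.high.get(aa))


def classify_frequency(table: CodonUsageTable) -> CodonFrequencyClass:
    """Assign the modal ("high") codon per amino acid; ties and unobserved
    amino acids fall back alphabetically (with a warning for the latter)."""
    high: dict[str, str] = {}
    for aa, codons in table.code.synonymous.items():
        obs = [(table.counts.get(c, 0), c) for c in codons]
        best_count = max(n for n, _ in obs)
        if best_count == 0 and len(codons) > 1:
            logger.warning("amino acid %s unobserved; all its codons classed low", aa)
            continue
        # codons are alphabetical already: first with the maximal count wins ties
        high[aa] = next(c for n, c in obs if n == best_count)
    return CodonFrequencyClass(high=high, code=table.code)


@dataclass(frozen=True)
class RCBSResult:
    """Relative-codon-bias strength of one gene.

    ``d[codon]`` is the enrichment of an observed codon xyz over the product
    of the gene's positional base compositions f1(x)·f2(y)·f3(z); ``rcbs`` is
    the geometric mean of (1+d) over the gene's codons, minus 1.
    """

    gene_id: str
    d: dict[str, float]
    rcbs: float


def rcbs(gene: CodingSequence) -> RCBSResult:
    """Strength of relative codon bias of a single gene.

    The background is the gene's own positional nucleotide composition, so
    every observed codon has a strictly positive expected frequency.
    """
    codons = gene.sense_codons
    L = len(codons)
    if L < 1:
        raise ValueError("gene must have at least one sense codon")
    pos_freq = [{b: 0.0 for b in "ACGT"} for _ in range(3)]
    codon_count: dict[str, int] = {}
    for codon in codons:
        codon_count[codon] = codon_count.get(codon, 0) + 1
        for j, base in enumerate(codon):
            pos_freq[j][base] += 1
    for j in range(3):
        for b in "ACGT":
            pos_freq[j][b] /= L

    d: dict[str, float] = {}
    for codon, n in codon_count.items():
        f_obs = n / L
        f_exp = pos_freq[0][codon[0]] * pos_freq[1][codon[1]] * pos_freq[2][codon[2]]
        if f_exp == 0:
            raise ValueError(f"zero positional-product frequency for {codon}")
        d[codon] = (f_obs - f_exp) / f_exp

    log_prod = sum(math.log1p(d[codon]) for codon in codons)
    return RCBSResult(gene_id=gene.id, d=d, rcbs=math.expm1(log_prod / L))


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])


def _usage_vector(table: CodonUsageTable, kind: str) -> np.ndarray:
    code = table.code
    if kind == "rel_freq":
        # 59-dim within-amino-acid frequencies: degenerate amino acids only
        codons = [
            c for aa in code.degenerate_amino_acids for c in code.codons_for(aa)
        ]
        return np.array([table.rel_freq.get(c, 0.0) for c in codons])
    if kind == "fraction":
        codons = sorted(c for c in code.forward)
        total = sum(table.counts.values()) or 1
        return np.array([table.counts.get(c, 0) / total for c in codons])
    raise ValueError(f"unknown usage-vector kind {kind!r}")


def usage_distance_matrix(
    tables: Sequence[CodonUsageTable], kind: str = "rel_freq"
) -> DistanceMatrix:
    """Pairwise Euclidean distances between codon-usage vectors.

    ``kind='rel_freq'`` (default) uses the 59-dimensional within-amino-acid
    relative-frequency vector (Met/Trp/stops carry no usage signal);
    ``kind='fraction'`` uses raw 61-dimensional codon fractions.
    """
    if len(tables) < 2:
        raise ValueError("need at least two usage tables")
    code_ids = {t.code.table_id for t in tables}
    if len(code_ids) != 1:
        raise ValueError("usage tables built under different genetic codes")
    X = np.vstack([_usage_vector(t, kind) for t in tables])
    D = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(labels=tuple(t.corpus_id for t in tables), values=D)


def bootstrap_distance_matrices(
    genomes: Mapping[str, Sequence[CodingSequence]],
    n_genes: int = 2000,
    replicates: int = 1000,
    seed: int | None = None,
    kind: str = "rel_freq",
    replace: bool | None = None,
) -> list[DistanceMatrix]:
    """Distance matrices from repeated random gene subsamples of each genome.

    Each replicate draws ``n_genes`` genes per genome — without replacement
    when the genome has at least that many genes, with replacement otherwise
    (override with ``replace``; ``replace=False`` on a small genome takes the
    whole genome) — recomputes each genome's usage table and the pairwise
    distances. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    names = list(genomes)
    out: list[DistanceMatrix] = []
    for _ in range(replicates):
        tables = []
        for name in names:
            corpus = genomes[name]
            rep = len(corpus) < n_genes if replace is None else replace
            size = n_genes if rep else min(n_genes, len(corpus))
            idx = rng.choice(len(corpus), size=size, replace=rep)
            tables.append(count_usage([corpus[i] for i in idx], corpus_id=name))
        out.append(usage_distance_matrix(tables, kind=kind))
    return out


def write_usage_tsv(table: CodonUsageTable, path: str | Path) -> None:
    """Write a usage table as TSV: codon, amino_acid, count, rel_freq."""
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tcount\trel_freq\n")
        for aa in sorted(table.code.synonymous):
            for codon in table.code.codons_for(aa):
                fh.write(
                    f"{codon}\t{aa}\t{table.counts.get(codon, 0)}\t"
                    f"{table.rel_freq.get(codon, float('nan')):.6f}\n"
                )


def write_phylip(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a distance matrix in PHYLIP square format (for external tree
    building, e.g. neighbor-joining / consensus programs)."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.labels):5d}\n")
        for label, row in zip(matrix.labels, matrix.values):
            name = label[:10].ljust(10)
            fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
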