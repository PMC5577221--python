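"""BLOSUM62 matched-percent search against a CSI and similarity-weighted
aggregation of matched records into a fixed-length feature vector.

A query window is compared with each index peptide sharing its middle
residue. The matched score s is the sum of positionwise BLOSUM62 scores, the
maximal score m the query's self-score (sum of diagonal entries, strictly
positive), and the matched percent p = s/m. Records with p ≥ c contribute to
the feature vector with weight s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from functools import lru_cache

from .csi import CSIIndex, CSIRecord
from .seqio import STANDARD_AA, GeneticCode, blosum62_score

N_DIST_SLOTS = 6  # maximal synonymous-set size (Leu, Arg, Ser)

_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}


@lru_cache(maxsize=1)
def _blosum_array() -> np.ndarray:
    B = np.empty((20, 20), dtype=np.int64)
    for a, i in _AA_INDEX.items():
        for b, j in _AA_INDEX.items():
            B[i, j] = blosum62_score(a, b)
    return B


def _encoded_bucket(index: CSIIndex, aa: str) -> tuple[list[CSIRecord], np.ndarray]:
    """Bucket records with their peptides encoded as an (n, w) int matrix,
    cached on the index for repeated searches."""
    cache = getattr(index, "_encoded", None)
    if cache is None:
        cache = {}
        index._encoded = cache  # type: ignore[attr-defined]
    if aa not in cache:
        records = index.buckets.get(aa, [])
        mat = np.array(
            [[_AA_INDEX[ch] for ch in rec.peptide] for rec in records], dtype=np.int64
        ).reshape(len(records), index.w)
        cache[aa] = (records, mat)
    return cache[aa]


@dataclass(frozen=True)
class MatchResult:
    query: str
    record: CSIRecord
    s: int  # matched score
    m: int  # expected maximal score (query self-score)

    @property
    def p(self) -> float:
        return self.s / self.m


@dataclass(frozen=True)
class FeatureVector:
    """Input vector of one window: the (weighted) mean of matched records.

    ``values`` holds the middle-codon distribution in alphabetical codon
    order, zero-padded to 6 slots, followed by the w per-position average
    codon-usage values.
    """

    amino_acid: str
    w: int
    values: tuple[float, ...]
    n_matches: int
    total_weight: float


def matched_percent(query: str, candidate: str) -> tuple[int, int, float]:
    """(s, m, p) for a query/candidate peptide pair of equal length."""
    if len(query) != len(candidate):
        raise ValueError("query and candidate must have equal length")
    s = sum(blosum62_score(q, c) for q, c in zip(query, candidate))
    m = sum(blosum62_score(q, q) for q in query)
    return s, m, s / m


def search(index: CSIIndex, query: str, c: float) -> list[MatchResult]:
    """All index records with the query's middle residue and p ≥ c.

    The comparison is inclusive so c = 1 selects exactly the identical
    peptide when present. Results are sorted by p descending, ties broken by
    peptide alphabetically. The scan is restricted to the middle-residue
    bucket; no other pruning is applied.
    """
    query = query.upper()
    if len(query) != index.w:
        raise ValueError(f"query length {len(query)} != index window {index.w}")
    if not 0 < c <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {c}")
    try:
        q = np.array([_AA_INDEX[ch] for ch in query], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-standard amino acid {exc} in query {query!r}") from exc
    B = _blosum_array()
    m = int(B[q, q].sum())
    records, mat = _encoded_bucket(index, query[index.w // 2])
    if not records:
        return []
    scores = B[q[np.newaxis, :], mat].sum(axis=1)
    # compare on p = s/m so float behaviour matches a scalar brute-force scan
    hits = np.nonzero(scores / m >= c)[0]
    out = [
        MatchResult(query=query, record=records[i], s=int(scores[i]), m=m)
        for i in hits
    ]
    out.sort(key=lambda r: (-r.p, r.record.peptide))
    return out


def aggregate_features(
    matches: Sequence[MatchResult],
    code: GeneticCode,
    weighted: bool = True,
) -> FeatureVector | None:
    """Combine matched records into one feature vector.

    The vector is the mean of each record's (middle distribution padded to 6
    slots, per-position averages), weighted by the matched score s
    (``weighted=False`` gives the plain arithmetic mean). Returns None for an
    empty match list — the caller decides the fallback.
    """
    if not matches:
        return None
    aa = matches[0].record.middle
    w = len(matches[0].query)
    codons = code.codons_for(aa)
    acc = np.zeros(N_DIST_SLOTS + w)
    total = 0.0
    for mt in matches:
        if mt.record.middle != aa:
            raise ValueError("matches mix middle amino acids")
        weight = float(mt.s) if weighted else 1.0
        vec = np.zeros(N_DIST_SLOTS + w)
        for i, codon in enumerate(codons):
            vec[i] = mt.record.middle_dist.get(codon, 0.0)
        vec[N_DIST_SLOTS:] = mt.record.pos_avg
        acc += weight * vec
        total += weight
    acc /= total
    return FeatureVector(
        amino_acid=aa, w=w, values=tuple(acc), n_matches=len(matches), total_weight=total
    )


def verify_diagonal_dominance() -> bool:
    """Check that every off-diagonal BLOSUM62 entry is strictly smaller than
    both corresponding diagonal entries, so p = 1 iff query == candidate."""
    from .seqio import STANDARD_AA

    for a in STANDARD_AA:
        for b in STANDARD_AA:
            if a != b and blosum62_score(a, b) >= min(
                blosum62_score(a, a), blosum62_score(b, b)
            ):
                return False
    return True
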