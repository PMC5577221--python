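"""Codon-selection index (CSI): peptide windows mapped to the codon-usage
distribution of their middle residue.

Every protein in a training corpus is split into overlapping windows of
w ∈ {3, 5, 7} residues. Identical peptides are merged across all genes into
one record holding (a) the distribution of codons observed at the middle
residue and (b) for each window position, the mean corpus-wide relative
frequency of the codon observed there. Windows never span genes; stop codons
are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .profile import CodonUsageTable, count_usage, usage_entropy
from .seqio import CodingSequence, GeneticCode, genetic_code

FORMAT_MAGIC = "#csi-index"
FORMAT_VERSION = 1
ALLOWED_WINDOWS = (3, 5, 7)


@dataclass(frozen=True)
class PeptideFragment:
    """One peptide window with the codon observed at its middle residue."""

    peptide: str
    middle_codon: str
    source_id: str
    codons: tuple[str, ...]  # codons of every window position

    @property
    def middle(self) -> str:
        return self.peptide[len(self.peptide) // 2]


@dataclass
class CSIRecord:
    """Merged statistics of all occurrences of one peptide window."""

    peptide: str
    n_occurrences: int
    middle_dist: dict[str, float]  # codon -> frequency, sums to 1
    pos_avg: tuple[float, ...]  # per position: mean rel_freq of observed codon

    @property
    def middle(self) -> str:
        return self.peptide[len(self.peptide) // 2]


@dataclass
class CSIIndex:
    """Peptide→record mapping at one window size, bucketed by middle residue."""

    w: int
    corpus_id: str
    code: GeneticCode
    records: dict[str, CSIRecord]
    usage: CodonUsageTable
    buckets: dict[str, list[CSIRecord]] = field(init=False)

    def __post_init__(self) -> None:
        self.buckets = {}
        for rec in self.records.values():
            self.buckets.setdefault(rec.middle, []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def query_exact(self, peptide: str) -> CSIRecord | None:
        """Exact (case-insensitive) peptide lookup; None when absent."""
        peptide = peptide.upper()
        if len(peptide) != self.w:
            raise ValueError(f"peptide length {len(peptide)} != index window {self.w}")
        return self.records.get(peptide)


def extract_fragments(cds: CodingSequence, w: int) -> list[PeptideFragment]:
    """All overlapping w-residue windows of a protein (stop excluded).

    Returns len(protein) − w + 1 fragments, or an empty list for proteins
    shorter than w.
    """
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window size must be odd and positive, got {w}")
    protein = cds.protein
    codons = cds.sense_codons
    half = w // 2
    out = []
    for i in range(half, len(protein) - half):
        out.append(
            PeptideFragment(
                peptide=protein[i - half : i + half + 1],
                middle_codon=codons[i],
                source_id=cds.id,
                codons=codons[i - half : i + half + 1],
            )
        )
    return out


def build_index(
    corpus: Iterable[CodingSequence],
    w: int,
    usage: CodonUsageTable | None = None,
    corpus_id: str = "corpus",
    code: GeneticCode | None = None,
) -> CSIIndex:
    """Build a CSI from a corpus at window size w.

    ``usage`` supplies the corpus-wide within-amino-acid relative frequencies
    for the per-position averages; by default it is computed from the corpus
    itself.
    """
    code = code or genetic_code()
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    if usage is None:
        usage = count_usage(corpus, corpus_id=corpus_id, code=code)

    counts: dict[str, dict[str, int]] = {}  # peptide -> middle codon -> count
    pos_sums: dict[str, list[float]] = {}  # peptide -> per-position rel_freq sum
    for cds in corpus:
        for frag in extract_fragments(cds, w):
            mc = counts.setdefault(frag.peptide, {})
            mc[frag.middle_codon] = mc.get(frag.middle_codon, 0) + 1
            sums = pos_sums.setdefault(frag.peptide, [0.0] * w)
            for j, codon in enumerate(frag.codons):
                sums[j] += usage.rel_freq.get(codon, 1.0)  # single-codon aa -> 1

    records: dict[str, CSIRecord] = {}
    for peptide, mc in counts.items():
        n = sum(mc.values())
        records[peptide] = CSIRecord(
            peptide=peptide,
            n_occurrences=n,
            middle_dist={c: k / n for c, k in sorted(mc.items())},
            pos_avg=tuple(s / n for s in pos_sums[peptide]),
        )
    return CSIIndex(w=w, corpus_id=corpus_id, code=code, records=records, usage=usage)


def entropy_by_window(
    indexes: Mapping[int, CSIIndex],
    usage: CodonUsageTable | None = None,
) -> dict[str, dict[int, float]]:
    """Occurrence-weighted mean normalized middle-codon entropy per amino acid
    and window size.

    With ``usage`` given, a pseudo window w=1 is included whose entropy is
    that of the genome-wide within-amino-acid codon distribution — the
    context-free reference the windowed entropies are compared against.
    """
    out: dict[str, dict[int, float]] = {}
    some_index = next(iter(indexes.values()))
    code = some_index.code
    if usage is not None:
        for aa in sorted(code.synonymous):
            dist = usage.aa_distribution(aa)
            if dist:
                out.setdefault(aa, {})[1] = usage_entropy(dist, code.degeneracy(aa))
    for w, index in indexes.items():
        acc: dict[str, list[float]] = {}
        for rec in index.records.values():
            aa = rec.middle
            h = usage_entropy(rec.middle_dist, code.degeneracy(aa))
            acc.setdefault(aa, []).append(h * rec.n_occurrences)
        totals: dict[str, int] = {}
        for rec in index.records.values():
            totals[rec.middle] = totals.get(rec.middle, 0) + rec.n_occurrences
        for aa, weighted in acc.items():
            out.setdefault(aa, {})[w] = sum(weighted) / totals[aa]
    return out


def write_index(index: CSIIndex, path: str | Path) -> None:
    """Serialize an index as a diffable TSV with `#` metadata header lines.

    Floats are written with 6 decimals; the round trip reproduces counts
    exactly and every float to 1e-6.
    """
    with open(path, "w") as fh:
        fh.write(f"{FORMAT_MAGIC} v{FORMAT_VERSION}\n")
        fh.write(f"#w={index.w}\n")
        fh.write(f"#corpus={index.corpus_id}\n")
        fh.write(f"#genetic_code={index.code.table_id}\n")
        fh.write("#usage=" + ",".join(
            f"{c}:{n}" for c, n in sorted(index.usage.counts.items())) + "\n")
        for peptide in sorted(index.records):
            rec = index.records[peptide]
            dist = ";".join(f"{c}:{f:.6f}" for c, f in sorted(rec.middle_dist.items()))
            pos = ",".join(f"{v:.6f}" for v in rec.pos_avg)
            fh.write(f"{peptide}\t{rec.n_occurrences}\t{rec.middle}\t{dist}\t{pos}\n")


def read_index(path: str | Path) -> CSIIndex:
    """Read an index written by :func:`write_index`.

    Raises ``ValueError`` on a wrong magic line or format version.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(FORMAT_MAGIC):
            raise ValueError(f"{path}: not a CSI index file (bad magic {first!r})")
        version = first.split(" v")[-1]
        if version != str(FORMAT_VERSION):
            raise ValueError(f"{path}: unsupported CSI format version {version}")
        meta: dict[str, str] = {}
        records: dict[str, CSIRecord] = {}
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
                continue
            peptide, n, _middle, dist_s, pos_s = line.split("\t")
            records[peptide] = CSIRecord(
                peptide=peptide,
                n_occurrences=int(n),
                middle_dist={
                    c: float(f) for c, f in (kv.split(":") for kv in dist_s.split(";"))
                },
                pos_avg=tuple(float(v) for v in pos_s.split(",")),
            )
    code = genetic_code(int(meta.get("genetic_code", 1)))
    counts = {
        c: int(n) for c, n in (kv.split(":") for kv in meta["usage"].split(",") if kv)
    }
    usage = CodonUsageTable(corpus_id=meta.get("corpus", ""), counts=counts, code=code)
    return CSIIndex(
        w=int(meta["w"]), corpus_id=meta.get("corpus", ""), code=code,
        records=records, usage=usage,
    )
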