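"""Sequence I/O, reading-frame validation, genetic code and BLOSUM62 access.

All other modules obtain the codon→amino-acid mapping, the per-amino-acid
synonymous-codon lists and substitution scores from here, so the genetic code
(NCBI table 1 by default, table 11 selectable — they agree on the translation
of complete bacterial CDS bodies) is configured in exactly one place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class InvalidSequenceError(ValueError):
    """A sequence violates frame, alphabet or stop-codon constraints."""


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon→amino acid plus canonical synonymous-codon lists.

    Synonymous codons are listed in alphabetical order; this ordering is the
    canonical slot order used by feature vectors and serialized files.
    """

    table_id: int
    forward: dict[str, str]
    stop_codons: frozenset[str]
    synonymous: dict[str, tuple[str, ...]] = field(init=False)

    def __post_init__(self) -> None:
        syn: dict[str, list[str]] = {}
        for codon in sorted(self.forward):
            syn.setdefault(self.forward[codon], []).append(codon)
        object.__setattr__(
            self, "synonymous", {aa: tuple(cs) for aa, cs in syn.items()}
        )

    def translate_codon(self, codon: str) -> str:
        return self.forward[codon]

    def codons_for(self, aa: str) -> tuple[str, ...]:
        return self.synonymous[aa]

    def degeneracy(self, aa: str) -> int:
        return len(self.synonymous[aa])

    @property
    def degenerate_amino_acids(self) -> tuple[str, ...]:
        """Amino acids with more than one synonymous codon (18 in table 1)."""
        return tuple(a for a in sorted(self.synonymous) if len(self.synonymous[a]) > 1)


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 1) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return GeneticCode(
        table_id=table_id,
        forward=dict(table.forward_table),
        stop_codons=frozenset(table.stop_codons),
    )


@dataclass(frozen=True)
class CodingSequence:
    """A validated coding sequence in frame, without internal stop codons.

    ``codons`` includes a terminal stop codon when one was present in the
    input; ``protein`` never includes the stop.
    """

    id: str
    nucleotides: str
    codons: tuple[str, ...]
    protein: str

    def __len__(self) -> int:  # protein length in residues
        return len(self.protein)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """Codons of the protein body, terminal stop excluded."""
        return self.codons[: len(self.protein)]


def make_cds(seq_id: str, nucleotides: str, code: GeneticCode | None = None) -> CodingSequence:
    """Validate a nucleotide string and build a :class:`CodingSequence`.

    Raises :class:`InvalidSequenceError` on frame violations, ambiguous bases,
    or internal stop codons. A single terminal stop codon is allowed.
    """
    code = code or genetic_code()
    nt = nucleotides.upper().replace("U", "T")
    if len(nt) % 3 != 0:
        raise InvalidSequenceError(f"{seq_id}: length {len(nt)} not divisible by 3")
    if not nt:
        raise InvalidSequenceError(f"{seq_id}: empty sequence")
    if set(nt) - set("ACGT"):
        bad = "".join(sorted(set(nt) - set("ACGT")))
        raise InvalidSequenceError(f"{seq_id}: non-ACGT characters {bad!r}")
    codons = tuple(nt[i : i + 3] for i in range(0, len(nt), 3))
    protein_chars: list[str] = []
    for i, codon in enumerate(codons):
        if codon in code.stop_codons:
            if i != len(codons) - 1:
                raise InvalidSequenceError(f"{seq_id}: internal stop codon at codon {i + 1}")
        else:
            protein_chars.append(code.translate_codon(codon))
    if not protein_chars:
        raise InvalidSequenceError(f"{seq_id}: no sense codons")
    return CodingSequence(
        id=seq_id, nucleotides=nt, codons=codons, protein="".join(protein_chars)
    )


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.startswith(">") else "genbank"
    raise InvalidSequenceError(f"{path}: empty file")


def read_cds(
    path: str | Path,
    format: str | None = None,
    code: GeneticCode | None = None,
) -> list[CodingSequence]:
    """Read coding sequences from a nucleotide FASTA or GenBank file.

    Records failing frame/stop/alphabet validation are skipped and logged with
    their reason. GenBank input contributes one sequence per CDS feature.

    Raises ``FileNotFoundError`` for an unreadable path and
    :class:`InvalidSequenceError` if no record validates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    raw: list[tuple[str, str]] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(path, "fasta"):
            raw.append((rec.id, str(rec.seq)))
    elif fmt == "genbank":
        for rec in SeqIO.parse(path, "genbank"):
            for i, feat in enumerate(rec.features):
                if feat.type != "CDS":
                    continue
                name = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", [f"{rec.id}_cds{i}"]))[0]
                raw.append((name, str(feat.extract(rec.seq))))
    else:
        raise ValueError(f"unknown format {fmt!r}")

    accepted: list[CodingSequence] = []
    n_rejected = 0
    for seq_id, nt in raw:
        try:
            accepted.append(make_cds(seq_id, nt, code=code))
        except InvalidSequenceError as exc:
            n_rejected += 1
            logger.warning("skipping record: %s", exc)
    if not accepted:
        raise InvalidSequenceError(
            f"{path}: zero valid CDS records ({n_rejected} rejected)"
        )
    if n_rejected:
        logger.info("%s: accepted %d CDS, rejected %d", path, len(accepted), n_rejected)
    return accepted


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


@lru_cache(maxsize=1)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


def blosum62_score(aa1: str, aa2: str) -> int:
    """Standard BLOSUM62 score for a pair of standard amino-acid letters.

    Ambiguity letters (B, Z, X) and non-standard residues are rejected so the
    maximal self-score m (a sum of diagonal entries) is always well defined
    and strictly positive.
    """
    if aa1 not in STANDARD_AA or aa2 not in STANDARD_AA:
        raise ValueError(f"non-standard amino acid in pair ({aa1!r}, {aa2!r})")
    return int(_blosum62()[aa1, aa2])
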