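"""Sequences, annotations, and the coordinate/translation conventions.

Every module in the toolkit relies on the conventions fixed here:

* genomic coordinates are 1-based, inclusive, on the forward axis, with an
  explicit strand flag (minus-strand features are still stored start <= end);
* chromosomes are linear (Streptomyces chromosomes are linear), so no ORF
  wraps around an origin;
* nucleotide sequences are uppercased on ingest, ``U`` is mapped to ``T``,
  and only ``A/C/G/T/N`` survive ingest;
* translation uses the bacterial/archaeal codon table (NCBI table 11), and
  any codon at a configured start position may be rendered as the initiator
  methionine regardless of the residue it encodes genomically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

NT_ALPHABET = frozenset("ACGTN")

_TABLE = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA
#: default alternative start codons for bacterial smORF calling
DEFAULT_START_CODONS: tuple[str, ...] = ("ATG", "GTG", "CTG", "TTG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named linear nucleotide sequence over ``A/C/G/T/N``."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - NT_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def seq_id(self) -> str:
        return self.id


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on the forward axis with a strand flag."""

    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @classmethod
    def normalized(cls, seq_id: str, a: int, b: int, strand: str) -> "GenomicInterval":
        """Accept coordinates in either order (minus-strand features are often
        printed high-to-low) and normalize to forward-axis start <= end."""
        return cls(seq_id, min(a, b), max(a, b), strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.seq_id == other.seq_id and self.start <= other.end and other.start <= self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated feature (CDS or gene) with a unique feature id."""

    seq_id: str
    start: int
    end: int
    strand: str
    feature_id: str
    feature_type: str = "CDS"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: end < start "
                f"({self.start}-{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"feature {self.feature_id!r}: unknown strand {self.strand!r}"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.start, self.end, self.strand)

    @property
    def stop_codon_interval(self) -> GenomicInterval:
        """The terminal codon of the feature (CDS spans include their stop)."""
        if self.strand == "+":
            return GenomicInterval(self.seq_id, self.end - 2, self.end, "+")
        return GenomicInterval(self.seq_id, self.start, self.start + 2, "-")


def _normalize_residues(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a nucleotide FASTA; uppercase, map U->T, reject duplicates."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _normalize_residues(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotation(path: str | Path) -> list[AnnotationRecord]:
    """Read CDS/gene features from GFF3, sorted by (seq_id, start).

    The feature id is taken from the ``ID`` attribute, falling back to
    ``locus_tag``; ids must be unique within the file.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[AnnotationRecord] = []
    seen: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        ids = feat.attributes.get("ID") or feat.attributes.get("locus_tag")
        if not ids:
            raise ValueError(
                f"{path}: {feat.featuretype} feature at {feat.seqid}:"
                f"{feat.start}-{feat.end} has neither ID nor locus_tag"
            )
        feature_id = ids[0]
        if feature_id in seen:
            raise ValueError(f"{path}: duplicate feature id {feature_id!r}")
        seen.add(feature_id)
        records.append(
            AnnotationRecord(
                seq_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                feature_id=feature_id,
                feature_type=feat.featuretype,
            )
        )
    records.sort(key=lambda r: (r.seq_id, r.start))
    return records


def write_annotation(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    """Re-emit annotation records as GFF3 with the same conventions."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write(
                f"{r.seq_id}\tsmorfkit\t{r.feature_type}\t{r.start}\t{r.end}"
                f"\t.\t{r.strand}\t0\tID={r.feature_id}\n"
            )


def revcomp(residues: str) -> str:
    """Reverse complement over ``A/C/G/T/N`` (an involution)."""
    bad = set(residues) - NT_ALPHABET
    if bad:
        raise ValueError(f"illegal residues for revcomp: {sorted(bad)}")
    return residues.translate(_COMPLEMENT)[::-1]


def translate(
    residues: str,
    as_initiator: bool = False,
    start_set: Sequence[str] = DEFAULT_START_CODONS,
) -> str:
    """Translate with NCBI table 11; stops render ``*``, ambiguous codons ``X``.

    With ``as_initiator`` the first codon, if it is a configured start codon,
    is rendered ``M`` regardless of the residue it encodes genomically (the
    genomically encoded form is retrievable by translating without the flag).
    """
    if len(residues) % 3 != 0:
        raise ValueError(f"length {len(residues)} not divisible by 3")
    out: list[str] = []
    for i in range(0, len(residues), 3):
        codon = residues[i : i + 3]
        if i == 0 and as_initiator and codon in start_set:
            out.append("M")
        elif set(codon) - {"A", "C", "G", "T"}:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(CODON_TO_AA[codon])
    return "".join(out)
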