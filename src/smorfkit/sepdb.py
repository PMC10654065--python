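"""Transcript-derived SEP databases: smRNA filtering, six-frame translation,
cross-species prediction by direct matching, and provenance-tracking merges.

A SEP database is a flat list of peptide entries tagged with their source
(``genome_six_frame`` | ``transcript_six_frame`` | ``predicted_cross_species``).
Merging collapses entries by exact peptide sequence — I/L are *not* merged at
the database level; that equivalence belongs to peptide matching only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import GenomicInterval, SequenceRecord, revcomp, translate

logger = logging.getLogger(__name__)

SOURCES = ("genome_six_frame", "transcript_six_frame", "predicted_cross_species")

#: frame tags for the six reading frames: sign is strand, digit is offset
FRAME_TAGS = ("+0", "+1", "+2", "-0", "-1", "-2")


@dataclass(frozen=True)
class TranscriptRecord:
    """An assembled transcript with abundance; sequence and/or coordinates."""

    id: str
    sequence: str | None = None
    interval: GenomicInterval | None = None
    fpkm: float = 0.0

    @property
    def strand(self) -> str | None:
        return self.interval.strand if self.interval else None

    @property
    def length(self) -> int:
        if self.sequence is not None:
            return len(self.sequence)
        if self.interval is not None:
            return self.interval.length
        raise ValueError(f"transcript {self.id!r} has neither sequence nor interval")


@dataclass(frozen=True)
class SepDatabaseEntry:
    peptide: str
    sources: frozenset[str]
    origin_ids: frozenset[str]
    frame: str = ""

    def __post_init__(self) -> None:
        if not self.peptide or "*" in self.peptide:
            raise ValueError(f"invalid database peptide {self.peptide!r}")


def read_transcript_table(path: str | Path, genome: SequenceRecord | None = None) -> list[TranscriptRecord]:
    """Read a GTF-like transcript file carrying an FPKM attribute.

    When a genome is supplied, transcript sequences are sliced from it
    (reverse-complemented for minus-strand transcripts).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out: list[TranscriptRecord] = []
    for feat in db.all_features():
        if feat.featuretype != "transcript":
            continue
        tid = (feat.attributes.get("transcript_id") or [feat.id])[0]
        fpkm = float((feat.attributes.get("FPKM") or ["0"])[0])
        iv = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
        seq = None
        if genome is not None and genome.seq_id == feat.seqid:
            seq = transcript_sequence(genome, iv)
        out.append(TranscriptRecord(id=tid, sequence=seq, interval=iv, fpkm=fpkm))
    return out


def transcript_sequence(genome: SequenceRecord, interval: GenomicInterval) -> str:
    s = genome.residues[interval.start - 1 : interval.end]
    return s if interval.strand == "+" else revcomp(s)


def filter_transcripts(
    records: Iterable[TranscriptRecord],
    fpkm_min: float = 1.0,
    max_len: int = 300,
) -> list[TranscriptRecord]:
    """Retain transcripts with fpkm strictly greater than ``fpkm_min`` and
    length at most ``max_len`` (the smRNA filter).  Records with a negative
    FPKM are malformed and dropped with a warning."""
    kept: list[TranscriptRecord] = []
    for rec in records:
        if rec.fpkm < 0:
            logger.warning("transcript %s rejected: negative FPKM %g", rec.id, rec.fpkm)
            continue
        if rec.fpkm > fpkm_min and rec.length <= max_len:
            kept.append(rec)
    return kept


def sixframe_segments(sequence: str) -> list[tuple[str, int, str]]:
    """All six-frame inter-stop translation segments of a sequence.

    Returns ``(frame_tag, aa_offset_in_frame, segment)`` triples; the offset
    is the 0-based residue index of the segment within its full frame
    translation.
    """
    out: list[tuple[str, int, str]] = []
    for strand in ("+", "-"):
        s = sequence if strand == "+" else revcomp(sequence)
        for frame in range(3):
            n = (len(s) - frame) // 3
            if n <= 0:
                continue
            aa = translate(s[frame : frame + 3 * n])
            offset = 0
            for segment in aa.split("*"):
                if segment:
                    out.append((f"{strand}{frame}", offset, segment))
                offset += len(segment) + 1
    return out


def sixframe_translate_rnas(
    smrnas: Iterable[TranscriptRecord],
    min_len: int = 7,
    source: str = "transcript_six_frame",
) -> list[SepDatabaseEntry]:
    """Translate each smRNA in six frames, cutting at stop codons; every
    inter-stop segment of at least ``min_len`` residues becomes an entry."""
    entries: list[SepDatabaseEntry] = []
    for rec in smrnas:
        if rec.sequence is None:
            raise ValueError(f"transcript {rec.id!r} has no sequence to translate")
        for tag, _offset, segment in sixframe_segments(rec.sequence):
            if len(segment) >= min_len:
                entries.append(
                    SepDatabaseEntry(
                        peptide=segment,
                        sources=frozenset({source}),
                        origin_ids=frozenset({rec.id}),
                        frame=tag,
                    )
                )
    return entries


def genome_sixframe_entries(
    genome: SequenceRecord, min_len: int = 7
) -> list[SepDatabaseEntry]:
    """Six-frame inter-stop segments of a whole genome as database entries."""
    return sixframe_translate_rnas(
        [TranscriptRecord(id=genome.seq_id, sequence=genome.residues)],
        min_len=min_len,
        source="genome_six_frame",
    )


def predict_cross_species(
    entries: Iterable[SepDatabaseEntry],
    target_genome: SequenceRecord,
    identity_min: float = 80.0,
    coverage_min: float = 80.0,
) -> list[SepDatabaseEntry]:
    """Project a model-strain SEP database onto a target genome.

    An entry transfers when its peptide occurs as an ungapped full-length
    match in the target six-frame translation with identity >= ``identity_min``
    percent over >= ``coverage_min`` percent of its length (I/L equivalent).
    """
    from .mapping import MapperPolicy, filter_hits, map_peptide

    out: list[SepDatabaseEntry] = []
    for e in entries:
        budget = int(len(e.peptide) * (1.0 - identity_min / 100.0))
        policy = MapperPolicy(
            max_mismatch=budget, identity_min=identity_min, coverage_min=coverage_min
        )
        hits = filter_hits(map_peptide(e.peptide, target_genome, policy), policy)
        if hits:
            out.append(
                replace(e, sources=frozenset({"predicted_cross_species"}))
            )
    return out


def merge_dbs(
    dbs: Sequence[Sequence[SepDatabaseEntry]],
) -> tuple[list[SepDatabaseEntry], pd.DataFrame]:
    """Merge SEP databases, collapsing identical peptide sequences.

    Returns the merged entries (each carrying the union of sources and
    origin ids of its contributors) plus an overlap report with the shared /
    unique entry counts for every source-set combination (the Venn numbers).
    """
    if not dbs:
        raise ValueError("merge_dbs needs at least one database")
    merged: dict[str, SepDatabaseEntry] = {}
    for db in dbs:
        for e in db:
            if e.peptide in merged:
                prev = merged[e.peptide]
                merged[e.peptide] = replace(
                    prev,
                    sources=prev.sources | e.sources,
                    origin_ids=prev.origin_ids | e.origin_ids,
                )
            else:
                merged[e.peptide] = e
    entries = sorted(merged.values(), key=lambda e: e.peptide)

    by_source: dict[str, set[str]] = {}
    for e in entries:
        for s in e.sources:
            by_source.setdefault(s, set()).add(e.peptide)
    rows = []
    labels = sorted(by_source)
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            shared = set.intersection(*(by_source[s] for s in combo))
            exclusive = shared - set().union(
                *(by_source[s] for s in labels if s not in combo), set()
            )
            rows.append(
                {
                    "sources": "&".join(combo),
                    "shared": len(shared),
                    "exclusive": len(exclusive),
                }
            )
    report = pd.DataFrame(rows, columns=["sources", "shared", "exclusive"])
    return entries, report


def write_sep_db(entries: Sequence[SepDatabaseEntry], path: str | Path) -> None:
    """Write a SEP database as FASTA with source tags in the headers."""
    with open(path, "w") as fh:
        for i, e in enumerate(entries, 1):
            sources = ",".join(sorted(e.sources))
            origins = ",".join(sorted(e.origin_ids))
            fh.write(f">sep{i:06d} sources={sources} origins={origins} frame={e.frame}\n")
            fh.write(e.peptide + "\n")
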