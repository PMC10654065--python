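"""Stop-to-stop ORF enumeration in six frames and the smORF database.

Candidate ORFs follow the stop-codon-to-stop-codon principle: within each
frame segment bounded by in-frame stop codons (or the sequence start), every
configured start codon upstream of the terminating stop is a candidate start,
and all candidates sharing a stop are grouped into one record.  ORFs truncated
by the sequence end (no stop codon) are excluded — a SEP must map to a
complete ORF.  Codons containing ``N`` are neither starts nor stops.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import reports
from .genome import (
    DEFAULT_START_CODONS,
    STOP_CODONS,
    GenomicInterval,
    SequenceRecord,
    revcomp,
    translate,
)


@dataclass(frozen=True)
class CandidateStart:
    interval: GenomicInterval
    codon: str


@dataclass(frozen=True)
class OrfRecord:
    """One stop-anchored ORF with all in-frame candidate starts.

    ``frame`` is the 0/1/2 offset on the ORF's own strand; coordinates are on
    the forward axis.  ``candidate_starts`` is ordered furthest-upstream
    first (reading order); ``orf_interval``, ``nt_length`` and ``peptide``
    describe the maximal ORF (furthest-upstream start through the stop codon,
    initiator rendered ``M``, terminal stop excluded).
    """

    seq_id: str
    strand: str
    frame: int
    stop_interval: GenomicInterval
    candidate_starts: tuple[CandidateStart, ...]
    orf_interval: GenomicInterval
    nt_length: int
    peptide: str

    @property
    def start_codon(self) -> str:
        return self.candidate_starts[0].codon

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Locus identity: one ORF per (seq_id, strand, stop codon)."""
        return (self.seq_id, self.strand, self.stop_interval.start, self.stop_interval.end)


@dataclass
class SmorfDatabase:
    entries: list[OrfRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.entries)


def _local_to_forward(length: int, strand: str, a: int, b: int) -> tuple[int, int]:
    """Map a 1-based inclusive strand-local span to the forward axis."""
    if strand == "+":
        return a, b
    return length + 1 - b, length + 1 - a


def enumerate_orfs(
    genome: SequenceRecord,
    start_set: Sequence[str] = DEFAULT_START_CODONS,
    stop_set: frozenset[str] = STOP_CODONS,
) -> list[OrfRecord]:
    """Enumerate all six-frame stop-to-stop ORFs with candidate starts.

    Returns one record per (strand, frame, stop codon) that has at least one
    in-frame candidate start with no intervening in-frame stop.  Minus-strand
    ORFs are found on the reverse complement and reported with forward-axis
    coordinates.
    """
    if not start_set:
        raise ValueError("start_set must be non-empty")
    L = len(genome.residues)
    records: list[OrfRecord] = []
    for strand in ("+", "-"):
        s = genome.residues if strand == "+" else revcomp(genome.residues)
        for frame in range(3):
            pending: list[tuple[int, str]] = []  # (codon index, codon) of open starts
            n_codons = (L - frame) // 3
            for ci in range(n_codons):
                codon = s[frame + 3 * ci : frame + 3 * ci + 3]
                if codon in stop_set:
                    if pending:
                        records.append(
                            _build_record(genome.seq_id, s, L, strand, frame, pending, ci, start_set)
                        )
                    pending = []
                elif codon in start_set:
                    pending.append((ci, codon))
            # starts still pending at the sequence end lack a stop: dropped
    records.sort(key=lambda r: (r.seq_id, r.orf_interval.start, r.strand, r.frame))
    return records


def _build_record(
    seq_id: str,
    s: str,
    L: int,
    strand: str,
    frame: int,
    starts: list[tuple[int, str]],
    stop_ci: int,
    start_set: Sequence[str],
) -> OrfRecord:
    def codon_iv(ci: int) -> GenomicInterval:
        a = frame + 3 * ci + 1
        f_start, f_end = _local_to_forward(L, strand, a, a + 2)
        return GenomicInterval(seq_id, f_start, f_end, strand)

    cands = tuple(CandidateStart(codon_iv(ci), codon) for ci, codon in starts)
    first_ci = starts[0][0]
    a = frame + 3 * first_ci + 1
    b = frame + 3 * stop_ci + 3
    f_start, f_end = _local_to_forward(L, strand, a, b)
    orf_iv = GenomicInterval(seq_id, f_start, f_end, strand)
    coding = s[a - 1 : frame + 3 * stop_ci]  # start through codon before stop
    peptide = translate(coding, as_initiator=True, start_set=start_set)
    return OrfRecord(
        seq_id=seq_id,
        strand=strand,
        frame=frame,
        stop_interval=codon_iv(stop_ci),
        candidate_starts=cands,
        orf_interval=orf_iv,
        nt_length=orf_iv.length,
        peptide=peptide,
    )


def extract_smorfs(
    orfs: Iterable[OrfRecord],
    max_nt: int = 300,
    max_aa: int = 100,
    mode: str = "aa",
) -> SmorfDatabase:
    """Select small ORFs from an enumeration.

    The size filter applies to the maximal ORF of each record.  ``mode``
    selects which threshold is active: ``"aa"`` (peptide <= max_aa, the
    default), ``"nt"`` (ORF span including the stop <= max_nt), ``"either"``
    or ``"both"``.  Note a 100-aa peptide occupies a 303-nt ORF span, so the
    two filters are not interchangeable.
    """
    if max_nt <= 0 or max_aa <= 0:
        raise ValueError("thresholds must be positive")
    if mode not in ("aa", "nt", "either", "both"):
        raise ValueError(f"unknown filter mode {mode!r}")
    kept: dict[tuple, OrfRecord] = {}
    for orf in orfs:
        pass_aa = len(orf.peptide) <= max_aa
        pass_nt = orf.nt_length <= max_nt
        ok = {
            "aa": pass_aa,
            "nt": pass_nt,
            "either": pass_aa or pass_nt,
            "both": pass_aa and pass_nt,
        }[mode]
        if ok:
            kept.setdefault(orf.key, orf)
    return SmorfDatabase(
        entries=list(kept.values()),
        provenance=f"smorfkit smORF database mode={mode} max_nt={max_nt} max_aa={max_aa}",
    )


def write_db(db: SmorfDatabase, path: str | Path) -> None:
    """Write the database as FASTA; headers encode the locus.

    Header schema: ``seq_id|strand|orf_start|orf_end|start_codon|frame``.
    A leading ``;`` comment line carries the provenance.
    """
    with open(path, "w") as fh:
        fh.write(f";{db.provenance}\n")
        for e in db.entries:
            fh.write(
                f">{e.seq_id}|{e.strand}|{e.orf_interval.start}|"
                f"{e.orf_interval.end}|{e.start_codon}|{e.frame}\n"
            )
            fh.write(e.peptide + "\n")


def read_db(path: str | Path, genome: SequenceRecord) -> SmorfDatabase:
    """Re-read a database written by :func:`write_db` (bit-exact round trip).

    The genome is required to reconstruct full records (candidate starts and
    stop intervals are re-derived by re-enumerating the encoded locus).
    """
    provenance = ""
    headers: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(";"):
                provenance = line[1:]
            elif line.startswith(">"):
                headers.append(line[1:])
    by_key = {o.key: o for o in enumerate_orfs(genome)}
    entries = []
    for h in headers:
        seq_id, strand, start, end, codon, frame = h.split("|")
        iv = GenomicInterval(seq_id, int(start), int(end), strand)
        stop = (
            GenomicInterval(seq_id, iv.end - 2, iv.end, strand)
            if strand == "+"
            else GenomicInterval(seq_id, iv.start, iv.start + 2, strand)
        )
        key = (seq_id, strand, stop.start, stop.end)
        if key not in by_key:
            raise ValueError(f"database entry {h!r} not found in genome {genome.seq_id!r}")
        entries.append(by_key[key])
    return SmorfDatabase(entries=entries, provenance=provenance)


def summarize_start_codons(db: SmorfDatabase | Sequence[OrfRecord]):
    """Start-codon usage table of the reported start of each entry."""
    entries = db.entries if isinstance(db, SmorfDatabase) else list(db)
    if not entries:
        raise ValueError("empty database has no start-codon usage")
    counts = Counter(e.start_codon for e in entries)
    return reports.start_codon_usage(counts)
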