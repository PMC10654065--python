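"""Back-correlation of mapped peptides to ORFs and SEP classification.

A mapped peptide locus is tied back to its containing stop-to-stop ORF; the
SEP start is the furthest-upstream candidate start codon (at or upstream of
the peptide) whose resulting peptide does not exceed the smORF cap.  Calls
are then classified against the annotation:

* ``annotated`` — chosen start and stop coincide exactly with an annotated CDS;
* ``ISEP``      — a same-frame, same-strand CDS shares the stop codon and the
  chosen start is strictly internal (a hidden start codon: the SEP is an
  N-terminally truncated isoform of the annotated protein);
* ``CSEP``      — everything else (intergenic, different frame, or opposite
  strand), with every overlap relation still recorded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import reports
from .genome import (
    CODON_TO_AA,
    DEFAULT_START_CODONS,
    STOP_CODONS,
    AnnotationRecord,
    GenomicInterval,
    SequenceRecord,
    revcomp,
    translate,
)
from .mapping import MappedLocus
from .orfs import CandidateStart, OrfRecord

SEP_CLASSES = ("annotated", "ISEP", "CSEP")

OVERLAP_RELATIONS = (
    "same_frame_contained",
    "shared_stop",
    "same_strand_overlap",
    "opposite_strand_overlap",
    "none",
)


@dataclass(frozen=True)
class BackCorrelation:
    """A locus resolved to its ORF and chosen start (or an orphan flag)."""

    orf: OrfRecord | None
    chosen_start: CandidateStart | None
    sep_length: int = 0
    orphan: bool = False
    reason: str = ""

    @property
    def sep_interval(self) -> GenomicInterval:
        assert self.orf is not None and self.chosen_start is not None
        lo = min(self.chosen_start.interval.start, self.orf.stop_interval.start)
        hi = max(self.chosen_start.interval.end, self.orf.stop_interval.end)
        return GenomicInterval(self.orf.seq_id, lo, hi, self.orf.strand)


@dataclass(frozen=True)
class SepCall:
    """A classified SEP with its ORF, chosen start, and peptide evidence."""

    orf: OrfRecord
    chosen_start: CandidateStart
    sep_class: str
    sep_interval: GenomicInterval
    sep_length: int
    parent_feature: AnnotationRecord | None
    overlapping_features: tuple[tuple[AnnotationRecord, str], ...]
    evidence: tuple[MappedLocus, ...]
    notes: tuple[str, ...] = ()

    @property
    def start_codon(self) -> str:
        return self.chosen_start.codon

    def peptide(self, genome: SequenceRecord, as_initiator: bool = True) -> str:
        """The SEP amino-acid sequence (stop excluded) from the genome."""
        iv = self.sep_interval
        s = genome.residues[iv.start - 1 : iv.end]
        if self.orf.strand == "-":
            s = revcomp(s)
        return translate(s[:-3], as_initiator=as_initiator)


@dataclass(frozen=True)
class CoverageProfile:
    covered_residues: frozenset[int]
    coverage_pct: float
    full_length: bool
    n_term_excised: str | None = None


def back_correlate(
    locus: MappedLocus,
    genome: SequenceRecord,
    start_set: Sequence[str] = DEFAULT_START_CODONS,
    max_aa: int = 100,
) -> BackCorrelation:
    """Resolve an accepted locus to its stop-to-stop ORF and chosen start.

    Candidate starts are restricted to those at or upstream of the locus;
    the chosen start is the furthest upstream yielding a SEP of at most
    ``max_aa`` residues.  Loci with no usable candidate start, or in a frame
    segment truncated by the sequence end, are flagged as orphans.
    """
    L = len(genome.residues)
    s = genome.residues if locus.strand == "+" else revcomp(genome.residues)
    local_a = locus.interval.start if locus.strand == "+" else L + 1 - locus.interval.end
    frame = locus.frame
    if (local_a - 1 - frame) % 3 != 0:
        raise ValueError("locus start is not in its stated frame")
    ci = (local_a - 1 - frame) // 3
    plen = locus.interval.length // 3
    n_codons = (L - frame) // 3

    def codon(i: int) -> str:
        return s[frame + 3 * i : frame + 3 * i + 3]

    # upstream scan: segment lower bound and candidate starts at/upstream of locus
    seg_lo = 0
    for i in range(ci - 1, -1, -1):
        if codon(i) in STOP_CODONS:
            seg_lo = i + 1
            break
    candidates = [
        (i, codon(i)) for i in range(seg_lo, ci + 1) if codon(i) in start_set
    ]
    # downstream scan: terminating stop
    js = None
    for i in range(ci + plen, n_codons):
        if codon(i) in STOP_CODONS:
            js = i
            break
    if js is None:
        return BackCorrelation(None, None, orphan=True, reason="no stop codon (truncated frame segment)")
    if not candidates:
        return BackCorrelation(None, None, orphan=True, reason="no candidate start upstream of peptide")
    chosen = next(((i, c) for i, c in candidates if js - i <= max_aa), None)
    if chosen is None:
        return BackCorrelation(
            None, None, orphan=True, reason=f"no candidate start within {max_aa} aa of the stop"
        )

    def codon_iv(i: int) -> GenomicInterval:
        a = frame + 3 * i + 1
        if locus.strand == "+":
            return GenomicInterval(genome.seq_id, a, a + 2, "+")
        return GenomicInterval(genome.seq_id, L + 1 - (a + 2), L + 1 - a, "-")

    cand_starts = tuple(CandidateStart(codon_iv(i), c) for i, c in candidates)
    first_i = candidates[0][0]
    a = frame + 3 * first_i + 1
    b = frame + 3 * js + 3
    if locus.strand == "+":
        orf_iv = GenomicInterval(genome.seq_id, a, b, "+")
    else:
        orf_iv = GenomicInterval(genome.seq_id, L + 1 - b, L + 1 - a, "-")
    orf = OrfRecord(
        seq_id=genome.seq_id,
        strand=locus.strand,
        frame=frame,
        stop_interval=codon_iv(js),
        candidate_starts=cand_starts,
        orf_interval=orf_iv,
        nt_length=orf_iv.length,
        peptide=translate(s[a - 1 : frame + 3 * js], as_initiator=True, start_set=start_set),
    )
    ci_chosen, codon_chosen = chosen
    return BackCorrelation(
        orf=orf,
        chosen_start=CandidateStart(codon_iv(ci_chosen), codon_chosen),
        sep_length=js - ci_chosen,
    )


def classify(
    bc: BackCorrelation,
    annotation: Sequence[AnnotationRecord],
    genome_length: int,
    evidence: Sequence[MappedLocus] = (),
) -> SepCall:
    """Classify a back-correlated ORF as annotated / ISEP / CSEP."""
    if bc.orphan or bc.orf is None or bc.chosen_start is None:
        raise ValueError(f"cannot classify an orphan locus: {bc.reason}")
    orf = bc.orf
    sep_iv = bc.sep_interval

    def feature_frame(f: AnnotationRecord) -> int:
        return (f.start - 1) % 3 if f.strand == "+" else (genome_length - f.end) % 3

    relations: list[tuple[AnnotationRecord, str]] = []
    parent: AnnotationRecord | None = None
    annotated_hit: AnnotationRecord | None = None
    notes: list[str] = []
    shared_stop_parents: list[AnnotationRecord] = []
    for f in annotation:
        if not f.interval.overlaps(sep_iv):
            continue
        same_strand = f.strand == orf.strand
        same_frame = same_strand and feature_frame(f) == orf.frame
        if same_frame and f.stop_codon_interval == GenomicInterval(
            orf.seq_id, orf.stop_interval.start, orf.stop_interval.end, orf.strand
        ):
            relations.append((f, "shared_stop"))
            if f.start == sep_iv.start and f.end == sep_iv.end:
                annotated_hit = f
            else:
                # CDS start strictly upstream of the chosen start: hidden start
                upstream = f.start < sep_iv.start if orf.strand == "+" else f.end > sep_iv.end
                if upstream:
                    shared_stop_parents.append(f)
        elif same_frame and f.interval.contains(sep_iv):
            relations.append((f, "same_frame_contained"))
        elif same_strand:
            relations.append((f, "same_strand_overlap"))
        else:
            relations.append((f, "opposite_strand_overlap"))

    if annotated_hit is not None:
        sep_class = "annotated"
        parent = annotated_hit
    elif shared_stop_parents:
        sep_class = "ISEP"
        shared_stop_parents.sort(key=lambda f: f.feature_id)
        parent = shared_stop_parents[0]
        if len(shared_stop_parents) > 1:
            notes.append("multiple shared-stop parents; chose lexically first feature_id")
    else:
        sep_class = "CSEP"
        if any(rel == "opposite_strand_overlap" for _, rel in relations):
            notes.append("isoform_like_overlap: overlaps an annotated feature on the opposite strand")

    return SepCall(
        orf=orf,
        chosen_start=bc.chosen_start,
        sep_class=sep_class,
        sep_interval=sep_iv,
        sep_length=bc.sep_length,
        parent_feature=parent,
        overlapping_features=tuple(relations),
        evidence=tuple(evidence),
        notes=tuple(notes),
    )


def compute_coverage(
    call: SepCall, assigned_peptides: Sequence[MappedLocus], genome: SequenceRecord
) -> CoverageProfile:
    """Residue coverage of a SEP by its assigned peptide loci.

    Coverage is the union of residue intervals (duplicates and order are
    irrelevant).  A SEP is full length when every residue is covered, or when
    residues 2..L are covered and the genomically encoded first residue is
    methionine or valine (N-terminal excision).
    """
    L = call.sep_length
    covered: set[int] = set()
    for locus in assigned_peptides:
        if not call.sep_interval.contains(locus.interval) or locus.strand != call.orf.strand:
            raise ValueError(
                f"assigned peptide {locus.peptide!r} at "
                f"{locus.interval.start}-{locus.interval.end} lies outside the SEP"
            )
        if call.orf.strand == "+":
            r = (locus.interval.start - call.sep_interval.start) // 3 + 1
        else:
            r = (call.sep_interval.end - locus.interval.end) // 3 + 1
        plen = locus.interval.length // 3
        if r < 1 or r + plen - 1 > L:
            raise ValueError("assigned peptide extends beyond the SEP residues")
        covered.update(range(r, r + plen))

    encoded_first = CODON_TO_AA.get(call.start_codon, "X")
    full = covered.issuperset(range(1, L + 1))
    excised = None
    if not full and covered.issuperset(range(2, L + 1)) and encoded_first in ("M", "V"):
        full = True
        excised = encoded_first
    return CoverageProfile(
        covered_residues=frozenset(covered),
        coverage_pct=reports.percent(len(covered), L),
        full_length=full,
        n_term_excised=excised,
    )


def summarize_seps(
    calls: Sequence[SepCall], profiles: Sequence[CoverageProfile] = ()
) -> dict[str, pd.DataFrame]:
    """Summary tables: length bins, class tallies, start codons, coverage."""
    out: dict[str, pd.DataFrame] = {}
    out["length_bins"] = reports.length_bin_table([c.sep_length for c in calls])
    class_counts = Counter(c.sep_class for c in calls)
    out["classes"] = pd.DataFrame(
        [
            {"sep_class": k, "count": class_counts.get(k, 0),
             "pct": reports.percent(class_counts.get(k, 0), len(calls))}
            for k in SEP_CLASSES
        ],
        columns=["sep_class", "count", "pct"],
    )
    if calls:
        out["start_codons"] = reports.start_codon_usage(
            Counter(c.start_codon for c in calls)
        )
    else:
        out["start_codons"] = pd.DataFrame(columns=["codon", "count", "pct", "bucket"])
    out["coverage_bins"] = reports.coverage_bin_table(
        [p.coverage_pct for p in profiles]
    )
    return out
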