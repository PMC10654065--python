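"""Class codes for novel transcripts and codable-RNA detection.

Novel transcripts are related to the annotation with cuffcompare-style class
codes: ``c`` (same-strand containment), ``o`` (same-strand partial overlap),
``x`` (opposite-strand overlap), ``p`` (non-overlapping but within a window
of an annotated gene, 2000 nt by default), ``u`` (intergenic, farther than
the window).  Precedence when a transcript overlaps features on both strands
is c > o > x > p > u; distances are measured edge-to-edge on the forward
axis, strand-agnostic.  A candidate RNA is "codable" when one of its
six-frame inter-stop translation segments carries a de novo-only peptide.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from . import reports
from .denovo import canonicalize
from .genome import AnnotationRecord
from .sepdb import TranscriptRecord, sixframe_segments


@dataclass(frozen=True)
class TranscriptClassCall:
    transcript_id: str
    class_code: str
    nearest_feature: str | None = None  # for u/p
    distance: int | None = None  # nt, edge-to-edge, for u/p
    overlap_feature: str | None = None  # for x/o/c


@dataclass(frozen=True)
class CodableMatch:
    transcript_id: str
    frame: str
    offset: int  # 0-based residue offset within the frame translation
    peptide: str
    mismatches: int


def exclude_long(
    transcripts: Iterable[TranscriptRecord], max_len: int = 500
) -> list[TranscriptRecord]:
    """Drop transcripts longer than ``max_len`` nt (inclusive retention)."""
    return [t for t in transcripts if t.length <= max_len]


def classify_transcript(
    transcript: TranscriptRecord,
    annotation: Sequence[AnnotationRecord],
    window: int = 2000,
) -> TranscriptClassCall:
    """Assign exactly one class code relative to the annotation."""
    iv = transcript.interval
    if iv is None:
        raise ValueError(f"transcript {transcript.id!r} has no coordinates")
    same_contained = None
    same_overlap = None
    opposite_overlap = None
    for f in annotation:
        if f.seq_id != iv.seq_id:
            continue
        if f.interval.overlaps(iv):
            if f.strand == iv.strand:
                if f.interval.contains(iv):
                    same_contained = same_contained or f
                else:
                    same_overlap = same_overlap or f
            else:
                opposite_overlap = opposite_overlap or f
    if same_contained is not None:
        return TranscriptClassCall(transcript.id, "c", overlap_feature=same_contained.feature_id)
    if same_overlap is not None:
        return TranscriptClassCall(transcript.id, "o", overlap_feature=same_overlap.feature_id)
    if opposite_overlap is not None:
        return TranscriptClassCall(transcript.id, "x", overlap_feature=opposite_overlap.feature_id)

    nearest: AnnotationRecord | None = None
    best = None
    for f in annotation:
        if f.seq_id != iv.seq_id:
            continue
        d = f.start - iv.end if f.start > iv.end else iv.start - f.end
        if best is None or d < best:
            best, nearest = d, f
    if nearest is not None and best is not None and 0 < best <= window:
        return TranscriptClassCall(transcript.id, "p", nearest_feature=nearest.feature_id, distance=best)
    return TranscriptClassCall(
        transcript.id,
        "u",
        nearest_feature=nearest.feature_id if nearest else None,
        distance=best,
    )


def classify_transcripts(
    transcripts: Iterable[TranscriptRecord],
    annotation: Sequence[AnnotationRecord],
    window: int = 2000,
) -> list[TranscriptClassCall]:
    return [classify_transcript(t, annotation, window) for t in transcripts]


def class_code_counts(calls: Sequence[TranscriptClassCall]):
    """Per-class tally table; its total equals the number of calls."""
    return reports.class_code_table(Counter(c.class_code for c in calls))


def find_codable(
    transcripts: Iterable[TranscriptRecord],
    denovo_only_peptides: Sequence[str],
    max_mismatch: int = 1,
) -> list[CodableMatch]:
    """Transcripts whose six-frame translation carries a de novo-only peptide.

    A match is a contiguous window of an inter-stop segment equal to the
    peptide under I/L equivalence with at most ``max_mismatch`` mismatches;
    frame and residue offset are reported.
    """
    keys = [(p, canonicalize(p)) for p in denovo_only_peptides]
    matches: list[CodableMatch] = []
    for t in transcripts:
        if t.sequence is None:
            raise ValueError(f"transcript {t.id!r} has no sequence")
        for frame_tag, seg_offset, segment in sixframe_segments(t.sequence):
            cseg = canonicalize(segment)
            for pep, cpep in keys:
                m = len(cpep)
                for w in range(0, len(cseg) - m + 1):
                    mm = sum(1 for k in range(m) if cseg[w + k] != cpep[k])
                    if mm <= max_mismatch:
                        matches.append(
                            CodableMatch(
                                transcript_id=t.id,
                                frame=frame_tag,
                                offset=seg_offset + w,
                                peptide=pep,
                                mismatches=mm,
                            )
                        )
    return matches
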