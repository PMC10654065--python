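"""Ungapped placement of candidate peptides in the six-frame translation.

Short de novo peptides (typically 7-20 aa) are matched against every frame
window of the genome with a mismatch budget under I/L equivalence, instead of
a gapped protein alignment: at these lengths an ungapped full-length scan is
exhaustive and preserves the identity/coverage acceptance thresholds.

Two frame-aware rules apply during matching:

* a window never spans an in-frame stop codon (ORF semantics);
* a window whose first codon is a configured start codon matches a peptide
  beginning with ``M`` either as encoded or as the initiator methionine
  (GTG/TTG/CTG starts are read as Met in the mature peptide).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .denovo import canonicalize
from .genome import (
    DEFAULT_START_CODONS,
    GenomicInterval,
    SequenceRecord,
    revcomp,
    translate,
)


@dataclass(frozen=True)
class MapperPolicy:
    max_mismatch: int = 1
    identity_min: float = 80.0
    coverage_min: float = 80.0
    len_min: int = 7
    start_set: tuple[str, ...] = DEFAULT_START_CODONS


@dataclass(frozen=True)
class MappedLocus:
    """One placement of a peptide in a translation frame of the genome.

    Coordinates are forward-axis over the matched codons; ``frame`` is the
    0/1/2 offset on the locus strand; ``identity`` and ``coverage`` are
    percentages (full-length ungapped placements always have coverage 100).
    """

    peptide: str
    seq_id: str
    interval: GenomicInterval
    strand: str
    frame: int
    mismatches: int
    identity: float
    coverage: float
    matched_translation: str
    unique: bool | None = None


def _frame_translations(genome: SequenceRecord):
    """Yield (strand, frame, aa string, strand-local sequence) for 6 frames."""
    L = len(genome.residues)
    for strand in ("+", "-"):
        s = genome.residues if strand == "+" else revcomp(genome.residues)
        for frame in range(3):
            n = (L - frame) // 3
            if n > 0:
                yield strand, frame, translate(s[frame : frame + 3 * n]), s


def map_peptide(
    peptide: str,
    genome: SequenceRecord,
    policy: MapperPolicy = MapperPolicy(),
) -> list[MappedLocus]:
    """Every ungapped full-length placement with mismatches <= the budget.

    Placements are reported on the forward axis in deterministic order
    (seq_id, start, strand, frame); no hit yields an empty list.
    """
    if len(peptide) < policy.len_min:
        raise ValueError(
            f"peptide {peptide!r} shorter than policy.len_min={policy.len_min}"
        )
    pep = canonicalize(peptide)
    m = len(pep)
    L = len(genome.residues)
    hits: list[MappedLocus] = []
    for strand, frame, aa, s in _frame_translations(genome):
        caa = canonicalize(aa)
        initiator = peptide[0] == "M"
        for w in range(0, len(aa) - m + 1):
            window = aa[w : w + m]
            if "*" in window:
                continue
            mismatches = 0
            for k in range(m):
                if caa[w + k] == pep[k]:
                    continue
                if (
                    k == 0
                    and initiator
                    and s[frame + 3 * w : frame + 3 * w + 3] in policy.start_set
                ):
                    continue  # initiator-M rendering of a start codon
                mismatches += 1
                if mismatches > policy.max_mismatch:
                    break
            if mismatches > policy.max_mismatch:
                continue
            a = frame + 3 * w + 1  # strand-local 1-based
            b = a + 3 * m - 1
            if strand == "+":
                f_start, f_end = a, b
            else:
                f_start, f_end = L + 1 - b, L + 1 - a
            hits.append(
                MappedLocus(
                    peptide=peptide,
                    seq_id=genome.seq_id,
                    interval=GenomicInterval(genome.seq_id, f_start, f_end, strand),
                    strand=strand,
                    frame=frame,
                    mismatches=mismatches,
                    identity=round(100.0 * (m - mismatches) / m, 2),
                    coverage=100.0,
                    matched_translation=window,
                )
            )
    hits.sort(key=lambda h: (h.seq_id, h.interval.start, h.strand, h.frame))
    return hits


def filter_hits(
    loci: Iterable[MappedLocus], policy: MapperPolicy = MapperPolicy()
) -> list[MappedLocus]:
    """Retain loci meeting the identity/coverage/mismatch acceptance rules."""
    return [
        l
        for l in loci
        if l.identity >= policy.identity_min
        and l.coverage >= policy.coverage_min
        and l.mismatches <= policy.max_mismatch
    ]


def resolve_multimappers(
    peptide: str, loci: Sequence[MappedLocus]
) -> tuple[list[MappedLocus], dict[str, int]]:
    """Flag each locus of one peptide as unique/ambiguous; keep all of them."""
    for l in loci:
        if l.peptide != peptide:
            raise ValueError("resolve_multimappers expects loci of one peptide")
    unique = len(loci) == 1
    flagged = [replace(l, unique=unique) for l in loci]
    counts = {
        "n_loci": len(flagged),
        "n_unique": sum(1 for l in flagged if l.unique),
        "n_ambiguous": sum(1 for l in flagged if not l.unique),
    }
    return flagged, counts
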