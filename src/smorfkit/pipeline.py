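"""End-to-end discovery: QC -> mapping -> back-correlation -> classification.

This is the library backing of the ``discover`` subcommand: it takes parsed
inputs and policies and returns every intermediate product (accepted and
rejected peptides, mapped loci, orphan loci, SEP calls, coverage profiles,
summary tables) so tests and reports can inspect each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import reports
from .classify import (
    BackCorrelation,
    CoverageProfile,
    SepCall,
    back_correlate,
    classify,
    compute_coverage,
    summarize_seps,
)
from .denovo import FilterPolicy, PeptideRecord, filter_peptides, remove_known
from .genome import AnnotationRecord, SequenceRecord
from .mapping import MappedLocus, MapperPolicy, filter_hits, map_peptide, resolve_multimappers


@dataclass
class DiscoveryResult:
    calls: list[SepCall]
    profiles: list[CoverageProfile]
    orphans: list[tuple[MappedLocus, str]]
    accepted: list[PeptideRecord]
    rejected: list[tuple[PeptideRecord, str]]
    removed_known: list[tuple[PeptideRecord, str]]
    unmapped: list[PeptideRecord]
    summaries: dict[str, pd.DataFrame]


def discover(
    genome: SequenceRecord,
    annotation: Sequence[AnnotationRecord],
    peptides: Sequence[PeptideRecord],
    qc_policy: FilterPolicy = FilterPolicy(),
    map_policy: MapperPolicy = MapperPolicy(),
    max_aa: int = 100,
    known_proteins=None,
) -> DiscoveryResult:
    """Run the full SEP discovery pipeline on in-memory inputs.

    Accepted peptides are mapped in all six frames; accepted loci are
    back-correlated to stop-to-stop ORFs; loci sharing an ORF become one SEP
    call whose start is chosen from the most upstream evidence locus, so the
    SEP contains every supporting peptide.
    """
    accepted, rejected = filter_peptides(peptides, qc_policy)
    removed: list[tuple[PeptideRecord, str]] = []
    if known_proteins is not None:
        accepted, removed = remove_known(accepted, known_proteins)

    unmapped: list[PeptideRecord] = []
    all_loci: list[MappedLocus] = []
    for rec in accepted:
        loci = filter_hits(map_peptide(rec.sequence, genome, map_policy), map_policy)
        if not loci:
            unmapped.append(rec)
            continue
        flagged, _counts = resolve_multimappers(rec.sequence, loci)
        all_loci.extend(flagged)

    # group loci by containing ORF (one SEP per stop-anchored ORF)
    orphans: list[tuple[MappedLocus, str]] = []
    groups: dict[tuple, list[tuple[MappedLocus, BackCorrelation]]] = {}
    for locus in all_loci:
        bc = back_correlate(locus, genome, start_set=map_policy.start_set, max_aa=max_aa)
        if bc.orphan:
            orphans.append((locus, bc.reason))
            continue
        groups.setdefault(bc.orf.key, []).append((locus, bc))

    calls: list[SepCall] = []
    profiles: list[CoverageProfile] = []
    for _key, members in sorted(groups.items()):
        # the most upstream locus (reading direction) constrains the start
        if members[0][1].orf.strand == "+":
            locus, bc = min(members, key=lambda lb: lb[0].interval.start)
        else:
            locus, bc = max(members, key=lambda lb: lb[0].interval.end)
        evidence = tuple(l for l, _ in members)
        call = classify(bc, annotation, len(genome.residues), evidence)
        calls.append(call)
        profiles.append(compute_coverage(call, evidence, genome))

    return DiscoveryResult(
        calls=calls,
        profiles=profiles,
        orphans=orphans,
        accepted=accepted,
        rejected=rejected,
        removed_known=removed,
        unmapped=unmapped,
        summaries=summarize_seps(calls, profiles),
    )


def calls_table(result: DiscoveryResult) -> pd.DataFrame:
    """Flat TSV-ready table of SEP calls with coverage columns."""
    rows = []
    for call, prof in zip(result.calls, result.profiles):
        rows.append(
            {
                "seq_id": call.orf.seq_id,
                "start": call.sep_interval.start,
                "end": call.sep_interval.end,
                "strand": call.orf.strand,
                "frame": call.orf.frame,
                "sep_class": call.sep_class,
                "start_codon": call.start_codon,
                "sep_length_aa": call.sep_length,
                "parent_feature": call.parent_feature.feature_id if call.parent_feature else "",
                "coverage_pct": prof.coverage_pct,
                "full_length": prof.full_length,
                "n_term_excised": prof.n_term_excised or "",
                "n_peptides": len(call.evidence),
                "peptides": ",".join(sorted({l.peptide for l in call.evidence})),
                "notes": ";".join(call.notes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id", "start", "end", "strand", "frame", "sep_class",
            "start_codon", "sep_length_aa", "parent_feature", "coverage_pct",
            "full_length", "n_term_excised", "n_peptides", "peptides", "notes",
        ],
    )


def calls_gff3(result: DiscoveryResult, path: str | Path) -> None:
    """Write called SEPs as a GFF3 track."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, call in enumerate(result.calls, 1):
            attrs = f"ID=sep{i:04d};sep_class={call.sep_class};start_codon={call.start_codon}"
            if call.parent_feature:
                attrs += f";parent_feature={call.parent_feature.feature_id}"
            fh.write(
                f"{call.orf.seq_id}\tsmorfkit\tCDS\t{call.sep_interval.start}"
                f"\t{call.sep_interval.end}\t.\t{call.orf.strand}\t0\t{attrs}\n"
            )
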