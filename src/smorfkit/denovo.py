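"""Parsing and quality control of de novo sequenced peptide tables.

The input is the export shape of a de novo engine: a delimited table with at
least a peptide-sequence column and an ALC (average local confidence, percent)
column, optionally a -10lgP database-search score, a b/y fragment-ion pair
count, and a sample id.  Modification annotations embedded in the sequence
string as parenthesized mass tags — e.g. ``M(+15.99)RFPGGGE`` — are split out
into a modification list.

Filtering follows a fixed criterion order and every rejection is reported
with the *first* criterion that failed: ALC, then length, then modification
state, then -10lgP, then b/y ion pairs.  Optional scores that are absent are
not penalized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_MOD_RE = re.compile(r"\(([^()]*)\)")

#: joint symbol for the isoleucine/leucine mass degeneracy
IL_JOINT = "J"
_IL_TRANS = str.maketrans("IL", IL_JOINT * 2)


@dataclass(frozen=True)
class PeptideRecord:
    """One de novo peptide observation with its quality metrics."""

    sequence: str
    alc: float
    neg10lgp: float | None = None
    modifications: tuple[str, ...] = ()
    by_ion_pairs: int | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - AA_ALPHABET:
            raise ValueError(f"invalid peptide sequence {self.sequence!r}")
        if not 0.0 <= self.alc <= 100.0:
            raise ValueError(f"ALC {self.alc} out of [0, 100]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterPolicy:
    """Quality thresholds for accepting a de novo peptide as a candidate.

    ``max_mismatch`` is carried here for convenience but enforced at mapping
    time ("mismatch numbers less than 2 aa", read literally as <= 1 and
    overridable).
    """

    alc_min: float = 80.0
    len_min: int = 7
    require_unmodified: bool = True
    neg10lgp_min: float = 20.0
    by_pairs_min: int = 3
    max_mismatch: int = 1


# column-name normalization: lowercase, strip units/punctuation
_COLUMN_ALIASES = {
    "peptide": "sequence",
    "sequence": "sequence",
    "alc": "alc",
    "alc%": "alc",
    "10lgp": "neg10lgp",
    "neg10lgp": "neg10lgp",
    "byionpairs": "by_ion_pairs",
    "bypairs": "by_ion_pairs",
    "sample": "sample_id",
    "sampleid": "sample_id",
    "ptm": "ptm",
    "modifications": "ptm",
}


def _normalize_column(name: str) -> str | None:
    key = re.sub(r"[^a-z0-9]", "", name.lower().replace("(%)", ""))
    return _COLUMN_ALIASES.get(key)


def split_modifications(raw: str) -> tuple[str, tuple[str, ...]]:
    """Strip parenthesized mass tags from a sequence string.

    Each tag is reported as ``<tag>@<residue index>`` where the index is the
    1-based position of the residue the tag follows (0 for a tag preceding
    the first residue, i.e. a terminal modification).
    """
    mods: list[str] = []
    plain: list[str] = []
    pos = 0
    while pos < len(raw):
        m = _MOD_RE.match(raw, pos)
        if m:
            mods.append(f"{m.group(1)}@{len(plain)}")
            pos = m.end()
        else:
            plain.append(raw[pos])
            pos += 1
    return "".join(plain).upper(), tuple(mods)


def parse_denovo_table(path: str | Path) -> list[PeptideRecord]:
    """Parse a de novo export (comma or tab delimited, auto-detected).

    Rows whose sequence cannot be interpreted as plain residues after tag
    stripping are skipped (and counted in a warning); missing mandatory
    columns are a hard error naming them.
    """
    import logging

    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    colmap: dict[str, str] = {}
    for col in df.columns:
        norm = _normalize_column(str(col))
        if norm and norm not in colmap.values():
            colmap[col] = norm
    df = df.rename(columns=colmap)
    missing = [c for c in ("sequence", "alc") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    records: list[PeptideRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        seq, mods = split_modifications(str(row["sequence"]).strip())
        if "ptm" in df.columns and not mods:
            ptm = row.get("ptm")
            if isinstance(ptm, str) and ptm.strip():
                mods = tuple(t.strip() for t in ptm.split(";") if t.strip())
        try:
            records.append(
                PeptideRecord(
                    sequence=seq,
                    alc=float(row["alc"]),
                    neg10lgp=(
                        float(row["neg10lgp"])
                        if "neg10lgp" in df.columns and pd.notna(row["neg10lgp"])
                        else None
                    ),
                    modifications=mods,
                    by_ion_pairs=(
                        int(row["by_ion_pairs"])
                        if "by_ion_pairs" in df.columns and pd.notna(row["by_ion_pairs"])
                        else None
                    ),
                    sample_id=(
                        str(row["sample_id"]) if "sample_id" in df.columns else ""
                    ),
                )
            )
        except ValueError:
            skipped += 1
    if skipped:
        logging.getLogger(__name__).warning(
            "%s: skipped %d row(s) with unparseable sequences", path, skipped
        )
    return records


def filter_peptides(
    records: Iterable[PeptideRecord], policy: FilterPolicy = FilterPolicy()
) -> tuple[list[PeptideRecord], list[tuple[PeptideRecord, str]]]:
    """Apply the quality filters; returns (accepted, rejections).

    Each rejection carries the first criterion that failed.  Accepted and
    rejected records together partition the input.
    """
    accepted: list[PeptideRecord] = []
    rejected: list[tuple[PeptideRecord, str]] = []
    for rec in records:
        if rec.alc < policy.alc_min:
            rejected.append((rec, f"alc<{policy.alc_min:g}"))
        elif len(rec) < policy.len_min:
            rejected.append((rec, f"length<{policy.len_min}"))
        elif policy.require_unmodified and rec.modifications:
            rejected.append((rec, "modified"))
        elif rec.neg10lgp is not None and rec.neg10lgp < policy.neg10lgp_min:
            rejected.append((rec, f"neg10lgp<{policy.neg10lgp_min:g}"))
        elif rec.by_ion_pairs is not None and rec.by_ion_pairs < policy.by_pairs_min:
            rejected.append((rec, f"by_ion_pairs<{policy.by_pairs_min}"))
        else:
            accepted.append(rec)
    return accepted, rejected


def canonicalize(sequence: str) -> str:
    """Matching key under the I/L mass degeneracy: I and L both become J."""
    return sequence.translate(_IL_TRANS)


def remove_known(
    records: Iterable[PeptideRecord],
    known_proteins: str | Path | Sequence[tuple[str, str]],
) -> tuple[list[PeptideRecord], list[tuple[PeptideRecord, str]]]:
    """Drop peptides occurring in any known protein (de novo-only survivors).

    A peptide is "known" when its canonicalized sequence is a contiguous
    substring of a canonicalized known protein.  Returns (novel, removed)
    where each removal names the matching protein id.
    """
    if isinstance(known_proteins, (str, Path)):
        proteins = [
            (rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(known_proteins), "fasta")
        ]
    else:
        proteins = [(pid, seq.upper()) for pid, seq in known_proteins]
    canon_proteins = [(pid, canonicalize(seq)) for pid, seq in proteins]

    novel: list[PeptideRecord] = []
    removed: list[tuple[PeptideRecord, str]] = []
    for rec in records:
        key = canonicalize(rec.sequence)
        hit = next((pid for pid, cseq in canon_proteins if key in cseq), None)
        if hit is None:
            novel.append(rec)
        else:
            removed.append((rec, hit))
    return novel, removed
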