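"""Synthetic fixture generation with a machine-readable truth manifest.

The generator emulates the study system: a high-GC (Streptomyces-like,
default GC 0.72) linear chromosome carrying annotated CDSs, annotated
smORFs, isoform SEPs hidden inside larger annotated CDSs (internal in-frame
start codons sharing the parent's stop), cryptic SEPs in intergenic space, a
noisy de novo peptide export, and novel transcripts engineered to every
class code.  Every planted element is recorded in a JSON truth manifest so
each pipeline stage can be scored against ground truth without any download.

Planted ORFs are built codon-by-codon: an in-frame stop codon is placed
immediately upstream of every planted start so the stop-to-stop segment
begins exactly at the planted start, and the region of an ISEP parent
upstream of the hidden start encodes no residue whose codon could spell a
start codon.  Background sequence is random at the configured GC and is
deliberately *not* scrubbed outside the planted windows, so background
smORFs exist as they would in a real genome; truth recovery is therefore
evaluated on planted elements only.

Identical (seed, config) pairs produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import (
    CODON_TO_AA,
    STOP_CODONS,
    AnnotationRecord,
    GenomicInterval,
    SequenceRecord,
    revcomp,
    write_annotation,
    write_fasta,
)
from .mapping import MapperPolicy, filter_hits, map_peptide

#: codon choices per amino acid (table 11 sense codons)
_CODON_CHOICES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _CODON_CHOICES.setdefault(_aa, ())
    _CODON_CHOICES[_aa] += (_codon,)

_START_SET = ("ATG", "GTG", "CTG", "TTG")
#: codon choices that can never spell a start codon
_SAFE_CHOICES = {
    aa: tuple(c for c in codons if c not in _START_SET)
    for aa, codons in _CODON_CHOICES.items()
}
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: residues none of whose codons is a start codon
AA_NO_START = "".join(a for a in AA20 if a not in "MVL")


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic fixture."""

    seed: int = 0
    genome_length: int = 20_000
    n_annotated_cds: int = 3
    n_planted_annotated_smorf: int = 2
    n_planted_isep: int = 2
    n_planted_csep: int = 2
    gc_fraction: float = 0.72
    peptide_noise: float = 0.3
    alc_true: tuple[float, float] = (85.0, 99.5)
    alc_decoy: tuple[float, float] = (60.0, 95.0)
    n_transcripts_per_class: int = 1
    seq_id: str = "chr"

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if min(
            self.n_annotated_cds,
            self.n_planted_annotated_smorf,
            self.n_planted_isep,
            self.n_planted_csep,
            self.n_transcripts_per_class,
        ) < 0:
            raise ValueError("all counts must be >= 0")


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    bases = np.array(list("GCAT"))
    p = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=n, p=p))


def _encode(rng: np.random.Generator, peptide: str, safe: bool) -> str:
    """Pick a codon per residue; with ``safe`` no codon may be a start codon."""
    choices = _SAFE_CHOICES if safe else _CODON_CHOICES
    out = []
    for aa in peptide:
        opts = choices[aa]
        if not opts:
            raise ValueError(f"residue {aa!r} cannot be encoded start-free")
        out.append(opts[rng.integers(len(opts))])
    return "".join(out)


def _rand_peptide(rng: np.random.Generator, n: int, alphabet: str = AA20) -> str:
    return "".join(alphabet[rng.integers(len(alphabet))] for _ in range(n))


def _frame_of(genome_length: int, strand: str, start: int, end: int) -> int:
    return (start - 1) % 3 if strand == "+" else (genome_length - end) % 3


def generate_genome(
    config: FixtureConfig,
) -> tuple[SequenceRecord, list[AnnotationRecord], dict]:
    """Build the genome, its annotation, and the truth manifest skeleton."""
    rng = np.random.default_rng([config.seed, 0])
    parts: list[str] = []
    cursor = 1  # 1-based position of the next free base
    elements: list[dict] = []
    annotation: list[AnnotationRecord] = []

    def emit(seq: str) -> int:
        nonlocal cursor
        start = cursor
        parts.append(seq)
        cursor += len(seq)
        return start

    def plant(kind: str, idx: int) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
        if kind in ("annotated_smorf", "CSEP"):
            length = int(rng.integers(20, 91))
            # the full-coverage demonstration SEP needs an M/V-encoding start
            starts = ("ATG", "GTG") if (kind == "annotated_smorf" and idx == 0) else ("ATG", "GTG", "TTG")
            start_codon = starts[rng.integers(len(starts))]
            body = _rand_peptide(rng, length - 1)
            orf_nt = start_codon + _encode(rng, body, safe=False) + stop
            encoded = CODON_TO_AA[start_codon] + body
            d = "TAA" + orf_nt if strand == "+" else revcomp("TAA" + orf_nt)
            ins = emit(d)
            if strand == "+":
                orf_start, orf_end = ins + 3, ins + len(d) - 1
            else:
                orf_start, orf_end = ins, ins + len(orf_nt) - 1
            elem = {
                "id": f"{kind.lower()}_{idx + 1}",
                "type": kind,
                "strand": strand,
                "start": orf_start,
                "end": orf_end,
                "start_codon": start_codon,
                "length_aa": length,
                "peptide": "M" + body,
                "encoded_peptide": encoded,
            }
            if kind == "annotated_smorf":
                fid = f"SM{idx + 1:05d}"
                annotation.append(
                    AnnotationRecord(config.seq_id, orf_start, orf_end, strand, fid, "CDS")
                )
                elem["parent_id"] = fid
            elements.append(elem)
        elif kind == "ISEP":
            parent_len = int(rng.integers(110, 141))
            isep_len = int(rng.integers(15, 61))
            h = parent_len - isep_len  # 0-based residue index of the hidden start
            hidden_codon = ("ATG", "GTG", "TTG")[rng.integers(3)]
            upstream = _rand_peptide(rng, h - 1, AA_NO_START)
            downstream = _rand_peptide(rng, isep_len - 1)
            orf_nt = (
                "ATG"
                + _encode(rng, upstream, safe=True)
                + hidden_codon
                + _encode(rng, downstream, safe=False)
                + stop
            )
            d = "TAA" + orf_nt if strand == "+" else revcomp("TAA" + orf_nt)
            ins = emit(d)
            if strand == "+":
                p_start, p_end = ins + 3, ins + len(d) - 1
                s_start, s_end = p_start + 3 * h, p_end
            else:
                p_start, p_end = ins, ins + len(orf_nt) - 1
                s_start, s_end = p_start, p_end - 3 * h
            fid = f"RS{idx + 1:05d}"
            annotation.append(
                AnnotationRecord(config.seq_id, p_start, p_end, strand, fid, "CDS")
            )
            elements.append(
                {
                    "id": f"isep_{idx + 1}",
                    "type": "ISEP",
                    "strand": strand,
                    "start": s_start,
                    "end": s_end,
                    "start_codon": hidden_codon,
                    "length_aa": isep_len,
                    "peptide": "M" + downstream,
                    "encoded_peptide": CODON_TO_AA[hidden_codon] + downstream,
                    "parent_id": fid,
                    "parent_start": p_start,
                    "parent_end": p_end,
                }
            )
        elif kind == "annotated_cds":
            length = int(rng.integers(110, 141))
            body = _rand_peptide(rng, length - 1)
            orf_nt = "ATG" + _encode(rng, body, safe=False) + stop
            d = "TAA" + orf_nt if strand == "+" else revcomp("TAA" + orf_nt)
            ins = emit(d)
            if strand == "+":
                orf_start, orf_end = ins + 3, ins + len(d) - 1
            else:
                orf_start, orf_end = ins, ins + len(orf_nt) - 1
            fid = f"CD{idx + 1:05d}"
            annotation.append(
                AnnotationRecord(config.seq_id, orf_start, orf_end, strand, fid, "CDS")
            )
            elements.append(
                {
                    "id": f"annotated_cds_{idx + 1}",
                    "type": "annotated_cds",
                    "strand": strand,
                    "start": orf_start,
                    "end": orf_end,
                    "start_codon": "ATG",
                    "length_aa": length,
                    "peptide": "M" + body,
                    "encoded_peptide": "M" + body,
                }
            )

    order = (
        [("annotated_cds", i) for i in range(config.n_annotated_cds)]
        + [("annotated_smorf", i) for i in range(config.n_planted_annotated_smorf)]
        + [("ISEP", i) for i in range(config.n_planted_isep)]
        + [("CSEP", i) for i in range(config.n_planted_csep)]
    )
    for kind, idx in order:
        emit(_random_background(rng, int(rng.integers(400, 601)), config.gc_fraction))
        plant(kind, idx)

    # far intergenic region (> 2000 nt from anything annotated) carrying the
    # codable-RNA cassette: stop / peptide codons / stop on the minus strand,
    # with a non-start first residue, so the peptide maps but is an orphan
    emit(_random_background(rng, 2600, config.gc_fraction))
    codable_pep = _rand_peptide(rng, 10, AA_NO_START)
    cassette_local = "TAA" + _encode(rng, codable_pep, safe=True) + "TAA"
    cassette_start = emit(revcomp(cassette_local))
    cassette_end = cassette_start + len(cassette_local) - 1
    emit(_random_background(rng, 400, config.gc_fraction))

    needed = cursor - 1
    if config.genome_length < needed:
        raise ValueError(
            f"genome_length {config.genome_length} too short for the requested "
            f"plants; minimum {needed}"
        )
    if config.genome_length > needed:
        emit(_random_background(rng, config.genome_length - needed, config.gc_fraction))

    residues = "".join(parts)
    genome = SequenceRecord(config.seq_id, residues)
    L = len(residues)
    for e in elements:
        e["frame"] = _frame_of(L, e["strand"], e["start"], e["end"])
    annotation.sort(key=lambda r: (r.seq_id, r.start))

    manifest = {
        "config": asdict(config),
        "genome": {"id": config.seq_id, "length": L, "residues": residues},
        "elements": elements,
        "codable_cassette": {
            "start": cassette_start,
            "end": cassette_end,
            "strand": "-",
            "peptide": codable_pep,
        },
        "annotation": [asdict(a) for a in annotation],
    }
    return genome, annotation, manifest


def _unique_on_genome(peptide: str, genome: SequenceRecord) -> bool:
    policy = MapperPolicy(max_mismatch=1, len_min=min(7, len(peptide)))
    return len(filter_hits(map_peptide(peptide, genome, policy), policy)) == 1


def generate_peptides(manifest: dict, config: FixtureConfig) -> pd.DataFrame:
    """Derive a de novo peptide export from the manifest.

    True peptides are 9-15 residue windows of the planted SEP translations
    (each SEP gets its N-terminal initiator window plus internal windows; the
    first annotated smORF is tiled over residues 2..L to exercise N-terminal
    excision); every true peptide is checked to map uniquely.  One true
    window is duplicated with an oxidation tag to exercise the modification
    filter.  Decoys are shuffles of true peptides, verified not to map, with
    ALC straddling the acceptance threshold.  Rows are appended to
    ``manifest["peptide_rows"]`` with their truth labels.
    """
    rng = np.random.default_rng([config.seed, 1])
    genome = SequenceRecord(manifest["genome"]["id"], manifest["genome"]["residues"])
    sep_elements = [
        e for e in manifest["elements"] if e["type"] in ("annotated_smorf", "ISEP", "CSEP")
    ]
    rows: list[dict] = []

    def add_row(display: str, truth: str, alc: float, lgp: float, modified: bool = False) -> None:
        rows.append(
            {
                "peptide": display,
                "truth": truth,
                "alc": round(float(alc), 1),
                "neg10lgp": round(float(lgp), 1),
                "modified": modified,
            }
        )

    def draw_alc(true: bool) -> float:
        lo, hi = config.alc_true if true else config.alc_decoy
        return rng.uniform(lo, hi)

    def checked_window(pep: str, lo: int, hi: int) -> str:
        """A window [lo, hi) of a SEP peptide, required to map uniquely."""
        window = pep[lo:hi]
        if not _unique_on_genome(window, genome):
            raise RuntimeError(
                f"derived peptide {window!r} is ambiguous on this genome; "
                "use a different seed or genome_length"
            )
        return window

    full_cov_id = None
    for e in sep_elements:
        pep = e["peptide"]  # initiator-rendered
        L = len(pep)
        if e["type"] == "annotated_smorf" and full_cov_id is None:
            # tile residues 2..L (1-based) to exercise N-terminal excision
            full_cov_id = e["id"]
            step, width = 8, 12
            r = 2
            while r <= L:
                lo = r - 1
                hi = min(L, lo + width)
                if hi - lo < 9:  # keep windows comfortably unique
                    lo = max(1, hi - 12)
                add_row(checked_window(pep, lo, hi), e["id"], draw_alc(True), rng.uniform(30, 60))
                if hi == L:
                    break
                r = lo + 1 + step
            continue
        # N-terminal window, starting at the initiator
        k = int(rng.integers(9, min(13, L) + 1))
        add_row(checked_window(pep, 0, k), e["id"], draw_alc(True), rng.uniform(30, 60))
        # one or two internal windows
        for _ in range(int(rng.integers(1, 3))):
            w = int(rng.integers(9, 14))
            if L - w - 1 <= 1:
                continue
            lo = int(rng.integers(1, L - w))
            add_row(checked_window(pep, lo, lo + w), e["id"], draw_alc(True), rng.uniform(30, 60))

    # a modified duplicate of one true window (rejected by the QC filter)
    if rows:
        src = rows[int(rng.integers(len(rows)))]
        seq = src["peptide"]
        add_row(seq[0] + "(+15.99)" + seq[1:], src["truth"], draw_alc(True), rng.uniform(30, 60), modified=True)

    n_true = len(rows)
    n_decoy = int(round(n_true * config.peptide_noise))
    made = 0
    while made < n_decoy:
        src = rows[int(rng.integers(n_true))]["peptide"].replace("(+15.99)", "")
        for _ in range(50):
            letters = list(src)
            rng.shuffle(letters)
            decoy = "".join(letters)
            policy = MapperPolicy(max_mismatch=1)
            if not filter_hits(map_peptide(decoy, genome, policy), policy):
                add_row(decoy, "decoy", draw_alc(False), rng.uniform(15, 45))
                made += 1
                break
        else:
            raise RuntimeError("could not shuffle a non-mapping decoy; change the seed")

    perm = rng.permutation(len(rows))
    rows = [rows[i] for i in perm]
    manifest["peptide_rows"] = rows
    return pd.DataFrame(
        {
            "Peptide": [r["peptide"] for r in rows],
            "ALC (%)": [r["alc"] for r in rows],
            "-10lgP": [r["neg10lgp"] for r in rows],
            "Sample": ["S1"] * len(rows),
        }
    )


def generate_transcripts(manifest: dict, config: FixtureConfig) -> list[dict]:
    """Engineer transcripts for every class code plus filter decoys.

    Per requested replicate: ``c`` inside a same-strand annotated CDS, ``o``
    straddling a CDS boundary on the same strand, ``x`` overlapping on the
    opposite strand, ``p`` within the 2000-nt window of a CDS without
    overlap, and ``u`` in the far intergenic region (the first ``u``
    transcript covers the codable cassette).  Decoys: one transcript longer
    than 500 nt and one at FPKM exactly 1.  Entries are appended to
    ``manifest["transcripts"]``.
    """
    rng = np.random.default_rng([config.seed, 2])
    ann = [AnnotationRecord(**a) for a in manifest["annotation"]]
    cds = [a for a in ann if a.feature_type == "CDS"]
    if not cds:
        raise ValueError("transcript generation needs at least one annotated CDS")
    cassette = manifest["codable_cassette"]
    out: list[dict] = []

    def flip(strand: str) -> str:
        return "-" if strand == "+" else "+"

    def add(tid: str, code: str | None, start: int, end: int, strand: str, fpkm: float, truth: str) -> None:
        out.append(
            {
                "id": tid,
                "class_code": code,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "fpkm": round(float(fpkm), 2),
                "truth": truth,
            }
        )

    for i in range(config.n_transcripts_per_class):
        f = cds[i % len(cds)]
        add(f"t_c_{i+1}", "c", f.start + 15 + 3 * i, f.start + 15 + 3 * i + 149, f.strand, rng.uniform(2, 50), "class")
        f = cds[(i + 1) % len(cds)]
        add(f"t_o_{i+1}", "o", f.start - 60 - 5 * i, f.start + 89, f.strand, rng.uniform(2, 50), "class")
        f = cds[(i + 2) % len(cds)]
        add(f"t_x_{i+1}", "x", f.start + 10 + 3 * i, f.start + 10 + 3 * i + 159, flip(f.strand), rng.uniform(2, 50), "class")
        f = cds[i % len(cds)]
        add(f"t_p_{i+1}", "p", f.end + 40 + 10 * i, f.end + 40 + 10 * i + 129, "+", rng.uniform(2, 50), "class")
        if i == 0:
            start = cassette["start"] - 20
            end = cassette["end"] + 20
        else:
            start = cassette["end"] + 60 + 40 * i
            end = start + 139
        add(f"t_u_{i+1}", "u", start, end, "+", rng.uniform(2, 50), "class")

    f = cds[0]
    add("t_long_decoy", None, f.end + 300, f.end + 300 + 620, "+", rng.uniform(2, 50), "decoy_long")
    add("t_fpkm_decoy", None, f.end + 40, f.end + 189, "+", 1.0, "decoy_fpkm")

    # record where the codable peptide sits in the carrier transcript's frames
    if config.n_transcripts_per_class > 0:
        from .denovo import canonicalize
        from .sepdb import sixframe_segments

        carrier = next(t for t in out if t["id"] == "t_u_1")
        tseq = manifest["genome"]["residues"][carrier["start"] - 1 : carrier["end"]]
        key = canonicalize(cassette["peptide"])
        for tag, seg_offset, segment in sixframe_segments(tseq):
            pos = canonicalize(segment).find(key)
            if pos >= 0:
                cassette["transcript_id"] = carrier["id"]
                cassette["expected_frame"] = tag
                cassette["expected_offset"] = seg_offset + pos
                break
        else:
            raise RuntimeError("codable cassette not recoverable from its carrier transcript")

    manifest["transcripts"] = out
    return out


def write_transcript_gtf(entries: Sequence[dict], seq_id: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in entries:
            attrs = f'transcript_id "{t["id"]}"; FPKM "{t["fpkm"]}";'
            fh.write(
                f"{seq_id}\tsmorfkit\ttranscript\t{t['start']}\t{t['end']}"
                f"\t.\t{t['strand']}\t.\t{attrs}\n"
            )


def generate_bundle(
    config: FixtureConfig, outdir: str | Path | None = None
) -> tuple[SequenceRecord, list[AnnotationRecord], pd.DataFrame, list[dict], dict]:
    """Generate the full fixture; optionally write it as plain-text files.

    Files written: ``genome.fasta``, ``annotation.gff3``, ``peptides.csv``,
    ``transcripts.gtf``, ``truth.json``.
    """
    genome, annotation, manifest = generate_genome(config)
    peptides = generate_peptides(manifest, config)
    transcripts = generate_transcripts(manifest, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([(genome.seq_id, genome.residues)], outdir / "genome.fasta")
        write_annotation(annotation, outdir / "annotation.gff3")
        peptides.to_csv(outdir / "peptides.csv", index=False)
        write_transcript_gtf(transcripts, config.seq_id, outdir / "transcripts.gtf")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return genome, annotation, peptides, transcripts, manifest
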