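"""Independent brute-force scanners used as oracles by the test suite.

These deliberately avoid the package's own translation/enumeration code:
complementation is a per-base dict walk, translation goes through
Bio.Seq.translate (table 11), and ORF/stop pairing is done by independently
indexing every codon position and pairing starts to the next stop.
"""

from bisect import bisect_right

from Bio.Seq import Seq

STARTS = ("ATG", "GTG", "CTG", "TTG")
STOPS = ("TAA", "TAG", "TGA")
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def naive_revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def bio_translate(nt: str) -> str:
    return str(Seq(nt).translate(table=11))


def _canon(aa: str) -> str:
    return aa.replace("I", "J").replace("L", "J")


def oracle_orfs(seq: str, starts=STARTS):
    """Every stop-anchored ORF as (strand, frame, stop_fwd, starts_fwd, pep).

    Each codon position is tested independently for start/stop identity; a
    start belongs to the nearest downstream in-frame stop (bisect pairing).
    """
    L = len(seq)
    grouped: dict[tuple, list] = {}
    strands = {"+": seq, "-": naive_revcomp(seq)}
    for strand, s in strands.items():
        for frame in range(3):
            stop_cis = []
            start_cis = []
            n = (L - frame) // 3
            for ci in range(n):
                codon = s[frame + 3 * ci : frame + 3 * ci + 3]
                if codon in STOPS:
                    stop_cis.append(ci)
                elif codon in starts:
                    start_cis.append((ci, codon))
            for ci, codon in start_cis:
                j = bisect_right(stop_cis, ci)
                if j < len(stop_cis):
                    grouped.setdefault((strand, frame, stop_cis[j]), []).append((ci, codon))

    out = set()
    for (strand, frame, stop_ci), cands in grouped.items():
        cands.sort()
        s = strands[strand]

        def fwd(ci):
            a = frame + 3 * ci + 1
            return (a, a + 2) if strand == "+" else (L + 1 - (a + 2), L + 1 - a)

        first = cands[0][0]
        coding = s[frame + 3 * first : frame + 3 * stop_ci]
        pep = "M" + bio_translate(coding[3:])
        out.add(
            (
                strand,
                frame,
                fwd(stop_ci),
                tuple((fwd(ci)[0], codon) for ci, codon in cands),
                pep,
            )
        )
    return out


def orf_record_key(rec):
    """Project an OrfRecord onto the oracle tuple shape."""
    return (
        rec.strand,
        rec.frame,
        (rec.stop_interval.start, rec.stop_interval.end),
        tuple((c.interval.start, c.codon) for c in rec.candidate_starts),
        rec.peptide,
    )


def oracle_map(peptide: str, seq: str, max_mm: int = 1, starts=STARTS):
    """Every full-length ungapped placement as (strand, frame, start, end, mm)."""
    m = len(peptide)
    L = len(seq)
    cp = _canon(peptide)
    hits = set()
    for strand in "+-":
        s = seq if strand == "+" else naive_revcomp(seq)
        for frame in range(3):
            n = (L - frame) // 3
            if n < m:
                continue
            aa = bio_translate(s[frame : frame + 3 * n])
            caa = _canon(aa)
            for w in range(n - m + 1):
                if "*" in aa[w : w + m]:
                    continue
                mm = 0
                for k in range(m):
                    if caa[w + k] == cp[k]:
                        continue
                    if k == 0 and peptide[0] == "M" and s[frame + 3 * w : frame + 3 * w + 3] in starts:
                        continue
                    mm += 1
                if mm <= max_mm:
                    a = frame + 3 * w + 1
                    b = a + 3 * m - 1
                    fs, fe = (a, b) if strand == "+" else (L + 1 - b, L + 1 - a)
                    hits.add((strand, frame, fs, fe, mm))
    return hits


def mapped_locus_key(locus):
    return (
        locus.strand,
        locus.frame,
        locus.interval.start,
        locus.interval.end,
        locus.mismatches,
    )


def random_dna(rng, n: int, gc: float = 0.6) -> str:
    import numpy as np

    bases = np.array(list("GCAT"))
    p = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=n, p=p))
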