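# Methods

This note documents the models, conventions, parameter choices, and known
limitations behind `smorfkit`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and translation conventions

All genomic coordinates are 1-based inclusive on the forward axis with an
explicit strand flag; minus-strand features printed high-to-low by other
tools are normalized on ingest (`GenomicInterval.normalized`). Chromosomes
are treated as linear — *Streptomyces* chromosomes are linear, so no ORF
wraps an origin. Ingest normalization maps lowercase to uppercase and U to
T; anything outside `A/C/G/T/N` is rejected with the offending characters
named. Translation uses NCBI table 11. A codon containing `N` translates to
`X` and is conservatively disqualified from being a start or stop. Any
configured start codon (ATG/GTG/CTG/TTG by default) may be rendered as the
initiator methionine; the genomically encoded form (V for GTG, L for
TTG/CTG) is always retrievable by translating without the initiator flag,
and is what the N-terminal-excision rule inspects.

## ORF model

Candidate ORFs follow the stop-to-stop principle: within each of the six
frames, the segment between consecutive in-frame stop codons (or from the
sequence start to the first stop) defines one potential ORF per terminating
stop, with every in-frame start codon in the segment recorded as a
candidate start, furthest-upstream first. ORFs truncated by the sequence
end (no stop codon) are excluded: a SEP must map to a complete ORF.
Nested starts sharing a stop are one record, because downstream hidden-start
analysis needs the full candidate list.

The size filter interprets "≤300 bases" as the ORF span *including* the
stop codon — forced by the arithmetic of the 300-nt/99-aa worked example (a
span of 100 codons encodes 99 residues). A 100-aa peptide therefore
occupies 303 nt, so the nucleotide and amino-acid filters are not
interchangeable; both are exposed (`mode="nt" | "aa" | "either" | "both"`),
with the amino-acid cap (≤100 aa) the default. The filter applies to the
maximal ORF of each record; selecting a shorter start *under* the cap is
deliberately not done here but at back-correlation time, where peptide
evidence constrains the choice. Database identity is the locus
(seq_id, strand, stop codon), not the peptide sequence, so paralogous
smORFs survive deduplication.

The start-codon usage summary buckets ATG, CTG, GTG, and TTG as
"canonical"; everything else is "other".

## Peptide QC and matching

The QC filter applies, in order: ALC ≥80 %, length ≥7, no modification,
−10lgP ≥20, ≥3 b/y ion pairs; the first failing criterion is reported per
rejection, and optional scores that are absent are not penalized (the
−10lgP score belongs to the database-search route and the b/y-pair count to
manually inspected spectra). "Mismatch numbers less than 2 aa" is read
literally as ≤1 mismatch and enforced at mapping time; the cap is
configurable for anyone preferring ≤2.

Mapping replaces a gapped protein search with an exhaustive ungapped
full-length scan of all six frame translations under I/L equivalence (both
residues become the joint symbol `J`). For 7–20-residue peptides this scan
is complete — every placement with at most the mismatch budget is found —
so no scoring-matrix or E-value model is needed; the identity ≥80 % and
coverage ≥80 % acceptance thresholds are preserved (full-length ungapped
placements always have coverage 100). Two frame-aware rules apply: a window
never spans an in-frame stop, and a window whose first codon is a
configured start codon matches a peptide-initial M either as encoded or as
the initiator. Partial (local) placements are not supported; a peptide that
only partially overlaps a frame segment simply does not match.

Novelty filtering against a known-protein FASTA is exact substring matching
under I/L equivalence. This replaces a homology search against a remote
database and is strictly more conservative about declaring a peptide
"known": only a literal (I/L-equivalent) occurrence removes it.

The cross-species "predicted SEPome" projection uses the same direct-match
contract: a model-strain database entry transfers to a target genome when
it occurs in the target's six-frame translation at ≥80 % identity over
≥80 % of its length.

## Back-correlation and the chosen start

An accepted locus is resolved to the stop-to-stop ORF of its strand and
frame. Candidate starts are restricted to those at or upstream of the
peptide; the chosen start is the **furthest upstream candidate whose SEP
length does not exceed the 100-aa cap**. This is the least arbitrary
deterministic rule consistent with reported single SEP lengths, and it
reproduces both worked-example geometries: an N-terminal peptide on an ATG
of a 300-nt ORF yields a 99-aa SEP, and a peptide in the C-terminal window
of a >100-aa annotated frame resolves to the internal (hidden) start
because the annotated ATG exceeds the cap. Loci with no usable start, or in
a frame segment with no downstream stop, are flagged orphans, not calls.
When several peptides support one ORF, the most upstream locus constrains
the start, so the SEP contains all of its evidence.

## Classification

* `annotated` requires coincidence of **both** the chosen start and the stop
  with an annotated CDS; stop-only coincidence with an internal start is
  precisely the hidden-start concept and is `ISEP`.
* `ISEP` requires a same-strand, same-frame CDS sharing the stop codon with
  the chosen start strictly internal. Ties between duplicate shared-stop
  CDSs are broken by lexical feature id and flagged.
* `CSEP` is everything else. All overlap relations (same-frame containment,
  shared stop, same-strand overlap, opposite-strand overlap) are recorded
  regardless of class; a CSEP overlapping an annotated gene on the opposite
  strand additionally carries an `isoform_like_overlap` note, because such
  cases are sometimes reported as isoforms even though the two ORFs are
  distinct — the classifier follows the positional definitions and surfaces
  the ambiguity instead of guessing.

Coverage is the union of residue intervals of assigned peptides (order- and
duplication-invariant). A SEP is full length when residues 1..L are covered
or when residues 2..L are covered and the genomically encoded first residue
is M or V (N-terminal excision); the excised residue is reported.

## Transcript class codes

Classes partition the retained transcript set with precedence
c > o > x > p > u: same-strand containment beats same-strand partial
overlap beats opposite-strand overlap; non-overlapping transcripts are `p`
within 2000 nt of the nearest feature (edge-to-edge on the forward axis,
strand-agnostic, a deliberate choice since no strand rule is stated for
proximity) and `u` beyond it. Transcripts longer than 500 nt are excluded
before classification, as are transcripts at FPKM ≤1 (unexpressed
assemblies). A retained transcript is "codable" when a six-frame inter-stop
segment contains a de novo-only peptide under I/L equivalence within the
mismatch budget; the frame and residue offset are reported and re-translate
to the peptide.

## Synthetic fixtures: what they emulate, and what they do not

`FixtureConfig` defaults define the study conditions: a 20-kb linear
chromosome at GC 0.72 (Streptomyces-like), 3 background annotated CDSs of
110–140 aa, 2 annotated smORFs (20–90 aa), 2 ISEPs (15–60 aa) hidden inside
>100-aa parents, 2 intergenic CSEPs, 1 transcript per class code, and a
decoy fraction of 0.3 with true-peptide ALC ~ U(85, 99.5) and decoy ALC ~
U(60, 95) straddling the 80 % threshold. True peptides are 9–15-residue
windows of planted SEPs (longer than the 7-aa QC floor so chance collisions
with the background are vanishingly rare; each window is verified to map
uniquely at generation time). Decoys are residue shuffles verified *not* to
map. Parent CDSs are built codon-by-codon so the region upstream of a
hidden start contains no start-codon spelling, and an in-frame stop is
placed immediately before every planted start so the chosen-start rule has
a unique correct answer. Background sequence is scrubbed only inside
planted windows: background smORFs exist, as in real genomes, and truth
recovery is scored on planted elements only.

The generator does not simulate mass spectra, retention times, fragment
ions, sequencing errors within true peptides, or spliced transcripts.
Passing recovery tests therefore demonstrates the correctness of the
coordinate logic, filters, and classification rules under realistic
composition — not the behaviour of a de novo sequencer on real spectra.

## Numerical and scale choices

All percentages flow through one rounding helper (two decimals by default;
one decimal or integers where the corresponding published figure prints
them). Randomized suites use fixed seeds; hypothesis runs derandomized.
Oracle-equivalence suites compare against independently written brute-force
scanners (per-base complementation, Bio.Seq translation, bisect-paired
stop indexing) on ~1000 random sequences of 60–1500 nt plus a handful at
5 kb — sizes chosen so the whole suite completes in well under a minute
while covering every frame/strand/boundary geometry; the acceptance script
uses 400 (enumeration) and 300 (mapping) sequences.

## Known limitations

* No gapped or partial peptide placement; tBLASTn-style local hits with
  coverage <100 % cannot arise.
* Bacterial contiguous CDSs only; no spliced gene models.
* No coding-potential scoring (Prodigal-style confidence), RBS motifs,
  functional annotation, or differential-abundance statistics.
* FPKM is consumed as an input field; no quantification is performed.
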