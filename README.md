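# smorfkit

Peptidogenomic discovery of smORF-encoded peptides (SEPs) for non-model
bacteria such as high-GC *Streptomyces*.

Small open reading frames (smORFs, ≤100 codons) are routinely discarded by
annotation pipelines, yet the microproteins they encode regulate gene
expression, stress responses, and secondary metabolism. When no curated
protein database exists, peptide evidence from de novo sequencing can be
correlated directly with the genome instead. `smorfkit` implements that
workflow as a reusable toolkit:

1. **smORF database construction** — enumerate every stop-codon-to-stop-codon
   ORF in all six frames with alternative bacterial start codons
   (ATG/GTG/CTG/TTG; stops TAA/TAG/TGA; NCBI translation table 11) and keep
   ORFs encoding ≤100 aa (or spanning ≤300 nt, including the stop codon).
2. **Transcript-derived SEP databases** — filter assembled transcripts to
   small RNAs (FPKM > 1, length ≤300 nt), six-frame translate them into
   inter-stop segments, and merge databases with source provenance.
3. **De novo peptide QC** — parse a PEAKS-style export and keep peptides
   with ALC ≥80 %, length ≥7, no post-translational modification, −10lgP ≥20
   when present, and (when flagged) ≥3 b/y fragment-ion pairs. Isoleucine
   and leucine are treated as equivalent during all matching.
4. **Peptide-to-genome back-correlation** — place each surviving peptide in
   the six-frame translation (ungapped, full length, ≤1 mismatch, identity
   and coverage ≥80 %), resolve its containing stop-to-stop ORF, and choose
   the furthest-upstream in-frame start codon that keeps the SEP within the
   100-aa cap.
5. **SEP classification** — `annotated` (start and stop coincide with an
   annotated CDS), `ISEP` (isoform SEP: a hidden internal start codon
   sharing an annotated CDS's stop — an N-terminally truncated isoform), or
   `CSEP` (cryptic SEP: intergenic, different frame, or opposite strand).
   Sequence coverage is computed per SEP, with full-length calls allowing
   N-terminal methionine/valine excision.
6. **Novel transcript classification** — cuffcompare-style class codes
   relative to the annotation (`c` contained, `o` same-strand overlap, `x`
   opposite-strand overlap, `p` within 2000 nt, `u` intergenic), plus
   detection of "codable" RNAs carrying de novo-only peptides in any frame.

A synthetic fixture generator (`smorfkit.simulate`) emulates the study
system — a high-GC chromosome with planted annotated smORFs, isoform SEPs,
cryptic SEPs, noisy de novo peptide tables, and transcripts of every class
code — and writes a JSON truth manifest so every stage is testable offline.

## Worked example

Simulate a fixture and run discovery:

```sh
smorfkit simulate --seed 11 --out demo/fix
smorfkit discover --genome demo/fix/genome.fasta \
    --annotation demo/fix/annotation.gff3 \
    --peptides demo/fix/peptides.csv --out demo/run
```

The log reports each stage:

```
INFO smorfkit: parsed 25 peptide rows
INFO smorfkit: QC: 21 accepted, 4 rejected; 0 known removed; 3 unmapped; 6 calls, 0 orphan loci
```

21 of 25 peptide rows pass QC (rejections: low ALC or a modification tag);
3 accepted rows are decoys that map nowhere; the rest resolve into 6 SEP
calls. `demo/run/calls.tsv` (abridged):

```
start  end   strand  sep_class  start_codon  sep_length_aa  parent_feature  coverage_pct  full_length  n_term_excised
3646   3840  +       annotated  GTG          64             SM00002         37.5          False
4560   4661  +       ISEP       ATG          33             RS00001         78.79         False
5430   5585  +       ISEP       TTG          51             RS00002         27.45         False
6557   6703  +       CSEP       TTG          48                             54.17         False
3068   3181  -       annotated  ATG          37             SM00001         97.3          True         M
6036   6131  -       CSEP       ATG          31                             51.61         False
```

Each row is one classified SEP: the two `ISEP` calls start at hidden
internal start codons and share their stop with the annotated parent CDS
(`RS…`); the two `CSEP` calls sit in unannotated sequence; the 37-aa
annotated smORF is covered over residues 2–37 and is called full length
with its initiator methionine excised (`n_term_excised = M`). Transcript
class codes come from `smorfkit transcripts`, and
`smorfkit report --calls demo/run/calls.tsv --out summary.yaml` re-derives
the length-bin, start-codon, and coverage summaries.

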