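import json

import pytest

from conftest import records_from_table
from smorfkit import pipeline
from smorfkit.denovo import filter_peptides
from smorfkit.genome import GenomicInterval, SequenceRecord
from smorfkit.mapping import MapperPolicy, filter_hits, map_peptide
from smorfkit.orfs import enumerate_orfs
from smorfkit.sepdb import TranscriptRecord, filter_transcripts, transcript_sequence
from smorfkit.simulate import FixtureConfig, generate_bundle, generate_genome
from smorfkit.transcripts import class_code_counts, classify_transcripts, exclude_long, find_codable


def transcript_records(genome, trans):
    out = []
    for t in trans:
        iv = GenomicInterval(genome.seq_id, t["start"], t["end"], t["strand"])
        out.append(
            TranscriptRecord(id=t["id"], interval=iv, fpkm=t["fpkm"],
                             sequence=transcript_sequence(genome, iv))
        )
    return out


class TestDeterminism:
    def test_byte_identical_reruns(self, tmp_path):
        cfg = FixtureConfig(seed=3, genome_length=16_000)
        a, b = tmp_path / "a", tmp_path / "b"
        generate_bundle(cfg, a)
        generate_bundle(cfg, b)
        for name in ("genome.fasta", "annotation.gff3", "peptides.csv", "transcripts.gtf", "truth.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes(), name

    def test_different_seeds_differ(self):
        g1, _, _ = generate_genome(FixtureConfig(seed=1))
        g2, _, _ = generate_genome(FixtureConfig(seed=2))
        assert g1.residues != g2.residues


class TestSoundness:
    def test_too_short_genome_reports_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            generate_genome(FixtureConfig(seed=1, genome_length=1000))

    def test_zero_plants_only_background_cds(self):
        _, ann, man = generate_genome(
            FixtureConfig(seed=1, n_planted_annotated_smorf=0, n_planted_isep=0, n_planted_csep=0)
        )
        assert all(e["type"] == "annotated_cds" for e in man["elements"])
        assert len(ann) == 3

    def test_planted_elements_are_valid_orfs(self, bundle):
        genome, ann, peps, trans, man = bundle
        orfs_by_key = {
            (o.strand, o.orf_interval.start, o.orf_interval.end): o
            for o in enumerate_orfs(genome)
        }
        for e in man["elements"]:
            if e["type"] == "ISEP":
                continue  # ISEP spans are sub-ORFs of their parent
            key = (e["strand"], e["start"], e["end"])
            # the planted span must be a complete enumerated ORF (span = start..stop)
            match = [o for o in orfs_by_key.values()
                     if o.strand == e["strand"]
                     and o.orf_interval.contains(GenomicInterval("chr", e["start"], e["end"], e["strand"]))]
            assert match, e["id"]

    def test_gc_content_near_configured(self, bundle):
        genome, *_ = bundle
        gc = sum(genome.residues.count(b) for b in "GC") / len(genome.residues)
        assert 0.60 < gc < 0.80

    def test_derived_peptides_map_uniquely(self, bundle):
        genome, ann, peps, trans, man = bundle
        policy = MapperPolicy(max_mismatch=1)
        for row in man["peptide_rows"]:
            if row["truth"] in ("decoy",) or row["modified"]:
                continue
            hits = filter_hits(map_peptide(row["peptide"], genome, policy), policy)
            assert len(hits) == 1, row

    def test_decoys_do_not_map(self, bundle):
        genome, ann, peps, trans, man = bundle
        policy = MapperPolicy(max_mismatch=1)
        for row in man["peptide_rows"]:
            if row["truth"] == "decoy":
                assert not filter_hits(map_peptide(row["peptide"], genome, policy), policy)


class TestEndToEndRecovery:
    def test_zero_noise_calls_equal_manifest(self, zero_noise_bundle):
        genome, ann, peps, trans, man = zero_noise_bundle
        res = pipeline.discover(genome, ann, records_from_table(peps))
        truth = {
            (e["type"].replace("annotated_smorf", "annotated"),
             e["start"], e["end"], e["strand"], e["start_codon"], e["length_aa"])
            for e in man["elements"]
            if e["type"] in ("annotated_smorf", "ISEP", "CSEP")
        }
        got = {
            (c.sep_class.replace("annotated", "annotated"),
             c.sep_interval.start, c.sep_interval.end, c.orf.strand, c.start_codon, c.sep_length)
            for c in res.calls
        }
        assert got == truth
        assert not res.orphans

    def test_full_coverage_element_shows_nterm_excision(self, zero_noise_bundle):
        genome, ann, peps, trans, man = zero_noise_bundle
        res = pipeline.discover(genome, ann, records_from_table(peps))
        target = next(e for e in man["elements"] if e["type"] == "annotated_smorf")
        prof = next(
            p for c, p in zip(res.calls, res.profiles)
            if (c.sep_interval.start, c.sep_interval.end) == (target["start"], target["end"])
        )
        assert prof.full_length
        assert prof.n_term_excised == target["encoded_peptide"][0]

    def test_modified_duplicate_rejected_by_qc(self, bundle):
        genome, ann, peps, trans, man = bundle
        accepted, rejected = filter_peptides(records_from_table(peps))
        reasons = [r for _, r in rejected]
        assert "modified" in reasons


class TestTranscriptRecovery:
    def test_class_codes_recover_manifest(self, bundle):
        genome, ann, peps, trans, man = bundle
        recs = transcript_records(genome, trans)
        kept = exclude_long([t for t in recs if t.fpkm > 1], 500)
        calls = classify_transcripts(kept, ann)
        counts = class_code_counts(calls)
        n = man["config"]["n_transcripts_per_class"]
        assert dict(zip(counts["class_code"], counts["count"])) == {
            "u": n, "p": n, "x": n, "o": n, "c": n,
        }
        by_id = {c.transcript_id: c.class_code for c in calls}
        for t in man["transcripts"]:
            if t["truth"] == "class":
                assert by_id[t["id"]] == t["class_code"]

    def test_decoys_removed_by_their_filters(self, bundle):
        genome, ann, peps, trans, man = bundle
        recs = transcript_records(genome, trans)
        long_decoy = next(t for t in recs if t.id == "t_long_decoy")
        fpkm_decoy = next(t for t in recs if t.id == "t_fpkm_decoy")
        assert long_decoy not in exclude_long(recs, 500)
        assert fpkm_decoy not in filter_transcripts(recs, fpkm_min=1.0, max_len=10_000)

    def test_codable_cassette_found_in_stated_frame(self, bundle):
        genome, ann, peps, trans, man = bundle
        cass = man["codable_cassette"]
        recs = transcript_records(genome, trans)
        carrier = [t for t in recs if t.id == cass["transcript_id"]]
        matches = find_codable(carrier, [cass["peptide"]])
        assert any(
            m.frame == cass["expected_frame"] and m.offset == cass["expected_offset"]
            for m in matches
        )
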