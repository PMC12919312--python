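"""Transcript loading, seed-site scanning and target sets."""

import re

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from dualseed.isomir import IsomiR, MatureMiRNA, make_extended_motif
from dualseed.scan import (
    ScanError,
    TranscriptRecord,
    annotate_extendable,
    build_target_set,
    gene_exon_lengths,
    load_transcripts,
    region_sequence,
    scan_sites,
    select_representative,
)

SHRNA_FRAGMENT = "CTACCTGCACGAACAGCACTTTGTT"

dna_seq = st.text(alphabet="ACGT", min_size=0, max_size=200)


def naive_scan(sequence: str, motif: str) -> list[int]:
    return [
        i + 1
        for i in range(len(sequence) - len(motif) + 1)
        if sequence[i : i + len(motif)] == motif
    ]


def write_genome(tmp_path, contigs: dict[str, str]):
    path = tmp_path / "genome.fa"
    path.write_text("".join(f">{name}\n{seq}\n" for name, seq in contigs.items()))
    return path


def write_gtf(tmp_path, rows):
    path = tmp_path / "toy.gtf"
    lines = []
    for seqid, ftype, start, end, strand, gid, tid in rows:
        attrs = f'gene_id "{gid}"; transcript_id "{tid}"; gene_name "{gid}";'
        lines.append(f"{seqid}\ttoy\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}")
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadTranscripts:
    def test_plus_strand_two_exons(self, tmp_path):
        contig = "AAACCCGGGTTTACGTACGTACGTAAACCCGGGTTT"
        fasta = write_genome(tmp_path, {"chr1": contig})
        gtf = write_gtf(
            tmp_path,
            [("chr1", "exon", 3, 8, "+", "G1", "T1"), ("chr1", "exon", 21, 30, "+", "G1", "T1")],
        )
        (rec,) = load_transcripts(fasta, gtf)
        assert rec.spliced_sequence == contig[2:8] + contig[20:30]
        assert rec.utr3_interval is None  # no CDS annotated

    def test_minus_strand_is_reverse_complement(self, tmp_path):
        contig = "AAACCCGGGTTTACGTACGTACGTAAACCCGGGTTT"
        fasta = write_genome(tmp_path, {"chr1": contig})
        plus = write_gtf(tmp_path, [("chr1", "exon", 3, 8, "+", "G1", "T1"),
                                    ("chr1", "exon", 21, 30, "+", "G1", "T1")])
        (rec_plus,) = load_transcripts(fasta, plus)
        minus = write_gtf(tmp_path, [("chr1", "exon", 3, 8, "-", "G1", "T1"),
                                     ("chr1", "exon", 21, 30, "-", "G1", "T1")])
        (rec_minus,) = load_transcripts(fasta, minus)
        assert rec_minus.spliced_sequence == str(
            Seq(rec_plus.spliced_sequence).reverse_complement()
        )

    def test_stop_codon_places_utr3(self, tmp_path):
        contig = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 nt, single exon
        fasta = write_genome(tmp_path, {"chr1": contig})
        gtf = write_gtf(
            tmp_path,
            [
                ("chr1", "exon", 1, 30, "+", "G1", "T1"),
                ("chr1", "CDS", 1, 15, "+", "G1", "T1"),
                ("chr1", "stop_codon", 16, 18, "+", "G1", "T1"),
            ],
        )
        (rec,) = load_transcripts(fasta, gtf)
        # stop codon starts at spliced offset 15 -> UTR = [18, 30)
        assert rec.utr3_interval == (18, 30)
        assert region_sequence(rec, "utr3") == contig[18:30]

    def test_utr3_from_cds_when_stop_missing(self, tmp_path):
        contig = "ACGTACGTACGTACGTACGTACGTACGTAC"
        fasta = write_genome(tmp_path, {"chr1": contig})
        gtf = write_gtf(
            tmp_path,
            [("chr1", "exon", 1, 30, "+", "G1", "T1"), ("chr1", "CDS", 1, 15, "+", "G1", "T1")],
        )
        (rec,) = load_transcripts(fasta, gtf)
        assert rec.utr3_interval == (18, 30)

    def test_transcript_mode_fasta(self, tmp_path):
        # FASTA keyed by transcript id: sequence taken verbatim
        fasta = tmp_path / "tx.fa"
        fasta.write_text(">T1.2\nACGTACGTACGTACGTACGTACGTACGTAC\n")
        gtf = write_gtf(
            tmp_path,
            [
                ("chr9", "exon", 101, 130, "+", "G1", "T1.2"),
                ("chr9", "stop_codon", 116, 118, "+", "G1", "T1.2"),
            ],
        )
        (rec,) = load_transcripts(fasta, gtf)
        assert rec.transcript_id == "T1"  # version stripped
        assert rec.utr3_interval == (18, 30)

    def test_unresolvable_transcript_warns_and_skips(self, tmp_path):
        fasta = write_genome(tmp_path, {"chr1": "ACGT" * 10})
        gtf = write_gtf(tmp_path, [("chr1", "exon", 1, 12, "+", "G1", "T1"),
                                   ("chrX", "exon", 1, 12, "+", "G2", "T2")])
        with pytest.warns(UserWarning, match="T2"):
            records = load_transcripts(fasta, gtf)
        assert [r.transcript_id for r in records] == ["T1"]

    def test_malformed_gtf_line_reports_line_number(self, tmp_path):
        fasta = write_genome(tmp_path, {"chr1": "ACGT" * 10})
        gtf = tmp_path / "bad.gtf"
        gtf.write_text('chr1\ttoy\texon\t1\t12\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
                       "chr1\ttoy\texon\n")
        with pytest.raises(ScanError, match=r"line 2"):
            load_transcripts(fasta, gtf)

    def test_gene_exon_lengths_merge_overlaps(self, tmp_path):
        gtf = write_gtf(
            tmp_path,
            [
                ("chr1", "exon", 1, 10, "+", "G1", "T1"),
                ("chr1", "exon", 5, 20, "+", "G1", "T2"),  # overlapping isoform
                ("chr1", "exon", 31, 40, "+", "G1", "T2"),
            ],
        )
        lengths = gene_exon_lengths(gtf)
        assert lengths["G1"] == 20 + 10


class TestRepresentative:
    def make(self, tid, gid, n, utr=None):
        return TranscriptRecord(tid, gid, gid, "A" * n, utr)

    def test_longest_spliced_and_tie_break(self):
        recs = [self.make("T2", "G1", 900), self.make("T1", "G1", 1200),
                self.make("T9", "G1", 1200)]
        (winner,) = select_representative(recs, "longest_spliced")["G1"]
        assert winner.transcript_id == "T1"  # longest, ties by smallest id

    def test_longest_utr3(self):
        recs = [self.make("T1", "G1", 100, (90, 100)), self.make("T2", "G1", 100, (50, 100))]
        (winner,) = select_representative(recs, "longest_utr3")["G1"]
        assert winner.transcript_id == "T2"

    def test_all_union_counts_any_isoform(self, mir93):
        motif = IsomiR(mir93).seed_motif("6mer")
        with_site = TranscriptRecord("T1", "G1", "G1", "GG" + motif.site_seq + "GG")
        without = TranscriptRecord("T2", "G1", "G1", "G" * 20)
        reps = select_representative([with_site, without], "all_union")
        ts = build_target_set(mir93.name, motif, reps, "full_mrna")
        assert ts.genes == {"G1"}

    def test_unknown_policy_rejected(self):
        with pytest.raises(ScanError):
            select_representative([], "first")


class TestScanSites:
    @pytest.mark.parametrize(
        "sequence, motif, expected",
        [
            (SHRNA_FRAGMENT, "CACTTT", [17]),
            (SHRNA_FRAGMENT, "AACAGCACTTT", [12]),
            (SHRNA_FRAGMENT, "AACAGCA", [12]),
            ("AAAA", "AAA", [1, 2]),
            ("", "AAA", []),
            ("CANCTTT", "CACTTT", []),  # N in window is a non-match
        ],
    )
    def test_examples(self, sequence, motif, expected):
        assert scan_sites(sequence, motif) == expected

    @given(sequence=dna_seq, motif=st.text(alphabet="ACGT", min_size=1, max_size=8))
    @settings(deadline=None, max_examples=300)
    def test_agrees_with_naive_sliding_window(self, sequence, motif):
        assert scan_sites(sequence, motif) == naive_scan(sequence, motif)


class TestExtendable:
    def test_fragment_site_is_extendable(self, mir93):
        ext = make_extended_motif(mir93, 4)
        starts = scan_sites(SHRNA_FRAGMENT, "CACTTT")
        assert annotate_extendable(starts, SHRNA_FRAGMENT, ext) == [True]

    def test_boundary_site_not_extendable(self, mir93):
        ext = make_extended_motif(mir93, 4)
        seq = "GGCACTTTGG"  # 6mer at start 3; window would begin at -2
        assert annotate_extendable(scan_sites(seq, "CACTTT"), seq, ext) == [False]

    def test_plain_6mer_not_extendable(self, mir93):
        ext = make_extended_motif(mir93, 4)
        seq = "GGGGGCACTTTGG"  # no AACAGCACTTT anywhere
        assert annotate_extendable(scan_sites(seq, "CACTTT"), seq, ext) == [False]

    @given(seq=st.text(alphabet="ACGT", min_size=30, max_size=120), shift=st.integers(1, 5))
    @settings(deadline=None, max_examples=200)
    def test_extendable_implies_isomir_site(self, seq, shift, mir93):
        """Every extendable 6mer start has the isomiR 7mer-m8 site at its window start."""
        ext = make_extended_motif(mir93, shift)
        motif6 = IsomiR(mir93).seed_motif("6mer").site_seq
        motif7 = IsomiR(mir93, shift5=shift).seed_motif("7mer-m8").site_seq
        # plant the extended site to make positives likely
        seq = seq[:10] + ext.site_seq + seq[10:]
        starts = scan_sites(seq, motif6)
        flags = annotate_extendable(starts, seq, ext)
        assert any(flags)
        iso_starts = set(scan_sites(seq, motif7))
        for p, flag in zip(starts, flags):
            if flag:
                assert p - (ext.length - 6) in iso_starts


class TestTargetSets:
    def test_utr3_subset_of_full_mrna(self, small_bundle, mir93):
        from dualseed.scan import load_transcripts, select_representative

        records = load_transcripts(small_bundle.transcript_fasta, small_bundle.gtf)
        reps = select_representative(records)
        for seed_type, shift in (("6mer", 0), ("7mer-m8", 4)):
            motif = IsomiR(mir93, shift5=shift).seed_motif(seed_type)
            utr = build_target_set("m", motif, reps, "utr3")
            full = build_target_set("m", motif, reps, "full_mrna")
            assert utr.genes <= full.genes

    def test_region_restriction(self, mir93):
        motif = IsomiR(mir93).seed_motif("6mer")
        # site in the CDS only: UTR excludes it
        rec = TranscriptRecord("T1", "G1", "G1", motif.site_seq + "G" * 14, (10, 20))
        reps = {"G1": (rec,)}
        assert build_target_set("m", motif, reps, "utr3").genes == set()
        assert build_target_set("m", motif, reps, "full_mrna").genes == {"G1"}

    def test_empty_universe_rejected(self, mir93):
        with pytest.raises(ScanError):
            build_target_set("m", IsomiR(mir93).seed_motif("6mer"), {}, "full_mrna")
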