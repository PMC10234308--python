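"""Annotation parsing, host assignment, and genomic-context features."""

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from snoexpress import genome_io
from snoexpress.genome_io import (
    AnnotationError,
    Gene,
    GenomicInterval,
    SnoRecord,
    Transcript,
    assign_host,
    derive_intron_context,
    distance_to_branchpoint,
    extract_flanks,
    read_annotation,
    reverse_complement,
)


def _write(path, text):
    path.write_text(text)
    return path


TOY_GTF = "\n".join(
    [
        'chr1\tx\tgene\t101\t200\t.\t+\t.\tgene_id "G1"; gene_biotype "protein_coding";',
        'chr1\tx\ttranscript\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
        'chr1\tx\texon\t101\t120\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
        'chr1\tx\texon\t181\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
    ]
) + "\n"


class TestReadAnnotation:
    def test_coordinate_conversion_and_intron(self, tmp_path):
        ann = read_annotation(_write(tmp_path / "toy.gtf", TOY_GTF))
        gene = ann.genes["G1"]
        assert (gene.interval.start, gene.interval.end) == (100, 200)
        tx = ann.transcripts["T1"]
        assert [(e.start, e.end) for e in tx.exons] == [(100, 120), (180, 200)]
        assert [(i.start, i.end) for i in tx.introns] == [(120, 180)]

    def test_transcript_without_exons_has_zero_introns(self, tmp_path):
        gtf = TOY_GTF + 'chr1\tx\ttranscript\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T2";\n'
        ann = read_annotation(_write(tmp_path / "t.gtf", gtf))
        assert ann.transcripts["T2"].exons == ()
        assert ann.transcripts["T2"].introns == ()

    def test_malformed_line_names_line_number(self, tmp_path):
        bad = TOY_GTF + "chr1\tonly\tthree\n"
        with pytest.raises(AnnotationError, match="line 5"):
            read_annotation(_write(tmp_path / "bad.gtf", bad))

    def test_exon_outside_transcript_rejected(self, tmp_path):
        gtf = TOY_GTF + 'chr1\tx\texon\t250\t260\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        with pytest.raises(AnnotationError, match="outside transcript"):
            read_annotation(_write(tmp_path / "bad.gtf", gtf))

    def test_gtf_round_trip_coordinates(self, smoke_cohort):
        """GTF -> internal -> GTF emits the identical 1-based coordinates."""
        paths, _ = smoke_cohort
        ann = read_annotation(paths.gtf)
        on_disk = {}
        for line in paths.gtf.read_text().splitlines():
            fields = line.split("\t")
            if fields[2] == "gene":
                gid = fields[8].split('"')[1]
                on_disk[gid] = (fields[0], int(fields[3]), int(fields[4]), fields[6])
        for gid, gene in ann.genes.items():
            iv = gene.interval
            assert on_disk[gid] == (iv.chrom, iv.start + 1, iv.end, iv.strand)

    def test_cohort_record_counts_match_manifest(self, smoke_cohort):
        paths, manifest = smoke_cohort
        ann = read_annotation(paths.gtf)
        snornas = ann.genes_with_biotype("snoRNA")
        assert len(snornas) == len(manifest["snornas"])
        n_hosted = sum(1 for t in manifest["snornas"].values() if t["host_id"])
        assert len(ann.genes) == len(snornas) + n_hosted


def _sno(chrom="chr1", start=150, end=230, strand="+", sno_type="CD"):
    return SnoRecord("S1", GenomicInterval(chrom, start, end, strand), sno_type, "A" * (end - start))


class TestAssignHost:
    def test_same_strand_overlap_assigned(self):
        genes = [Gene("G1", GenomicInterval("chr1", 100, 500, "+"), "protein_coding")]
        a = assign_host(_sno(), genes)
        assert (a.host_id, a.host_biotype) == ("G1", "protein_coding")

    def test_opposite_strand_is_intergenic(self):
        genes = [Gene("G1", GenomicInterval("chr1", 100, 500, "+"), "protein_coding")]
        a = assign_host(_sno(strand="-"), genes)
        assert a.is_intergenic and a.host_biotype == "intergenic"

    def test_nested_genes_smallest_containing_wins(self):
        genes = [
            Gene("BIG", GenomicInterval("chr1", 0, 1000, "+"), "protein_coding"),
            Gene("SMALL", GenomicInterval("chr1", 100, 400, "+"), "lncRNA"),
        ]
        a = assign_host(_sno(), genes)
        assert a.host_id == "SMALL" and a.host_biotype == "noncoding"

    def test_candidate_set_matches_exhaustive_scan(self, rng):
        genes = [
            Gene(
                f"G{k}",
                GenomicInterval(
                    "chr1", s := int(rng.integers(0, 900)), s + int(rng.integers(50, 600)),
                    "+-"[rng.integers(2)],
                ),
                "protein_coding",
            )
            for k in range(40)
        ]
        for _ in range(50):
            s = int(rng.integers(0, 950))
            sno = _sno(start=s, end=s + 60, strand="+-"[rng.integers(2)])
            brute = {
                g.id
                for g in genes
                if g.interval.chrom == sno.interval.chrom
                and g.interval.strand == sno.interval.strand
                and g.interval.start < sno.interval.end
                and sno.interval.start < g.interval.end
            }
            a = assign_host(sno, genes)
            if not brute:
                assert a.is_intergenic
            else:
                assert a.host_id in brute
                containing = [g for g in genes if g.id in brute and g.interval.contains(sno.interval)]
                pool = containing or [g for g in genes if g.id in brute]
                assert a.host_id == min(pool, key=lambda g: (g.interval.length, g.id)).id


def _host_transcript(n_introns, exon_len=100, intron_len=500, strand="+"):
    exons, pos = [], 0
    for _ in range(n_introns + 1):
        exons.append(GenomicInterval("chr1", pos, pos + exon_len, strand))
        pos += exon_len + intron_len
    end = exons[-1].end
    return Transcript("T1", "G1", GenomicInterval("chr1", 0, end, strand), tuple(exons))


class TestIntronContext:
    def test_third_of_four_introns(self):
        tx = _host_transcript(4)
        # third intron (5' order, + strand) spans [1300, 1800)
        sno = SnoRecord("S", GenomicInterval("chr1", 1400, 1480, "+"), "CD", "A" * 80)
        ctx = derive_intron_context(sno, [tx])
        assert (ctx.rank_5p, ctx.rank_3p, ctx.relative_rank_3p) == (3, 2, 0.5)
        assert ctx.total_introns == 4 and ctx.intron_length == 500
        assert ctx.dist_upstream_exon == 100 and ctx.dist_downstream_exon == 320

    def test_single_intron_host(self):
        tx = _host_transcript(1)
        sno = SnoRecord("S", GenomicInterval("chr1", 200, 280, "+"), "CD", "A" * 80)
        ctx = derive_intron_context(sno, [tx])
        assert (ctx.rank_5p, ctx.rank_3p, ctx.relative_rank_3p) == (1, 1, 1.0)

    def test_exonic_snorna_has_missing_context(self):
        tx = _host_transcript(2)
        sno = SnoRecord("S", GenomicInterval("chr1", 10, 90, "+"), "CD", "A" * 80)
        assert derive_intron_context(sno, [tx]) is None

    def test_minus_strand_ranks_count_from_transcript_5p(self):
        tx = _host_transcript(2, strand="-")
        # genomically-first intron [100, 600) is the LAST from the 5' end on -
        sno = SnoRecord("S", GenomicInterval("chr1", 200, 280, "-"), "CD", "A" * 80)
        ctx = derive_intron_context(sno, [tx])
        assert (ctx.rank_5p, ctx.rank_3p) == (2, 1)
        assert ctx.dist_upstream_exon == 600 - 280 and ctx.dist_downstream_exon == 100

    def test_cohort_contexts_match_generator_truth(self, smoke_cohort, smoke_features):
        _, manifest = smoke_cohort
        raw = smoke_features.raw
        checked = 0
        for sno_id, truth in manifest["snornas"].items():
            ctx = truth["intron_context"]
            if ctx is None:
                continue
            row = raw.loc[sno_id]
            assert row["total_introns"] == ctx["total_introns"]
            assert row["intron_length"] == ctx["intron_length"]
            assert row["intron_rank_5p"] == ctx["rank_5p"]
            assert row["relative_intron_rank_3p"] == pytest.approx(ctx["relative_rank_3p"])
            assert row["dist_upstream_exon"] == ctx["dist_upstream_exon"]
            assert row["dist_downstream_exon"] == ctx["dist_downstream_exon"]
            assert row["dist_branchpoint"] == ctx["dist_branchpoint"]
            assert (
                ctx["dist_upstream_exon"]
                + (row["sno_length"])
                + ctx["dist_downstream_exon"]
                == ctx["intron_length"]
            )
            checked += 1
        assert checked > 5


class TestBranchpointDistance:
    def test_highest_probability_wins(self):
        sno = SnoRecord("S", GenomicInterval("chr1", 900, 1001, "+"), "CD", "A" * 101)
        assert distance_to_branchpoint(sno, [(1040, 0.9), (1100, 0.3)]) == 40

    def test_probability_tie_goes_to_nearer(self):
        sno = SnoRecord("S", GenomicInterval("chr1", 900, 1001, "+"), "CD", "A" * 101)
        assert distance_to_branchpoint(sno, [(1100, 0.5), (1040, 0.5)]) == 40

    def test_empty_set_is_missing(self):
        assert distance_to_branchpoint(_sno(), []) is None

    def test_random_configurations_match_bruteforce(self, rng):
        for _ in range(100):
            strand = "+-"[rng.integers(2)]
            start = int(rng.integers(100, 2000))
            sno = SnoRecord(
                "S", GenomicInterval("chr1", start, start + 80, strand), "CD", "A" * 80
            )
            entries = [
                (int(rng.integers(0, 3000)), float(rng.integers(1, 11)) / 10)
                for _ in range(int(rng.integers(1, 6)))
            ]
            three_prime = start + 79 if strand == "+" else start
            best = min(entries, key=lambda e: (-e[1], abs(e[0] - three_prime)))
            assert distance_to_branchpoint(sno, entries) == abs(best[0] - three_prime)


class TestExtractFlanks:
    @pytest.fixture
    def genome(self, tmp_path, rng):
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 400))
        fa = tmp_path / "g.fa"
        fa.write_text(f">chr1\n{seq}\n")
        return seq, Fasta(str(fa))

    def test_plus_strand_windows(self, genome):
        seq, fasta = genome
        sno = SnoRecord("S", GenomicInterval("chr1", 100, 180, "+"), "CD", "N" * 80)
        up, down = extract_flanks(sno, fasta)
        assert up == seq[85:100].replace("T", "U")
        assert down == seq[180:195].replace("T", "U")

    def test_minus_strand_mirrors_and_reverse_complements(self, genome):
        seq, fasta = genome
        sno = SnoRecord("S", GenomicInterval("chr1", 100, 180, "-"), "CD", "N" * 80)
        up, down = extract_flanks(sno, fasta)
        assert up == reverse_complement(seq[180:195]).replace("T", "U")
        assert down == reverse_complement(seq[85:100]).replace("T", "U")

    def test_strand_symmetry_round_trip(self, tmp_path, rng):
        """Flanks of a locus and of its reverse-complemented mirror agree."""
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 300))
        rc = reverse_complement(seq)
        fa = tmp_path / "two.fa"
        fa.write_text(f">fwd\n{seq}\n>rev\n{rc}\n")
        fasta = Fasta(str(fa))
        for _ in range(20):
            start = int(rng.integers(20, 200))
            end = start + int(rng.integers(30, 80))
            plus = SnoRecord("S", GenomicInterval("fwd", start, end, "+"), "CD", "N" * (end - start))
            minus = SnoRecord(
                "S", GenomicInterval("rev", 300 - end, 300 - start, "-"), "CD", "N" * (end - start)
            )
            assert extract_flanks(plus, fasta) == extract_flanks(minus, fasta)

    def test_chromosome_edge_truncates(self, genome):
        _, fasta = genome
        sno = SnoRecord("S", GenomicInterval("chr1", 5, 60, "+"), "CD", "N" * 55)
        up, down = extract_flanks(sno, fasta)
        assert len(up) == 5 and len(down) == 15


class TestInvariants:
    def test_interval_rejects_empty_and_bad_strand(self):
        with pytest.raises(ValueError):
            GenomicInterval("c", 10, 10, "+")
        with pytest.raises(ValueError):
            GenomicInterval("c", 0, 10, "*")

    def test_snorecord_length_consistency(self):
        with pytest.raises(ValueError, match="length"):
            SnoRecord("S", GenomicInterval("c", 0, 10, "+"), "CD", "ACGU")
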