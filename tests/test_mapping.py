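"""Gene regions, the spliced aligner, external alignment ingestion, assignment."""

from __future__ import annotations

import random

import pytest

from floret import io as fio
from floret import mapping
from floret.mapping import AlignParams, GeneModel, align_est, assign_to_gene, define_gene_regions


def _gene(gid, chrom, exons, strand="+", **kw):
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand, exons=tuple(exons), **kw)


class TestGeneRegions:
    def test_distant_neighbors_get_full_flanks(self):
        g = _gene("g1", "c", [(5000, 8000)])
        regions = define_gene_regions([g], {"c": 20000})
        assert (regions[0].start, regions[0].end) == (4000, 9000)

    def test_chromosome_boundary_clamps(self):
        g = _gene("g1", "c", [(500, 900)])
        regions = define_gene_regions([g], {"c": 1900})
        assert (regions[0].start, regions[0].end) == (0, 1900)

    def test_neighbor_conflict_truncates_at_gap_midpoint(self):
        g1 = _gene("g1", "c", [(1000, 2000)])
        g2 = _gene("g2", "c", [(2400, 3000)])
        regions = {r.gene_id: r for r in define_gene_regions([g1, g2], {"c": 10000})}
        assert regions["g1"].end == 2200
        assert regions["g2"].start == 2200

    def test_order_independent_and_idempotent(self):
        genes = [
            _gene("g1", "c", [(1000, 2000)]),
            _gene("g2", "c", [(2400, 3000)]),
            _gene("g3", "c", [(6000, 6500)]),
        ]
        a = define_gene_regions(genes, {"c": 10000})
        b = define_gene_regions(genes[::-1], {"c": 10000})
        assert a == b == define_gene_regions(genes, {"c": 10000})

    def test_regions_contain_genes_and_never_overlap(self, study):
        chrom_lengths = {c: len(s) for c, s in study.genome.items()}
        regions = define_gene_regions(study.genes, chrom_lengths)
        by_gene = {r.gene_id: r for r in regions}
        for g in study.genes:
            r = by_gene[g.gene_id]
            assert r.start <= g.start and r.end >= g.end
        by_chrom: dict[str, list] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for rs in by_chrom.values():
            rs.sort(key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                assert a.end <= b.start

    def test_cds_anchored_flanks(self):
        g = _gene("g1", "c", [(5000, 8000)], cds_start=5400, cds_end=7500)
        regions = define_gene_regions([g], {"c": 20000})
        # flank measured from translation start/stop, clipped to contain the gene
        assert (regions[0].start, regions[0].end) == (4400, 8500)


class TestAlignEst:
    def _setup(self):
        rng = random.Random(17)
        exon1 = "".join(rng.choice("ACGT") for _ in range(120))
        exon2 = "".join(rng.choice("ACGT") for _ in range(120))
        intron = "GT" + "".join(rng.choice("ACGT") for _ in range(76)) + "AG"
        # disambiguation: base before donor and after acceptor differ from motif starts
        exon1 = exon1[:-1] + "C"
        exon2 = "T" + exon2[1:]
        region = exon1 + intron + exon2
        transcript = exon1 + exon2
        return region, transcript

    def test_error_free_junction_read_gets_two_blocks(self):
        region, transcript = self._setup()
        read = transcript[80:180]  # spans the junction at offset 120
        blocks, identity, coverage = align_est(read, region)
        assert identity == 1.0 and coverage == 1.0
        assert len(blocks) == 2
        (q1s, q1e, t1s, t1e), (q2s, q2e, t2s, t2e) = blocks
        assert (t1e, t2s) == (120, 200)  # the annotated intron

    def test_low_identity_read_rejected(self):
        region, transcript = self._setup()
        rng = random.Random(5)
        read = list(transcript[:100])
        for i in range(0, 100, 10):  # 10% scattered mismatches
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        assert align_est("".join(read), region) is None

    def test_low_coverage_read_rejected(self):
        region, transcript = self._setup()
        rng = random.Random(6)
        tail = "".join(rng.choice("ACGT") for _ in range(60))
        read = transcript[:140] + tail  # only 70% of the read is alignable
        assert align_est(read, region) is None

    def test_accepts_at_thresholds(self):
        region, transcript = self._setup()
        read = transcript[:100]
        blocks, identity, coverage = align_est(read, region)
        assert (identity, coverage) == (1.0, 1.0)
        assert blocks == [(0, 100, 0, 100)]


class TestAssignment:
    def _aln(self, gene, ident, cov, qlen=100):
        n = int(round(ident * cov * qlen))
        return mapping.SplicedAlignment(
            est_id="r", library="G", gene_id=gene, chrom="c", strand="+",
            blocks=[(0, int(cov * qlen), 0, int(cov * qlen))],
            identity=ident, coverage=cov, query_length=qlen,
        )

    def test_single_candidate_wins(self):
        a = self._aln("g1", 1.0, 1.0)
        assert assign_to_gene([a]) is a

    def test_tie_breaks_lexicographically(self):
        a = self._aln("g2", 0.98, 0.9)
        b = self._aln("g1", 0.98, 0.9)
        assert assign_to_gene([a, b]).gene_id == "g1"

    def test_higher_score_beats_gene_id(self):
        a = self._aln("g9", 1.0, 1.0)
        b = self._aln("g1", 0.96, 1.0)
        assert assign_to_gene([a, b]).gene_id == "g9"

    def test_no_alignments_is_unassigned(self):
        assert assign_to_gene([]) is None


class TestFixtureMapping:
    def test_all_reads_accepted_and_correctly_assigned(self, study, assignments):
        """On noise-free simulator output every read maps to its source gene."""
        assigned, unmapped = assignments
        assert unmapped == 0
        n_reads = sum(len(r) for r in study.reads.values())
        assert len(assigned) == n_reads
        for a in assigned:
            assert study.truth.read_origin[a.est_id] == a.gene_id
            assert a.identity >= 0.95 and a.coverage >= 0.80


class TestExternalAlignments:
    def _write_psl(self, path, rows):
        with open(path, "w") as fh:
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")

    def test_psl_single_block(self, tmp_path):
        p = tmp_path / "a.psl"
        row = [100, 0, 0, 0, 0, 0, 0, 0, "+", "G|r1", 100, 0, 100,
               "g0001", 5000, 200, 300, 1, "100,", "0,", "200,"]
        self._write_psl(p, [row])
        genes = [_gene("g0001", "chr1", [(100, 400)])]
        alns, skipped = fio.read_alignments(p, "PSL", genes)
        assert skipped == 0 and len(alns) == 1
        assert alns[0].blocks == [(0, 100, 200, 300)]
        assert alns[0].introns == []
        assert alns[0].library == "G"

    def test_psl_low_coverage_rejected(self, tmp_path):
        p = tmp_path / "a.psl"
        row = [150, 0, 0, 0, 0, 0, 0, 0, "+", "r1", 200, 0, 150,
               "g0001", 5000, 200, 350, 1, "150,", "0,", "200,"]
        self._write_psl(p, [row])
        genes = [_gene("g0001", "chr1", [(100, 400)])]
        alns, skipped = fio.read_alignments(p, "PSL", genes)
        assert alns == [] and skipped == 1  # coverage 0.75 < 0.80

    def test_psl_malformed_rows_skipped(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text("psLayout version 3\n\n1\t2\t3\n")
        alns, skipped = fio.read_alignments(p, "PSL", [])
        assert alns == [] and skipped == 1

    def test_psl_unknown_target_errors(self, tmp_path):
        p = tmp_path / "a.psl"
        row = [100, 0, 0, 0, 0, 0, 0, 0, "+", "r1", 100, 0, 100,
               "nope", 5000, 200, 300, 1, "100,", "0,", "200,"]
        self._write_psl(p, [row])
        genes = [_gene("g0001", "chr1", [(100, 400)])]
        with pytest.raises(ValueError, match="unknown alignment target"):
            fio.read_alignments(p, "PSL", genes)

    def test_gff3_match_parts_become_blocks(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "g0001\tblat\tmatch\t201\t400\t.\t+\t.\tID=m1;Target=r1 1 160;qsize=170\n"
            "g0001\tblat\tmatch_part\t201\t280\t.\t+\t.\tParent=m1;Target=r1 1 80\n"
            "g0001\tblat\tmatch_part\t321\t400\t.\t+\t.\tParent=m1;Target=r1 81 160\n"
        )
        genes = [_gene("g0001", "chr1", [(100, 500)])]
        alns, skipped = fio.read_alignments(p, "GFF3", genes)
        assert len(alns) == 1
        assert alns[0].blocks == [(0, 80, 200, 280), (80, 160, 320, 400)]
        assert alns[0].introns == [(280, 320)]
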