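"""Pileup construction, candidate sites and the three SNP filters."""

from __future__ import annotations

import pytest

from floret import snp
from floret.snp import (
    SNPRecord,
    apply_filters,
    call_snps,
    candidate_sites,
    class_tally,
    classify_variant,
    pileup_columns,
)


def _col(by_pos, pos, ins=0):
    return next(c for c in by_pos if (c.position, c.insert_index) == (pos, ins))


CONTIG = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 40 nt, no homopolymers


class TestPileup:
    def test_identical_reads_stack_cleanly(self):
        reads = [(f"G|r{i}", CONTIG) for i in range(5)]
        cols = pileup_columns("c1", CONTIG, reads)
        assert len(cols) == len(CONTIG)
        for c in cols:
            if 2 <= c.position < len(CONTIG) - 2:  # read ends are soft-trimmed
                assert c.allele_set("G") == {c.consensus}
                assert c.coverage("G") == 5
            else:
                assert c.coverage("G") == 0

    def test_deletion_contributes_gap_allele(self):
        read = CONTIG[:10] + CONTIG[11:]  # drop position 10
        cols = pileup_columns("c1", CONTIG, [("H|r1", read), ("G|r1", CONTIG)])
        c = _col(cols, 10)
        assert c.allele_set("H") == {"-"}
        assert c.allele_set("G") == {CONTIG[10]}

    def test_insertion_opens_gap_column(self):
        read = CONTIG[:10] + "T" + CONTIG[10:]
        cols = pileup_columns("c1", CONTIG, [("H|r1", read), ("G|r1", CONTIG)])
        ins = [c for c in cols if c.insert_index > 0]
        assert len(ins) == 1
        c = ins[0]
        assert c.allele_set("H") == {"T"}
        assert c.allele_set("G") == {"-"}  # spanning read without the insertion

    def test_lines_tallied_separately(self):
        sub = CONTIG[:20] + "A" + CONTIG[21:]
        cols = pileup_columns("c1", CONTIG, [("G|r1", CONTIG), ("H|r1", sub)])
        c = _col(cols, 20)
        assert c.allele_set("G") == {CONTIG[20]} and c.allele_set("H") == {"A"}

    def test_reverse_complement_reads_are_placed(self):
        from floret.mapping import revcomp

        cols = pileup_columns("c1", CONTIG, [("G|r1", revcomp(CONTIG))])
        assert all(
            c.allele_set("G") == {c.consensus}
            for c in cols
            if 2 <= c.position < len(CONTIG) - 2
        )


class TestCandidates:
    def test_monomorphic_column_is_not_candidate(self):
        cols = pileup_columns("c1", CONTIG, [("G|r1", CONTIG), ("H|r1", CONTIG)])
        assert candidate_sites(cols) == []

    def test_between_line_difference_is_candidate(self):
        sub = CONTIG[:8] + "G" + CONTIG[9:]
        cols = pileup_columns("c1", CONTIG, [("G|r1", CONTIG), ("H|r1", sub)])
        cand = candidate_sites(cols)
        assert [c.position for c in cand] == [8]

    def test_within_line_variation_is_candidate(self):
        sub = CONTIG[:8] + "G" + CONTIG[9:]
        cols = pileup_columns("c1", CONTIG, [("G|r1", CONTIG), ("G|r2", sub), ("H|r1", CONTIG)])
        cand = candidate_sites(cols)
        assert [c.position for c in cand] == [8]


class TestClassify:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            (("A", "G"), "transition"),
            (("C", "T"), "transition"),
            (("A", "C"), "transversion"),
            (("G", "T"), "transversion"),
            (("A", "-"), "indel"),
            (("A", "C", "G"), None),
        ],
    )
    def test_classes(self, alleles, expected):
        assert classify_variant(alleles) == expected


def build_confusion_fixture():
    """Contig and reads with one clean site per class and one violation of
    each criterion; returns (contig, reads, expectations by position)."""
    base = list("ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT")
    base[30:33] = list("AAA")  # homopolymer run for the criterion-2 case
    contig = "".join(base)

    def read(line, n, edits=(), dels=()):
        s = list(contig)
        for pos, b in edits:
            s[pos] = b
        for pos in sorted(dels, reverse=True):
            del s[pos]
        return [(f"{line}|{line}{n}_{i}", "".join(s)) for i in range(n)]

    reads = []
    reads += read("G", 3)  # reference line
    # clean transition at 4 (A->G), clean transversion at 8 (A->C), clean
    # deletion at 12; deletion at 31 inside the AAA run violates criterion 2
    # only; one H read keeps the reference base at 20 while another carries T,
    # so line H shares an allele with line G there (criterion-3 violation).
    reads += read("H", 2, edits=[(4, "G"), (8, "C"), (20, "A")], dels=[12, 31])
    reads += read("H", 1, edits=[(4, "G"), (8, "C"), (20, "T")], dels=[12, 31])
    expectations = {
        4: dict(cls="transition", c1=True, c2=True, c3=True),
        8: dict(cls="transversion", c1=True, c2=True, c3=True),
        12: dict(cls="indel", c1=True, c2=True, c3=True),
        # G:{A} vs H:{A,T}: allele sets overlap, the substitution itself is a
        # transversion pattern, but criterion 3 rejects it
        20: dict(cls="transversion", c1=True, c2=True, c3=False),
        # the gap may legally sit anywhere inside the AAA run (30..32)
        "homopolymer_del": dict(cls="indel", c1=True, c2=False, c3=True),
    }
    return contig, reads, expectations


class TestFilters:
    def test_confusion_fixture_matches_hand_truth(self):
        contig, reads, expect = build_confusion_fixture()
        records = {r.position: r for r in call_snps("c1", contig, reads) if r.insert_index == 0}
        homopolymer_want = expect.pop("homopolymer_del")
        hp = [records[p] for p in (30, 31, 32) if p in records]
        assert len(hp) == 1
        assert hp[0].var_class == homopolymer_want["cls"]
        assert hp[0].pass_coverage and not hp[0].pass_homopolymer
        assert hp[0].pass_disjoint and not hp[0].passed
        assert set(expect) <= set(records)
        for pos, want in expect.items():
            r = records[pos]
            assert r.var_class == want["cls"], pos
            assert r.pass_coverage is want["c1"], pos
            assert r.pass_homopolymer is want["c2"], pos
            assert r.pass_disjoint is want["c3"], pos
            assert r.passed is all(want[c] for c in ("c1", "c2", "c3")), pos

    def test_low_coverage_fails_criterion_one(self):
        contig = CONTIG
        reads = [("G|r1", contig), ("G|r2", contig),
                 ("H|r1", contig[:8] + "G" + contig[9:])]
        recs = [r for r in call_snps("c1", contig, reads) if r.position == 8]
        assert len(recs) == 1
        assert not recs[0].pass_coverage and not recs[0].passed
        assert recs[0].pass_disjoint

    def test_classes_partition_passing_records(self):
        contig, reads, _ = build_confusion_fixture()
        recs = call_snps("c1", contig, reads)
        tally = class_tally(recs)
        assert sum(tally.values()) == sum(1 for r in recs if r.passed)

    def test_unanimity_mode_is_stricter(self):
        contig = CONTIG
        reads = [("G|r1", contig), ("G|r2", contig[:8] + "G" + contig[9:]),
                 ("H|r1", contig[:8] + "T" + contig[9:]),
                 ("H|r2", contig[:8] + "T" + contig[9:])]
        loose = [r for r in call_snps("c1", contig, reads) if r.position == 8]
        strict = [
            r for r in call_snps("c1", contig, reads, require_within_line_unanimity=True)
            if r.position == 8
        ]
        assert loose[0].pass_disjoint and not strict[0].pass_disjoint


class TestEndToEnd:
    def test_injected_variants_recovered_when_covered(self, study, assignments, read_seqs):
        """Every injected inter-line variant whose site has >= 2 reads per
        line is recovered with the right class; no false positives."""
        assigned, _ = assignments
        by_gene: dict[str, list[tuple[str, str]]] = {}
        for a in assigned:
            by_gene.setdefault(a.gene_id, []).append((a.est_id, read_seqs[a.est_id]))
        truth = {(v.gene_id, v.transcript_pos): v.var_class for v in study.truth.snps}
        found = {}
        for gid, rds in by_gene.items():
            if gid in study.alt_isoforms:
                continue
            contig = study.transcript(gid)
            for r in call_snps(gid, contig, rds):
                if r.passed:
                    found[(gid, r.position)] = r.var_class
        for key, r in found.items():
            assert key in truth and truth[key] == r, f"false positive {key}"
        # recovery conditioned on observed coverage at the site
        for gid, rds in by_gene.items():
            if gid in study.alt_isoforms:
                continue
            cols = {
                (c.position, c.insert_index): c
                for c in pileup_columns(gid, study.transcript(gid), rds)
            }
            for (g2, pos), cls in truth.items():
                if g2 != gid or (pos, 0) not in cols:
                    continue
                c = cols[(pos, 0)]
                if c.coverage("G") >= 2 and c.coverage("H") >= 2:
                    assert (gid, pos) in found, (gid, pos, cls)
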