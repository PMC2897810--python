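"""Inter-line SNP calling from per-contig read columns, with three filters.

A transparent column caller replaces probabilistic genotyping: reads of
the two lines are aligned to the contig consensus, stacked into per-
position columns (plus gap columns for insertions), and columns where
more than one allele is observed become candidates.  A candidate passes
only when

  1. each line has coverage >= ``min_coverage`` (default 2) at the site,
  2. if it is an indel, no consensus homopolymer run of length >= 3
     overlaps the window [pos-1, pos+1],
  3. the two lines' allele sets are disjoint.

Passing biallelic substitutions classify as transition (A<->G, C<->T)
or transversion; any site whose allele union contains the gap symbol
"-" is an indel.  Multi-allelic non-indel candidates are rejected since
the transition/transversion dichotomy is defined for biallelic sites.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from .mapping import revcomp
from .simulate import run_length_at

GAP = "-"
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


@dataclass
class SiteColumn:
    """Observed alleles at one contig column, tallied per line.

    ``position`` indexes the consensus; ``insert_index`` > 0 marks gap
    columns for bases inserted after that consensus position.
    """

    contig: str
    position: int
    insert_index: int
    consensus: str
    alleles: dict[str, Counter] = field(default_factory=dict)

    def coverage(self, line: str) -> int:
        return sum(self.alleles.get(line, Counter()).values())

    def allele_set(self, line: str) -> frozenset[str]:
        return frozenset(self.alleles.get(line, Counter()))

    @property
    def allele_union(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.alleles.values():
            out |= set(c)
        return frozenset(out)


@dataclass(frozen=True)
class SNPRecord:
    contig: str
    position: int
    insert_index: int
    alleles_a: frozenset[str]
    alleles_b: frozenset[str]
    coverage_a: int
    coverage_b: int
    var_class: str | None
    pass_coverage: bool
    pass_homopolymer: bool
    pass_disjoint: bool

    @property
    def passed(self) -> bool:
        return (
            self.pass_coverage
            and self.pass_homopolymer
            and self.pass_disjoint
            and self.var_class is not None
        )


def _line_of(read_id: str) -> str:
    return read_id.split("|", 1)[0]


_CIGAR = re.compile(r"(\d+)([=XIDM])")


def _align_read(read: str, contig: str) -> tuple[int, str, int] | None:
    """Best infix alignment of the read (either orientation) to the contig.

    Returns (contig start, extended cigar, edit distance) or None when
    neither orientation aligns acceptably (<= 15% edits).
    """
    best = None
    for seq in (read, revcomp(read)):
        res = edlib.align(seq, contig, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[2]:
            best = (res["locations"][0][0], res["cigar"], res["editDistance"], seq)
    if best is None or best[2] > 0.15 * len(read):
        return None
    return best


def pileup_columns(
    contig_id: str,
    contig: str,
    reads: Iterable[tuple[str, str]],
    line_of=_line_of,
    end_trim: int = 2,
) -> list[SiteColumn]:
    """Stack reads on the consensus; one column per position plus insertions.

    Reads are placed by infix alignment (both orientations tried);
    deletions contribute the gap allele at the deleted columns, and an
    inserted base opens a gap column in which every other read spanning
    the flanking consensus positions contributes the gap allele.  The
    first and last ``end_trim`` aligned read bases contribute no
    evidence: equal-cost alignment paths can misplace an indel that
    touches a read end, so end columns are unreliable.
    """
    columns: dict[tuple[int, int], SiteColumn] = {}
    spans: list[tuple[str, int, int]] = []  # (line, start, end) on consensus
    for pos in range(len(contig)):
        columns[(pos, 0)] = SiteColumn(contig_id, pos, 0, contig[pos])

    def col(pos: int, ins: int) -> SiteColumn:
        key = (pos, ins)
        if key not in columns:
            columns[key] = SiteColumn(
                contig_id, pos, ins, contig[pos] if ins == 0 and pos < len(contig) else GAP
            )
        return columns[key]

    def add(pos: int, ins: int, line: str, base: str) -> None:
        c = col(pos, ins)
        c.alleles.setdefault(line, Counter())[base] += 1

    for rid, seq in reads:
        hit = _align_read(seq, contig)
        if hit is None:
            continue
        tpos, cigar, _, oriented = hit
        line = line_of(rid)
        lo, hi = end_trim, len(oriented) - end_trim  # usable query window
        qpos = 0
        span_start = span_end = None
        for n_str, op in _CIGAR.findall(cigar):
            n = int(n_str)
            if op in "=XM":
                for k in range(n):
                    if lo <= qpos + k < hi:
                        add(tpos + k, 0, line, oriented[qpos + k])
                        if span_start is None:
                            span_start = tpos + k
                        span_end = tpos + k + 1
                tpos += n
                qpos += n
            elif op == "D":  # gap in read: deletion relative to consensus
                if lo < qpos < hi:  # strictly inside the trimmed read
                    for k in range(n):
                        add(tpos + k, 0, line, GAP)
                    span_end = tpos + n
                tpos += n
            elif op == "I":  # extra read bases: insertion after consensus tpos-1
                for k in range(n):
                    if lo <= qpos + k < hi:
                        add(tpos - 1, k + 1, line, oriented[qpos + k])
                qpos += n
        if span_start is not None:
            spans.append((line, span_start, span_end))

    # reads spanning an insertion point without the insertion carry the gap allele
    for (pos, ins), c in list(columns.items()):
        if ins == 0:
            continue
        spanning: Counter = Counter()
        for line, s, e in spans:
            if s <= pos and pos + 1 < e:
                spanning[line] += 1
        for line, n_span in spanning.items():
            n_with = c.alleles.get(line, Counter()).total()
            if n_span > n_with:
                c.alleles.setdefault(line, Counter())[GAP] += n_span - n_with
    return [columns[k] for k in sorted(columns)]


def candidate_sites(columns: Iterable[SiteColumn]) -> list[SiteColumn]:
    """Columns where the allele union across lines has >= 2 members."""
    return [c for c in columns if len(c.allele_union) >= 2]


def classify_variant(alleles: Iterable[str]) -> str | None:
    """indel if a gap is present; else transition/transversion for biallelic sites."""
    alleles = set(alleles)
    if GAP in alleles:
        return "indel"
    if len(alleles) != 2:
        return None
    if alleles <= PURINES or alleles <= PYRIMIDINES:
        return "transition"
    return "transversion"


def apply_filters(
    candidates: Iterable[SiteColumn],
    consensus: str,
    min_coverage: int = 2,
    homopolymer_min_run: int = 3,
    lines: tuple[str, str] = ("G", "H"),
    require_within_line_unanimity: bool = False,
) -> list[SNPRecord]:
    """Apply the three filter criteria to candidate columns.

    Criterion 1: both lines covered at least ``min_coverage`` times.
    Criterion 2: indel candidates are rejected when a consensus
    homopolymer of length >= ``homopolymer_min_run`` overlaps
    [pos-1, pos+1].  Criterion 3: line allele sets disjoint (with an
    optional stricter mode demanding a single allele per line).
    """
    la, lb = lines
    out: list[SNPRecord] = []
    for c in candidates:
        aa, ab = c.allele_set(la), c.allele_set(lb)
        cov_ok = c.coverage(la) >= min_coverage and c.coverage(lb) >= min_coverage
        union = aa | ab
        cls = classify_variant(union)
        homo_ok = True
        if cls == "indel":
            lo = max(0, c.position - 1)
            hi = min(len(consensus) - 1, c.position + 1)
            homo_ok = all(
                run_length_at(consensus, p) < homopolymer_min_run for p in range(lo, hi + 1)
            )
        disjoint = bool(aa) and bool(ab) and not (aa & ab)
        if require_within_line_unanimity:
            disjoint = disjoint and len(aa) == 1 and len(ab) == 1
        out.append(
            SNPRecord(
                contig=c.contig,
                position=c.position,
                insert_index=c.insert_index,
                alleles_a=aa,
                alleles_b=ab,
                coverage_a=c.coverage(la),
                coverage_b=c.coverage(lb),
                var_class=cls,
                pass_coverage=cov_ok,
                pass_homopolymer=homo_ok,
                pass_disjoint=disjoint,
            )
        )
    return out


def call_snps(
    contig_id: str,
    contig: str,
    reads: Iterable[tuple[str, str]],
    min_coverage: int = 2,
    **kwargs,
) -> list[SNPRecord]:
    """pileup + candidates + filters for one contig."""
    cols = pileup_columns(contig_id, contig, reads)
    return apply_filters(candidate_sites(cols), contig, min_coverage=min_coverage, **kwargs)


def class_tally(records: Sequence[SNPRecord]) -> dict[str, int]:
    """transition/transversion/indel partition of passing records."""
    tally = {"transition": 0, "transversion": 0, "indel": 0}
    for r in records:
        if r.passed:
            tally[r.var_class] += 1
    return tally
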