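"""Spliced mapping of ESTs onto flanked gene regions.

Gene regions extend each annotated gene by up to 1 kb on each side
(anchored at the translation start/stop when a CDS is annotated),
truncated so that neighboring regions never overlap.  ESTs are aligned
with a seed-and-chain spliced aligner: exact k-mer anchors are merged
into ungapped segments, chained collinearly, and inter-segment genomic
gaps of at least ``min_intron`` become introns whose boundaries are
shifted within a small window to prefer canonical GT..AG (CT..AC on the
minus strand) dinucleotides.  An alignment is accepted only with
>= 95% identity and >= 80% query coverage.

Coordinates are 0-based half-open throughout; GFF3 I/O converts.
"""

from __future__ import annotations

import logging
from bisect import insort
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene: ordered exons on a chromosome strand.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping;
    gaps between consecutive exons are the introns.  ``cds_start``/``cds_end``
    bound the translated region when annotated.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 - e1 < 1:
                raise ValueError(f"{self.gene_id}: exons overlap or abut ({e1} !< {s2})")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, chrom_seq: str) -> str:
        """Mature transcript in transcription orientation."""
        t = "".join(chrom_seq[s:e] for s, e in self.exons)
        return t if self.strand == "+" else revcomp(t)

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position to plus-strand transcript offset, or None if intronic."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
        return None


@dataclass(frozen=True)
class GeneRegion:
    """A gene body plus flanks, clipped against neighbors and chromosome ends."""

    gene_id: str
    chrom: str
    start: int
    end: int


@dataclass
class SplicedAlignment:
    """An EST placed on the genome as ordered exonic blocks.

    ``blocks`` are (qstart, qend, tstart, tend) pairs of equal length on
    query (in aligned orientation) and target (chromosome) coordinates.
    Gaps between consecutive blocks of at least ``min_intron`` target
    nucleotides are the inferred introns.
    """

    est_id: str
    library: str
    gene_id: str
    chrom: str
    strand: str  # orientation of the read relative to the genome
    blocks: list[tuple[int, int, int, int]]
    identity: float
    coverage: float
    query_length: int
    min_intron: int = 40

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (_, _, _, te), (_, _, ts, _) in zip(self.blocks, self.blocks[1:]):
            if ts - te >= self.min_intron:
                out.append((te, ts))
        return out

    @property
    def tstart(self) -> int:
        return self.blocks[0][2]

    @property
    def tend(self) -> int:
        return self.blocks[-1][3]

    @property
    def aligned_length(self) -> int:
        return sum(qe - qs for qs, qe, _, _ in self.blocks)

    @property
    def score(self) -> float:
        return self.identity * self.coverage


# ---------------------------------------------------------------------------
# gene regions


def define_gene_regions(
    genes: Sequence[GeneModel],
    chrom_lengths: dict[str, int],
    flank: int = 1000,
) -> list[GeneRegion]:
    """Extend each gene by up to ``flank`` nt per side without overlap.

    Flanks are anchored at the CDS bounds when annotated (the translation
    start/stop), else at the gene bounds, and always contain the full gene.
    When the flanks of two neighbors would overlap, both are truncated at
    the midpoint of the intergenic gap; overlapping gene bodies truncate
    at the bodies themselves (logged).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    regions: list[GeneRegion] = []
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.start, g.end, g.gene_id))
        clen = chrom_lengths[chrom]
        for i, g in enumerate(gs):
            a_start = g.cds_start if g.cds_start is not None else g.start
            a_end = g.cds_end if g.cds_end is not None else g.end
            start = max(0, min(g.start, a_start - flank))
            end = min(clen, max(g.end, a_end + flank))
            if i > 0:
                prev = gs[i - 1]
                if prev.end > g.start:
                    log.warning(
                        "gene bodies overlap: %s and %s on %s", prev.gene_id, g.gene_id, chrom
                    )
                    start = max(start, g.start)
                else:
                    mid = (prev.end + g.start) // 2
                    start = max(start, min(mid, g.start))
            if i + 1 < len(gs):
                nxt = gs[i + 1]
                if g.end > nxt.start:
                    end = min(end, g.end)
                else:
                    mid = (g.end + nxt.start) // 2
                    end = min(end, max(mid, g.end))
            regions.append(GeneRegion(g.gene_id, chrom, start, end))
    regions.sort(key=lambda r: (r.chrom, r.start, r.gene_id))
    return regions


# ---------------------------------------------------------------------------
# seed-and-chain spliced alignment


@dataclass
class AlignParams:
    k: int = 15
    min_intron: int = 40
    max_intron: int = 10_000
    shift_window: int = 10
    min_identity: float = 0.95
    min_coverage: float = 0.80


def _index_kmers(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _anchor_segments(read: str, region: str, idx: dict[str, list[int]], k: int):
    """Maximal exact diagonal segments (qs, qe, ts) seeded by k-mer hits."""
    hits: list[tuple[int, int]] = []  # (diag, qpos)
    for i in range(len(read) - k + 1):
        for p in idx.get(read[i : i + k], ()):
            hits.append((p - i, i))
    hits.sort()
    segments: list[tuple[int, int, int]] = []
    prev_diag, seg_qs, seg_qe = None, 0, 0
    for diag, q in hits:
        if diag == prev_diag and q <= seg_qe:
            seg_qe = max(seg_qe, q + k)
        else:
            if prev_diag is not None:
                segments.append((seg_qs, seg_qe, seg_qs + prev_diag))
            prev_diag, seg_qs, seg_qe = diag, q, q + k
    if prev_diag is not None:
        segments.append((seg_qs, seg_qe, seg_qs + prev_diag))
    # extend each segment maximally (exact matches only)
    out = set()
    for qs, qe, ts in segments:
        d = ts - qs
        while qs > 0 and qs + d > 0 and read[qs - 1] == region[qs + d - 1]:
            qs -= 1
        while qe < len(read) and qe + d < len(region) and read[qe] == region[qe + d]:
            qe += 1
        out.add((qs, qe, qs + d))
    return sorted(out)


def _chain(segments, max_intron: int):
    """Collinear chain maximizing total exactly-matched length."""
    if not segments:
        return []
    n = len(segments)
    best = [qe - qs for qs, qe, _ in segments]
    back = [-1] * n
    for j in range(n):
        qs_j, qe_j, ts_j = segments[j]
        for i in range(j):
            qs_i, qe_i, ts_i = segments[i]
            te_i = ts_i + (qe_i - qs_i)
            # overlapping segment starts are trimmed at assembly time
            o = max(qe_i - qs_j, te_i - ts_j, 0)
            if qe_j - (qs_j + o) <= 0:
                continue
            if (ts_j + o) - te_i > max_intron:
                continue
            cand = best[i] + (qe_j - qs_j - o)
            if cand > best[j]:
                best[j] = cand
                back[j] = i
    j = max(range(n), key=lambda j: (best[j], -segments[j][0]))
    chain = []
    while j != -1:
        chain.append(segments[j])
        j = back[j]
    return chain[::-1]


def _shift_junction(read, region, qe, donor, acceptor, motifs, window):
    """Slide an inferred intron within +-window to land on splice motifs.

    Returns the preferred (donor, acceptor) pair.  A shift s is feasible
    when the s read bases at the junction match the genome on both sides;
    among feasible shifts with canonical motifs the smallest |s| wins,
    with 0 preferred outright when already canonical.
    """
    dm, am = motifs

    def canonical(d, a):
        return region[d : d + 2] == dm and region[a - 2 : a] == am

    if canonical(donor, acceptor):
        return donor, acceptor
    for s in sorted(range(-window, window + 1), key=abs):
        if s == 0:
            continue
        d, a = donor + s, acceptor + s
        if d < 1 or a + 1 > len(region):
            continue
        if s > 0:
            if read[qe : qe + s] != region[donor : donor + s]:
                continue
            if region[donor:d] != region[acceptor:a]:
                continue
        else:
            if read[qe + s : qe] != region[acceptor + s : acceptor]:
                continue
            if region[d:donor] != region[a:acceptor]:
                continue
        if canonical(d, a):
            return d, a
    return donor, acceptor


def _extend_end(read, region, q0, t0, direction, xdrop=6):
    """Greedy end extension with X-drop; returns (length, errors) kept."""
    best = cur = 0
    best_i = best_e = errs = 0
    i = 0
    while True:
        if direction < 0:
            q, t = q0 - 1 - i, t0 - 1 - i
            if q < 0 or t < 0:
                break
        else:
            q, t = q0 + i, t0 + i
            if q >= len(read) or t >= len(region):
                break
        if read[q] == region[t]:
            cur += 1
        else:
            cur -= 2
            errs += 1
        if cur > best:
            best, best_i, best_e = cur, i + 1, errs
        if cur <= best - xdrop:
            break
        i += 1
    return best_i, best_e


def _rescue_indel_end(read, region, blocks, side, min_len=6, max_len=20):
    """Place a short unanchored end across a small (1-2 nt) indel.

    The leftover bases must match exactly on a diagonal shifted by the
    indel size; the indel counts as that many errors.  Leftovers shorter
    than ``min_len`` are left unaligned (an exact match that short is
    uninformative).  Returns the error increment (0 when nothing was
    rescued).
    """
    if side == "left":
        t, ts = blocks[0][0], blocks[0][2]
        if not min_len <= t <= max_len:
            return 0
        head = read[:t]
        for d in (1, 2):  # deletion in the read: region has d extra bases
            if ts - d - t >= 0 and region[ts - d - t : ts - d] == head:
                blocks.insert(0, [0, t, ts - d - t, ts - d])
                return d
        for d in (1, 2):  # insertion in the read: d read bases unmatched
            if t - d >= 1 and ts - (t - d) >= 0 and region[ts - (t - d) : ts] == head[: t - d]:
                blocks.insert(0, [0, t - d, ts - (t - d), ts])
                return d
        return 0
    t = len(read) - blocks[-1][1]
    qe, te = blocks[-1][1], blocks[-1][3]
    if not min_len <= t <= max_len:
        return 0
    tail = read[qe:]
    for d in (1, 2):
        if te + d + t <= len(region) and region[te + d : te + d + t] == tail:
            blocks.append([qe, qe + t, te + d, te + d + t])
            return d
    for d in (1, 2):
        if t - d >= 1 and te + (t - d) <= len(region) and region[te : te + t - d] == tail[d:]:
            blocks.append([qe + d, qe + t, te, te + t - d])
            return d
    return 0


def _rescue_tail(read, region, blocks, side, motifs, min_intron):
    """Place a short unanchored read end across one more intron.

    Scans the region for a splice-consistent continuation (donor/acceptor
    motifs plus an exact match of the leftover bases) and appends a block
    only when exactly one candidate exists; ambiguity leaves the tail
    unaligned.  Rescues junction-straddling ends shorter than the k-mer
    anchor.
    """
    dm, am = motifs
    if side == "right":
        qe, te = blocks[-1][1], blocks[-1][3]
        t = len(read) - qe
        if t < 1 or region[te : te + 2] != dm:
            return
        tail = read[qe:]
        hits = []
        for a in range(te + min_intron, len(region) - t + 1):
            if region[a - 2 : a] == am and region[a : a + t] == tail:
                hits.append(a)
                if len(hits) > 1:
                    return
        if len(hits) == 1:
            blocks.append([qe, len(read), hits[0], hits[0] + t])
    else:
        qs, ts = blocks[0][0], blocks[0][2]
        t = qs
        if t < 1 or region[ts - 2 : ts] != am:
            return
        head = read[:qs]
        hits = []
        for d in range(0, ts - min_intron - t + 1):
            if region[d + t : d + t + 2] == dm and region[d : d + t] == head:
                hits.append(d)
                if len(hits) > 1:
                    return
        if len(hits) == 1:
            blocks.insert(0, [0, qs, hits[0], hits[0] + t])


def align_est(
    read_seq: str,
    region_seq: str,
    params: AlignParams | None = None,
    *,
    splice_motifs: tuple[str, str] = ("GT", "AG"),
    region_index: dict[str, list[int]] | None = None,
) -> tuple[list[tuple[int, int, int, int]], float, float] | None:
    """Align one EST to one gene-region sequence.

    Returns ``(blocks, identity, coverage)`` with region-local target
    coordinates, or None when no acceptable alignment exists.  Identity
    counts matches over aligned columns (indel columns count as errors);
    coverage is the fraction of the read inside blocks.
    """
    p = params or AlignParams()
    if len(read_seq) < p.k:
        return None
    idx = region_index if region_index is not None else _index_kmers(region_seq, p.k)
    segs = _anchor_segments(read_seq, region_seq, idx, p.k)
    chain = _chain(segs, p.max_intron)
    if not chain:
        return None

    blocks: list[list[int]] = []  # [qs, qe, ts, te]
    errors = 0
    for qs, qe, ts in chain:
        te = ts + (qe - qs)
        if blocks:
            pqs, pqe, pts, pte = blocks[-1]
            # trim the new segment so both gaps are non-negative
            o = max(pqe - qs, pte - ts, 0)
            qs, ts = qs + o, ts + o
            if qe <= qs:
                continue
            qgap = qs - pqe
            tgap = ts - pte
            if tgap < p.min_intron:
                # small genomic gap: absorb as mismatch/indel columns
                if qgap == tgap:
                    mism = sum(
                        1
                        for i in range(qgap)
                        if read_seq[pqe + i] != region_seq[pte + i]
                    )
                    errors += mism
                    blocks[-1][1], blocks[-1][3] = qe, te
                else:
                    errors += max(qgap, tgap)
                    blocks.append([qs, qe, ts, te])
                continue
            # genomic gap becomes an intron; clean junctions may slide to motifs
            if qgap == 0:
                d, a = _shift_junction(
                    read_seq, region_seq, pqe, pte, ts, splice_motifs, p.shift_window
                )
                s = d - pte
                if s:
                    blocks[-1][1] += s
                    blocks[-1][3] += s
                    qs += s
                    ts = a
            blocks.append([qs, qe, ts, te])
            continue
        blocks.append([qs, qe, ts, te])

    # first try splice-consistent placement of short unanchored ends, then
    # X-drop extension of the remaining ends (match +1, mismatch -2, drop 6)
    if blocks[0][0] > 0:
        _rescue_tail(read_seq, region_seq, blocks, "left", splice_motifs, p.min_intron)
    if blocks[0][0] > 0:
        errors += _rescue_indel_end(read_seq, region_seq, blocks, "left")
    if blocks[-1][1] < len(read_seq):
        _rescue_tail(read_seq, region_seq, blocks, "right", splice_motifs, p.min_intron)
    if blocks[-1][1] < len(read_seq):
        errors += _rescue_indel_end(read_seq, region_seq, blocks, "right")
    b = blocks[0]
    n_ext, e_ext = _extend_end(read_seq, region_seq, b[0], b[2], -1)
    b[0] -= n_ext
    b[2] -= n_ext
    errors += e_ext
    b = blocks[-1]
    n_ext, e_ext = _extend_end(read_seq, region_seq, b[1], b[3], +1)
    b[1] += n_ext
    b[3] += n_ext
    errors += e_ext

    aligned = sum(qe - qs for qs, qe, _, _ in blocks)
    if aligned == 0:
        return None
    identity = max(0.0, (aligned - errors) / aligned)
    coverage = aligned / len(read_seq)
    if identity < p.min_identity or coverage < p.min_coverage:
        return None
    return [tuple(b) for b in blocks], identity, coverage


# ---------------------------------------------------------------------------
# driver: map a read set against all gene regions


class RegionCatalog:
    """Gene regions with cached sequences and k-mer indexes."""

    def __init__(self, genome: dict[str, str], genes: Sequence[GeneModel], params: AlignParams):
        self.params = params
        self.genes = {g.gene_id: g for g in genes}
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        self.regions = {r.gene_id: r for r in define_gene_regions(genes, chrom_lengths)}
        self.seqs = {
            gid: genome[r.chrom][r.start : r.end] for gid, r in self.regions.items()
        }
        self.indexes = {gid: _index_kmers(s, params.k) for gid, s in self.seqs.items()}
        # global seed index: kmer -> [(gene_id, region-local pos)]
        self.seed_index: dict[str, list[tuple[str, int]]] = {}
        for gid, idx in self.indexes.items():
            for kmer, positions in idx.items():
                bucket = self.seed_index.setdefault(kmer, [])
                for p in positions:
                    bucket.append((gid, p))

    def candidate_genes(self, read: str) -> list[str]:
        votes: dict[str, int] = {}
        k = self.params.k
        for i in range(0, len(read) - k + 1, k):
            for gid, _ in self.seed_index.get(read[i : i + k], ()):
                votes[gid] = votes.get(gid, 0) + 1
        return sorted(votes, key=lambda g: (-votes[g], g))[:8]


def map_read(
    est_id: str,
    library: str,
    read_seq: str,
    catalog: RegionCatalog,
) -> list[SplicedAlignment]:
    """All accepted alignments of one read (both orientations)."""
    out: list[SplicedAlignment] = []
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        for gid in catalog.candidate_genes(seq):
            gene = catalog.genes[gid]
            region = catalog.regions[gid]
            motifs = ("GT", "AG") if gene.strand == "+" else ("CT", "AC")
            res = align_est(
                seq,
                catalog.seqs[gid],
                catalog.params,
                splice_motifs=motifs,
                region_index=catalog.indexes[gid],
            )
            if res is None:
                continue
            blocks, identity, coverage = res
            gblocks = [
                (qs, qe, ts + region.start, te + region.start) for qs, qe, ts, te in blocks
            ]
            out.append(
                SplicedAlignment(
                    est_id=est_id,
                    library=library,
                    gene_id=gid,
                    chrom=region.chrom,
                    strand=strand,
                    blocks=gblocks,
                    identity=identity,
                    coverage=coverage,
                    query_length=len(read_seq),
                    min_intron=catalog.params.min_intron,
                )
            )
    return out


def assign_to_gene(alignments: Sequence[SplicedAlignment]) -> SplicedAlignment | None:
    """Best alignment for one read: identity*coverage, then aligned length, then gene id."""
    if not alignments:
        return None
    return min(
        alignments,
        key=lambda a: (-a.score, -a.aligned_length, a.gene_id),
    )


def map_reads(
    reads: Iterable[tuple[str, str, str]],
    genome: dict[str, str],
    genes: Sequence[GeneModel],
    params: AlignParams | None = None,
) -> tuple[list[SplicedAlignment], int]:
    """Map (est_id, library, sequence) triples; returns (assignments, n_unmapped)."""
    catalog = RegionCatalog(genome, genes, params or AlignParams())
    assigned: list[SplicedAlignment] = []
    unmapped = 0
    for est_id, library, seq in reads:
        best = assign_to_gene(map_read(est_id, library, seq, catalog))
        if best is None:
            unmapped += 1
        else:
            assigned.append(best)
    return assigned, unmapped
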