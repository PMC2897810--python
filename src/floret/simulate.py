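"""Synthetic EST study generator.

Emulates a two-library 454-style EST experiment on a compact plant-like
genome: multi-exon genes with GT..AG introns, two near-isogenic lines
(G, the reference line, and H, carrying injected SNPs/indels), reads of
~175 nt mean length sampled uniformly along transcripts, differential
expression injected as a fold change on chosen genes, the five
alternative-splicing event types injected as alternative isoforms,
di- to hexa-nucleotide SSRs embedded in UTRs, and 454-style homopolymer
indel errors.

Every quantity downstream modules estimate is recorded in truth tables,
so the generator doubles as the oracle for end-to-end tests.

A single integer seed drives one RNG stream; sub-stages draw in a fixed
order, so a fixed seed yields byte-identical fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mapping import GeneModel, revcomp

AS_TYPES = ("AltD", "AltA", "AltP", "IntronR", "ExonS")
BASES = "ACGT"

# motif pool for injected SSRs (all primitive)
SSR_MOTIFS = ("AG", "AT", "AC", "AAG", "AAT", "ACC", "AGG", "AAAG", "AACAT", "AACGTC")


class InfeasibleConfig(ValueError):
    """Raised when a configuration cannot produce the requested features."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic EST experiment.

    Defaults follow the emulated study where it states a value (two
    libraries; mean read length 175 nt) and otherwise use desk-scale
    sizes a pilot EST screen would produce.
    """

    n_chromosomes: int = 2
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_len: tuple[int, int] = (90, 240)
    intron_len: tuple[int, int] = (60, 120)
    intergenic_len: tuple[int, int] = (300, 800)
    flank_utr_len: int = 60
    n_de_genes: int = 4
    de_fold: float = 4.0
    base_expression: float = 25.0
    expression_shape: float = 2.0
    library_sizes: tuple[int, int] = (1500, 1500)
    read_len_mean: float = 175.0
    read_len_sd: float = 50.0
    read_len_min: int = 40
    homopolymer_error_rate: float = 0.0
    n_as_events_per_type: tuple[int, int, int, int, int] = (1, 1, 1, 1, 1)
    as_alt_fraction: float = 0.5
    n_snps: int = 6
    n_indels: int = 3
    n_ssr_loci: int = 6
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "n_genes": self.n_genes,
            "n_de_genes": self.n_de_genes,
            "n_snps": self.n_snps,
            "n_indels": self.n_indels,
            "n_ssr_loci": self.n_ssr_loci,
        }
        for name, v in counts.items():
            if v < 0:
                raise InfeasibleConfig(f"{name} must be >= 0, got {v}")
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise InfeasibleConfig("need at least one chromosome and one gene")
        if self.de_fold <= 1:
            raise InfeasibleConfig(f"de_fold must exceed 1, got {self.de_fold}")
        if self.read_len_mean <= 0:
            raise InfeasibleConfig("read_len_mean must be positive")
        if any(n < 0 for n in self.n_as_events_per_type) or len(self.n_as_events_per_type) != 5:
            raise InfeasibleConfig("n_as_events_per_type must be five counts >= 0")
        n_as = sum(self.n_as_events_per_type)
        if n_as and self.exons_per_gene[1] < 2:
            raise InfeasibleConfig(
                "alternative-splicing events need multi-exon genes, "
                f"but exons_per_gene={self.exons_per_gene} allows none"
            )
        if self.n_as_events_per_type[4] and self.exons_per_gene[1] < 3:
            raise InfeasibleConfig("ExonS needs genes with >= 3 exons")
        if n_as > self.n_genes:
            raise InfeasibleConfig(
                f"{n_as} AS events requested but only {self.n_genes} genes (one event per gene)"
            )
        if (self.n_snps + self.n_indels) and n_as >= self.n_genes:
            raise InfeasibleConfig("SNP injection needs at least one gene without an AS event")
        if self.n_ssr_loci > self.n_genes:
            raise InfeasibleConfig("at most one SSR locus per gene")
        if any(n <= 0 for n in self.library_sizes):
            raise InfeasibleConfig("library sizes must be positive")
        if self.exon_len[0] < 4 * self.flank_utr_len // 3 + 20 and self.n_ssr_loci:
            # SSR + breaker bases must fit inside the UTR portion of exon 1
            if self.exon_len[0] < self.flank_utr_len + 8:
                raise InfeasibleConfig("exon_len too short for flank_utr_len SSR placement")


@dataclass(frozen=True)
class ASTruth:
    gene_id: str
    event_type: str
    introns: tuple[tuple[int, int], ...]  # genomic intervals, annotated first
    skipped_exon: tuple[int, int] | None = None


@dataclass(frozen=True)
class SNPTruth:
    gene_id: str
    transcript_pos: int  # 0-based on the canonical line-G transcript
    allele_a: str
    allele_b: str
    var_class: str  # transition | transversion | indel


@dataclass(frozen=True)
class SSRTruth:
    seq_id: str
    motif: str  # as it appears on the transcript
    repeats: int
    start: int  # transcript coordinates, 0-based half-open
    end: int


@dataclass
class TruthTables:
    de: dict[str, tuple[float, str]] = field(default_factory=dict)  # gene -> (fold, up lib)
    as_events: list[ASTruth] = field(default_factory=list)
    snps: list[SNPTruth] = field(default_factory=list)
    ssrs: list[SSRTruth] = field(default_factory=list)
    read_origin: dict[str, str] = field(default_factory=dict)  # read id -> gene id


@dataclass
class Fixture:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    alt_isoforms: dict[str, tuple[tuple[int, int], ...]]
    truth: TruthTables
    reads: dict[str, list[tuple[str, str]]] = field(default_factory=dict)  # lib -> [(id, seq)]
    expected_counts: dict[str, tuple[float, float]] = field(default_factory=dict)
    _rng: np.random.Generator | None = None

    @property
    def gene_index(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def transcript(self, gene_id: str) -> str:
        g = self.gene_index[gene_id]
        return g.spliced_sequence(self.genome[g.chrom])


# ---------------------------------------------------------------------------
# helpers


def _rand_seq(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(bytes(BASES, "ascii")[i] for i in rng.integers(0, 4, n))


def _pick_base(rng: np.random.Generator, exclude: set[int]) -> int:
    choices = [ord(b) for b in BASES if ord(b) not in exclude]
    return int(rng.choice(choices))


def _fix_junction(seq: bytearray, d: int, a: int, strand: str, rng: np.random.Generator) -> None:
    """Write splice motifs and disambiguating flank bases for intron [d, a)."""
    dm, am = (b"GT", b"AG") if strand == "+" else (b"CT", b"AC")
    seq[d : d + 2] = dm
    seq[a - 2 : a] = am
    if seq[a] == seq[d]:
        seq[a] = _pick_base(rng, {seq[d]})
    if seq[d - 1] == seq[a - 1]:
        seq[d - 1] = _pick_base(rng, {seq[a - 1]})


def _junction_ok(seq: bytearray, d: int, a: int, strand: str) -> bool:
    dm, am = (b"GT", b"AG") if strand == "+" else (b"CT", b"AC")
    return (
        bytes(seq[d : d + 2]) == dm
        and bytes(seq[a - 2 : a]) == am
        and seq[a] != seq[d]
        and seq[d - 1] != seq[a - 1]
    )


def _plus_offset(exons, pos: int) -> int:
    off = 0
    for s, e in exons:
        if s <= pos < e:
            return off + pos - s
        off += e - s
    raise ValueError(f"position {pos} not exonic")


def _t_interval(exons, strand: str, gs: int, ge: int) -> tuple[int, int]:
    """Transcript interval of an exonic genomic interval [gs, ge)."""
    length = sum(e - s for s, e in exons)
    a = _plus_offset(exons, gs)
    b = _plus_offset(exons, ge - 1) + 1
    if strand == "+":
        return a, b
    return length - b, length - a


def homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal homopolymer runs as (start, length)."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        runs.append((i, j - i))
        i = j
    return runs


def run_length_at(seq: str, pos: int) -> int:
    i = pos
    while i > 0 and seq[i - 1] == seq[pos]:
        i -= 1
    j = pos
    while j + 1 < len(seq) and seq[j + 1] == seq[pos]:
        j += 1
    return j - i + 1


TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


# ---------------------------------------------------------------------------
# genome generation


def generate_genome(config: SimulationConfig) -> Fixture:
    """Build chromosomes, gene models, alternative isoforms and marker truth.

    Deterministic for a fixed seed.  Raises :class:`InfeasibleConfig` when
    the requested features cannot coexist (e.g. intron-requiring events on
    single-exon genes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    gene_ids = [f"g{i + 1:04d}" for i in range(n)]

    # role assignment (fixed draw order)
    as_roles: dict[int, str] = {}
    n_as = sum(config.n_as_events_per_type)
    if n_as:
        hosts = rng.choice(n, size=n_as, replace=False)
        k = 0
        for t, cnt in zip(AS_TYPES, config.n_as_events_per_type):
            for _ in range(cnt):
                as_roles[int(hosts[k])] = t
                k += 1
    ssr_hosts = set(
        int(i) for i in rng.choice(n, size=config.n_ssr_loci, replace=False)
    ) if config.n_ssr_loci else set()
    strands = ["+" if b else "-" for b in rng.integers(0, 2, n)]

    lo, hi = config.exons_per_gene
    exon_counts = rng.integers(lo, hi + 1, n)
    for i, role in as_roles.items():
        need = 3 if role == "ExonS" else 2
        if exon_counts[i] < need:
            exon_counts[i] = need

    chrom_of = {i: f"chr{(i % config.n_chromosomes) + 1}" for i in range(n)}

    chrom_seqs: dict[str, bytearray] = {}
    chrom_cursor: dict[str, int] = {}
    genes: list[GeneModel] = []
    alt_isoforms: dict[str, tuple[tuple[int, int], ...]] = {}
    truth = TruthTables()
    junctions_to_fix: list[tuple[str, int, int, str]] = []
    ssr_pending: list[tuple[int, str, int, int, int]] = []  # gene idx, motif, k, gstart, gend

    for i in range(n):
        chrom = chrom_of[i]
        if chrom not in chrom_seqs:
            chrom_seqs[chrom] = bytearray()
            chrom_cursor[chrom] = 0
        seq = chrom_seqs[chrom]
        seq += _rand_seq(rng, int(rng.integers(*config.intergenic_len)))

        ne = int(exon_counts[i])
        exon_lens = [int(rng.integers(config.exon_len[0], config.exon_len[1] + 1)) for _ in range(ne)]
        intron_lens = [
            int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            for _ in range(ne - 1)
        ]
        strand = strands[i]
        gstart = len(seq)
        exons = []
        for j, el in enumerate(exon_lens):
            es = len(seq)
            seq += _rand_seq(rng, el)
            exons.append((es, es + el))
            if j < ne - 1:
                iv = len(seq)
                seq += _rand_seq(rng, intron_lens[j])
                junctions_to_fix.append((chrom, iv, iv + intron_lens[j], strand))
        gend = len(seq)

        utr = min(config.flank_utr_len, min(exon_lens) // 2)
        gene = GeneModel(
            gene_id=gene_ids[i],
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            cds_start=gstart + utr,
            cds_end=gend - utr,
        )
        genes.append(gene)

        # SSR in the UTR portion of the genomic-first exon
        if i in ssr_hosts:
            motif = str(rng.choice(SSR_MOTIFS))
            u = len(motif)
            kmin = 6 if u == 2 else 5
            k_rep = kmin + int(rng.integers(0, 4))
            start = exons[0][0] + 4
            if start + u * k_rep + 1 >= exons[0][1]:
                k_rep = kmin
            if start + u * k_rep + 1 < exons[0][1]:
                ssr_pending.append((i, motif, k_rep, start, start + u * k_rep))

        # alternative isoform for AS hosts
        role = as_roles.get(i)
        if role:
            introns = gene.introns
            delta = 12 + int(rng.integers(0, 6))
            if role == "IntronR":
                iv = introns[0]
                alt = [(exons[0][0], exons[1][1])] + list(exons[2:])
                truth.as_events.append(ASTruth(gene.gene_id, role, (iv,)))
            elif role == "ExonS":
                j1, j2 = introns[0], introns[1]
                alt = [exons[0], *exons[2:]]
                skip = (j1[1], j2[0])
                truth.as_events.append(
                    ASTruth(gene.gene_id, role, (j1, j2, (j1[0], j2[1])), skipped_exon=skip)
                )
                junctions_to_fix.append((chrom, j1[0], j2[1], strand))
            else:
                s0, e0 = introns[0]
                if role == "AltD":
                    alt_iv = (s0 - delta, e0) if strand == "+" else (s0, e0 + delta)
                elif role == "AltA":
                    alt_iv = (s0, e0 + delta) if strand == "+" else (s0 - delta, e0)
                else:  # AltP: overlap, share neither boundary
                    alt_iv = (s0 + delta, e0 + delta)
                alt = list(exons)
                alt[0] = (exons[0][0], alt_iv[0])
                alt[1] = (alt_iv[1], exons[1][1])
                truth.as_events.append(ASTruth(gene.gene_id, role, ((s0, e0), alt_iv)))
                junctions_to_fix.append((chrom, alt_iv[0], alt_iv[1], strand))
            alt_isoforms[gene.gene_id] = tuple(alt)

    # settle splice junctions; a couple of passes resolve shared neighborhoods
    for _ in range(6):
        dirty = False
        for chrom, d, a, strand in junctions_to_fix:
            if not _junction_ok(chrom_seqs[chrom], d, a, strand):
                _fix_junction(chrom_seqs[chrom], d, a, strand, rng)
                dirty = True
        if not dirty:
            break
    else:
        raise RuntimeError("junction disambiguation did not converge")

    # write SSRs (UTRs are far from junction neighborhoods by construction)
    for i, motif, k_rep, gs, ge in ssr_pending:
        gene = genes[i]
        seq = chrom_seqs[gene.chrom]
        seq[gs:ge] = (motif * k_rep).encode()
        if seq[gs - 1] == ord(motif[-1]):
            seq[gs - 1] = _pick_base(rng, {ord(motif[-1])})
        if seq[ge] == ord(motif[0]):
            seq[ge] = _pick_base(rng, {ord(motif[0])})
        ts, te = _t_interval(gene.exons, gene.strand, gs, ge)
        tseq = gene.spliced_sequence(bytes(seq).decode())
        truth.ssrs.append(
            SSRTruth(gene.gene_id, tseq[ts : ts + len(motif)], k_rep, ts, te)
        )

    genome = {c: bytes(s).decode() for c, s in chrom_seqs.items()}
    fixture = Fixture(
        config=config,
        genome=genome,
        genes=genes,
        alt_isoforms=alt_isoforms,
        truth=truth,
        _rng=rng,
    )
    _inject_variants(fixture, rng)
    return fixture


def _inject_variants(fixture: Fixture, rng: np.random.Generator) -> None:
    """Choose inter-line SNP/indel sites on canonical transcripts of non-AS genes."""
    cfg = fixture.config
    non_as = [g for g in fixture.genes if g.gene_id not in fixture.alt_isoforms]
    if not (cfg.n_snps + cfg.n_indels):
        return
    taken: dict[str, list[int]] = {}
    k_guard = 17  # keep variants clear of splice junctions in read space

    def junction_offsets(g: GeneModel) -> list[int]:
        offs, acc = [], 0
        for s, e in g.exons[:-1]:
            acc += e - s
            offs.append(acc)
        L = g.transcript_length()
        return offs if g.strand == "+" else [L - o for o in offs]

    def place(kind: str) -> SNPTruth | None:
        for _ in range(300):
            g = non_as[int(rng.integers(len(non_as)))]
            t = fixture.transcript(g.gene_id)
            L = len(t)
            if L < 2 * k_guard + 10:
                continue
            p = int(rng.integers(k_guard, L - k_guard))
            if any(abs(p - j) < k_guard for j in junction_offsets(g)):
                continue
            if any(abs(p - q) < 25 for q in taken.get(g.gene_id, [])):
                continue
            if kind == "indel":
                # unique gap placement (deleted base differs from neighbors)
                # and no >= 3 homopolymer in the filter window
                if run_length_at(t, p) != 1:
                    continue
                if max(run_length_at(t, q) for q in (p - 1, p, p + 1)) >= 3:
                    continue
                rec = SNPTruth(g.gene_id, p, t[p], "-", "indel")
            else:
                a = t[p]
                if rng.random() < 0.5:
                    b, cls = TRANSITIONS[a], "transition"
                else:
                    b, cls = str(rng.choice(list(TRANSVERSIONS[a]))), "transversion"
                # avoid alternative equal-cost gapped alignments: the variant
                # allele must differ from both neighboring consensus bases
                if b in (t[p - 1], t[p + 1]):
                    continue
                rec = SNPTruth(g.gene_id, p, a, b, cls)
            taken.setdefault(g.gene_id, []).append(p)
            return rec
        return None

    for _ in range(cfg.n_snps):
        rec = place("snp")
        if rec:
            fixture.truth.snps.append(rec)
    for _ in range(cfg.n_indels):
        rec = place("indel")
        if rec:
            fixture.truth.snps.append(rec)


# ---------------------------------------------------------------------------
# library simulation


def line_transcript(fixture: Fixture, gene_id: str, line: str) -> str:
    """Canonical transcript of a gene for line G (reference) or H (variants applied)."""
    t = fixture.transcript(gene_id)
    if line == "G":
        return t
    edits = sorted(
        (v.transcript_pos, v.allele_b) for v in fixture.truth.snps if v.gene_id == gene_id
    )
    out, prev = [], 0
    for p, b in edits:
        out.append(t[prev:p])
        if b != "-":
            out.append(b)
        prev = p + 1
    out.append(t[prev:])
    return "".join(out)


def _apply_homopolymer_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    out = []
    i = 0
    while i < len(read):
        j = i
        while j < len(read) and read[j] == read[i]:
            j += 1
        run = read[i:j]
        if j - i >= 3 and rng.random() < rate:
            if rng.random() < 0.5:
                run = run + read[i]  # over-call: insert one base
            else:
                run = run[:-1]  # under-call: delete one base
        out.append(run)
        i = j
    return "".join(out)


def _draw_len(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    L = int(round(rng.normal(cfg.read_len_mean, cfg.read_len_sd)))
    return max(cfg.read_len_min, L)


def _alt_junction_offset(fixture: Fixture, ev: ASTruth) -> tuple[int, int]:
    """(start, end) of the event footprint on the alternative transcript."""
    g = fixture.gene_index[ev.gene_id]
    alt = fixture.alt_isoforms[ev.gene_id]
    L = sum(e - s for s, e in alt)
    if ev.event_type == "IntronR":
        iv = ev.introns[0]
        return _t_interval(alt, g.strand, iv[0], iv[1])
    alt_iv = ev.introns[-1]  # the EST-specific intron
    off = 0
    for s, e in alt:
        if e == alt_iv[0]:
            off += e - s
            break
        off += e - s
    j = off if g.strand == "+" else L - off
    return j, j


def simulate_libraries(fixture: Fixture) -> Fixture:
    """Sample the two EST libraries and complete the truth tables.

    Read counts per gene are multinomial over gamma-distributed gene
    weights, with DE genes scaled by the configured fold in their "up"
    library; the totals match ``library_sizes`` exactly.  One guided read
    per injected AS event (library G, line G) guarantees that each event
    is covered; all remaining reads sample transcript positions uniformly.
    """
    cfg = fixture.config
    rng = fixture._rng if fixture._rng is not None else np.random.default_rng(cfg.seed + 1)
    n = len(fixture.genes)
    gene_ids = [g.gene_id for g in fixture.genes]

    shape = cfg.expression_shape
    weights = rng.gamma(shape, cfg.base_expression / shape, n)
    weights = np.maximum(weights, 1e-3)

    fixture.truth.de = {}
    fold_vec = {"G": np.ones(n), "H": np.ones(n)}
    if cfg.n_de_genes and cfg.de_fold > 1:
        de_idx = rng.choice(n, size=min(cfg.n_de_genes, n), replace=False)
        for r, i in enumerate(de_idx):
            up = "G" if r % 2 == 0 else "H"
            fold_vec[up][i] = cfg.de_fold
            fixture.truth.de[gene_ids[int(i)]] = (cfg.de_fold, up)

    # guided reads: one per AS event, in library G from line G
    guided: list[tuple[str, str]] = []  # (gene_id, seq)
    for ev in fixture.truth.as_events:
        g = fixture.gene_index[ev.gene_id]
        alt = fixture.alt_isoforms[ev.gene_id]
        chrom_seq = fixture.genome[g.chrom]
        t_alt = "".join(chrom_seq[s:e] for s, e in alt)
        if g.strand == "-":
            t_alt = revcomp(t_alt)
        a, b = _alt_junction_offset(fixture, ev)
        need = (b - a) + 2 * 24
        L = max(_draw_len(cfg, rng), need)
        L = min(L, len(t_alt))
        start = max(0, min((a + b) // 2 - L // 2, len(t_alt) - L))
        guided.append((ev.gene_id, t_alt[start : start + L]))

    counters = {"G": 0, "H": 0}
    fixture.reads = {"G": [], "H": []}
    expected: dict[str, list[float]] = {gid: [0.0, 0.0] for gid in gene_ids}

    for li, lib in enumerate(("G", "H")):
        w = weights * fold_vec[lib]
        p = w / w.sum()
        n_guided = len(guided) if lib == "G" else 0
        N = cfg.library_sizes[li]
        if N < n_guided:
            raise InfeasibleConfig("library size smaller than number of guided AS reads")
        counts = rng.multinomial(N - n_guided, p)
        for gid, e in zip(gene_ids, (N - n_guided) * p):
            expected[gid][li] = float(e)
        emitted: list[tuple[str, str]] = []
        if lib == "G":
            emitted.extend(guided)
        for gi, c in enumerate(counts):
            gid = gene_ids[gi]
            t_can = line_transcript(fixture, gid, lib if gid not in fixture.alt_isoforms else "G")
            g = fixture.gene_index[gid]
            t_alt = None
            if gid in fixture.alt_isoforms:
                chrom_seq = fixture.genome[g.chrom]
                t_alt = "".join(chrom_seq[s:e] for s, e in fixture.alt_isoforms[gid])
                if g.strand == "-":
                    t_alt = revcomp(t_alt)
            for _ in range(int(c)):
                t = t_can
                if t_alt is not None and rng.random() < cfg.as_alt_fraction:
                    t = t_alt
                L = min(_draw_len(cfg, rng), len(t))
                start = int(rng.integers(0, len(t) - L + 1))
                emitted.append((gid, t[start : start + L]))
        for gid, seq in emitted:
            seq = _apply_homopolymer_errors(seq, cfg.homopolymer_error_rate, rng)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rid = f"{lib}|r{counters[lib]:06d}"
            counters[lib] += 1
            fixture.reads[lib].append((rid, seq))
            fixture.truth.read_origin[rid] = gid

    fixture.expected_counts = {gid: (v[0], v[1]) for gid, v in expected.items()}
    return fixture


def simulate_study(config: SimulationConfig) -> Fixture:
    """Full run: genome + libraries."""
    return simulate_libraries(generate_genome(config))


def draw_count_matrix(config: SimulationConfig):
    """Count-level draw of the two-library experiment (no reads).

    Uses the same expression model as :func:`simulate_libraries`:
    gamma-distributed gene weights, the configured fold applied to DE
    genes in their "up" library (alternating G/H), and multinomial
    library sampling so totals equal ``library_sizes`` exactly.
    Returns ``(counts, truth)`` where ``counts`` is a gene x {G, H}
    DataFrame with ``attrs["library_sizes"]`` set, and ``truth`` maps
    DE genes to (fold, up library).  Also records each gene's expected
    counts in ``counts[["expected_G", "expected_H"]]``.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"g{i + 1:04d}" for i in range(n)]
    shape = config.expression_shape
    weights = np.maximum(rng.gamma(shape, config.base_expression / shape, n), 1e-3)
    truth: dict[str, tuple[float, str]] = {}
    fold_vec = {"G": np.ones(n), "H": np.ones(n)}
    if config.n_de_genes and config.de_fold > 1:
        de_idx = rng.choice(n, size=min(config.n_de_genes, n), replace=False)
        for r, i in enumerate(de_idx):
            up = "G" if r % 2 == 0 else "H"
            fold_vec[up][i] = config.de_fold
            truth[gene_ids[int(i)]] = (config.de_fold, up)
    data = {}
    expected = {}
    for li, lib in enumerate(("G", "H")):
        w = weights * fold_vec[lib]
        p = w / w.sum()
        data[lib] = rng.multinomial(config.library_sizes[li], p)
        expected[lib] = config.library_sizes[li] * p
    counts = pd.DataFrame(data, index=gene_ids)
    counts.attrs["library_sizes"] = {
        "G": int(config.library_sizes[0]), "H": int(config.library_sizes[1])
    }
    counts["expected_G"] = expected["G"]
    counts["expected_H"] = expected["H"]
    return counts, truth


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(fixture: Fixture, directory: str | os.PathLike) -> None:
    """Write genome.fa, genes.gff3, reads_G.fa, reads_H.fa and truth_*.tsv."""
    from . import io as fio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fio.write_fasta(sorted(fixture.genome.items()), d / "genome.fa")
    fio.write_gff3(fixture.genes, d / "genes.gff3")
    for lib in ("G", "H"):
        fio.write_fasta(fixture.reads.get(lib, []), d / f"reads_{lib}.fa")
    with open(d / "truth_de.tsv", "w") as fh:
        fh.write("gene_id\tfold\tup_library\n")
        for gid, (fold, up) in sorted(fixture.truth.de.items()):
            fh.write(f"{gid}\t{fold:g}\t{up}\n")
    with open(d / "truth_as.tsv", "w") as fh:
        fh.write("gene_id\tevent_type\tintrons\tskipped_exon\n")
        for ev in fixture.truth.as_events:
            iv = ";".join(f"{s}-{e}" for s, e in ev.introns)
            sk = f"{ev.skipped_exon[0]}-{ev.skipped_exon[1]}" if ev.skipped_exon else "."
            fh.write(f"{ev.gene_id}\t{ev.event_type}\t{iv}\t{sk}\n")
    with open(d / "truth_snp.tsv", "w") as fh:
        fh.write("gene_id\ttranscript_pos\tallele_a\tallele_b\tclass\n")
        for v in fixture.truth.snps:
            fh.write(f"{v.gene_id}\t{v.transcript_pos}\t{v.allele_a}\t{v.allele_b}\t{v.var_class}\n")
    with open(d / "truth_ssr.tsv", "w") as fh:
        fh.write("seq_id\tmotif\trepeats\tstart\tend\n")
        for s in fixture.truth.ssrs:
            fh.write(f"{s.seq_id}\t{s.motif}\t{s.repeats}\t{s.start}\t{s.end}\n")
    with open(d / "truth_reads.tsv", "w") as fh:
        fh.write("read_id\tgene_id\n")
        for rid, gid in fixture.truth.read_origin.items():
            fh.write(f"{rid}\t{gid}\n")


def read_fixture(directory: str | os.PathLike) -> Fixture:
    """Re-read a written fixture (truth tables and sequences, no RNG state)."""
    from . import io as fio

    d = Path(directory)
    genome = fio.read_fasta(d / "genome.fa")
    genes = fio.read_gff3_genes(d / "genes.gff3")
    truth = TruthTables()
    with open(d / "truth_de.tsv") as fh:
        next(fh)
        for line in fh:
            gid, fold, up = line.split()
            truth.de[gid] = (float(fold), up)
    with open(d / "truth_as.tsv") as fh:
        next(fh)
        for line in fh:
            gid, et, iv, sk = line.rstrip("\n").split("\t")
            introns = tuple(
                tuple(int(x) for x in part.split("-")) for part in iv.split(";")
            )
            skipped = None
            if sk != ".":
                a, b = sk.split("-")
                skipped = (int(a), int(b))
            truth.as_events.append(ASTruth(gid, et, introns, skipped))
    with open(d / "truth_snp.tsv") as fh:
        next(fh)
        for line in fh:
            gid, p, a, b, cls = line.split()
            truth.snps.append(SNPTruth(gid, int(p), a, b, cls))
    with open(d / "truth_ssr.tsv") as fh:
        next(fh)
        for line in fh:
            sid, motif, k, s, e = line.split()
            truth.ssrs.append(SSRTruth(sid, motif, int(k), int(s), int(e)))
    reads = {
        lib: list(fio.read_fasta(d / f"reads_{lib}.fa").items()) for lib in ("G", "H")
    }
    ro_path = d / "truth_reads.tsv"
    if ro_path.exists():
        with open(ro_path) as fh:
            next(fh)
            for line in fh:
                rid, gid = line.split()
                truth.read_origin[rid] = gid
    return Fixture(
        config=SimulationConfig(),
        genome=genome,
        genes=genes,
        alt_isoforms={},
        truth=truth,
        reads=reads,
    )
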