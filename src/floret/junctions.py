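"""Intron-exon junction extraction and alternative-splicing classification.

Junctions are de-duplicated introns read off spliced alignments; each
needs at least ``min_overhang`` aligned nucleotides on both flanks.
Events are classified against the union of annotated and EST-derived
introns into five types with a fixed precedence:

  ExonS   an intron i spans two disjoint introns j1, j2 exactly
          (i.start = j1.start, i.end = j2.end); the skipped exon is
          [j1.end, j2.start)
  AltD    two overlapping introns share the acceptor, donors differ
  AltA    share the donor, acceptors differ
  AltP    overlap but share neither boundary (and are not part of an
          ExonS triple)
  IntronR an intron exists and some EST block contiguously covers it
          plus ``retention_overhang`` nt on both sides (orthogonal to
          the pairwise logic)

Donor and acceptor are strand-aware: on the plus strand the donor is
the intron start, on the minus strand the intron end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .mapping import GeneModel, SplicedAlignment

AS_TYPES = ("AltD", "AltA", "AltP", "IntronR", "ExonS")


@dataclass(frozen=True)
class Junction:
    gene_id: str
    start: int
    end: int
    strand: str
    support: int  # number of distinct supporting ESTs (0 for annotation-only)
    annotated: bool
    est_ids: tuple[str, ...] = ()

    @property
    def donor(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ASEvent:
    event_type: str
    gene_id: str
    introns: tuple[tuple[int, int], ...]
    skipped_exon: tuple[int, int] | None = None
    est_ids: tuple[str, ...] = ()


def extract_junctions(
    alignments: Iterable[SplicedAlignment],
    genes: Sequence[GeneModel] | dict[str, GeneModel],
    min_overhang: int = 8,
) -> list[Junction]:
    """One junction per distinct (gene, intron interval) seen in ESTs.

    A junction from one alignment is kept only when the flanking blocks
    carry at least ``min_overhang`` aligned nucleotides each.  Support
    counts distinct EST ids; the ``annotated`` flag marks exact interval
    matches with the gene model's introns.
    """
    gene_map = genes if isinstance(genes, dict) else {g.gene_id: g for g in genes}
    seen: dict[tuple[str, int, int], set[str]] = {}
    for aln in alignments:
        if aln.gene_id not in gene_map:
            raise KeyError(f"alignment on unknown gene {aln.gene_id!r}")
        blocks = aln.blocks
        for left, right in zip(blocks, blocks[1:]):
            ts_gap = right[2] - left[3]
            if ts_gap < aln.min_intron:
                continue
            if (left[1] - left[0]) < min_overhang or (right[1] - right[0]) < min_overhang:
                continue
            seen.setdefault((aln.gene_id, left[3], right[2]), set()).add(aln.est_id)
    out = []
    for (gid, s, e), ests in sorted(seen.items()):
        g = gene_map[gid]
        out.append(
            Junction(
                gene_id=gid,
                start=s,
                end=e,
                strand=g.strand,
                support=len(ests),
                annotated=(s, e) in set(g.introns),
                est_ids=tuple(sorted(ests)),
            )
        )
    return out


def annotated_junctions(genes: Iterable[GeneModel]) -> list[Junction]:
    return [
        Junction(g.gene_id, s, e, g.strand, support=0, annotated=True)
        for g in genes
        for s, e in g.introns
    ]


def junction_concordance(
    observed: Iterable[Junction], genes: Iterable[GeneModel]
) -> float:
    """Fraction of observed junctions exactly matching an annotated intron."""
    annotated = {(g.gene_id, s, e) for g in genes for s, e in g.introns}
    obs = [(j.gene_id, j.start, j.end) for j in observed]
    if not obs:
        return float("nan")
    return sum(1 for o in obs if o in annotated) / len(obs)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_events(
    junctions: Sequence[Junction],
    alignments: Iterable[SplicedAlignment],
    genes: Sequence[GeneModel] | dict[str, GeneModel],
    retention_overhang: int = 8,
) -> list[ASEvent]:
    """Classify AS events per gene from the union of annotated and EST introns.

    Every event involves EST evidence: a pairwise event needs at least
    one EST-supported intron, and intron retention needs an EST block
    covering the intron with flanking overhang.  Duplicates collapse.
    """
    gene_map = genes if isinstance(genes, dict) else {g.gene_id: g for g in genes}

    by_gene: dict[str, dict[tuple[int, int], Junction]] = {}
    for j in junctions:
        if j.gene_id not in gene_map:
            raise KeyError(f"junction on unknown gene {j.gene_id!r}")
        by_gene.setdefault(j.gene_id, {})[j.interval] = j
    for j in annotated_junctions(gene_map.values()):
        by_gene.setdefault(j.gene_id, {}).setdefault(j.interval, j)

    # per-gene EST blocks for the retention test
    blocks_by_gene: dict[str, list[tuple[int, int, str]]] = {}
    for aln in alignments:
        for qs, qe, ts, te in aln.blocks:
            blocks_by_gene.setdefault(aln.gene_id, []).append((ts, te, aln.est_id))

    events: dict[tuple, ASEvent] = {}
    for gid, jmap in sorted(by_gene.items()):
        strand = gene_map[gid].strand
        ivs = sorted(jmap)

        # (1) ExonS triples, consuming their pairs
        consumed: set[frozenset] = set()
        for i_iv in ivs:
            for j1 in ivs:
                if j1 == i_iv or j1[0] != i_iv[0] or j1[1] >= i_iv[1]:
                    continue
                for j2 in ivs:
                    if j2 in (i_iv, j1) or j2[1] != i_iv[1] or j2[0] <= j1[1]:
                        continue
                    trio = (jmap[i_iv], jmap[j1], jmap[j2])
                    if not any(t.support for t in trio):
                        continue
                    key = (gid, "ExonS", i_iv, j1, j2)
                    events[key] = ASEvent(
                        "ExonS",
                        gid,
                        (j1, j2, i_iv),
                        skipped_exon=(j1[1], j2[0]),
                        est_ids=tuple(
                            sorted(set().union(*(t.est_ids for t in trio)))
                        ),
                    )
                    consumed.add(frozenset((i_iv, j1)))
                    consumed.add(frozenset((i_iv, j2)))

        # (2)-(4) pairwise donor/acceptor comparison
        for a_idx in range(len(ivs)):
            for b_idx in range(a_idx + 1, len(ivs)):
                a, b = ivs[a_idx], ivs[b_idx]
                if frozenset((a, b)) in consumed or not _overlap(a, b):
                    continue
                ja, jb = jmap[a], jmap[b]
                if not (ja.support or jb.support):
                    continue
                if ja.donor == jb.donor and ja.acceptor != jb.acceptor:
                    etype = "AltA"
                elif ja.acceptor == jb.acceptor and ja.donor != jb.donor:
                    etype = "AltD"
                elif ja.donor != jb.donor and ja.acceptor != jb.acceptor:
                    etype = "AltP"
                else:
                    continue
                key = (gid, etype, a, b)
                events[key] = ASEvent(
                    etype,
                    gid,
                    (a, b),
                    est_ids=tuple(sorted(set(ja.est_ids) | set(jb.est_ids))),
                )

        # IntronR: an EST block contiguously covers intron +- overhang
        gblocks = blocks_by_gene.get(gid, [])
        for iv in ivs:
            lo, hi = iv[0] - retention_overhang, iv[1] + retention_overhang
            supp = sorted({est for ts, te, est in gblocks if ts <= lo and te >= hi})
            if supp:
                events[(gid, "IntronR", iv)] = ASEvent(
                    "IntronR", gid, (iv,), est_ids=tuple(supp)
                )

    return [events[k] for k in sorted(events, key=str)]


def summarize_as(events: Iterable[ASEvent]) -> pd.DataFrame:
    """Per-type tallies of events and of distinct genes, with percentages."""
    rows = []
    events = list(events)
    total_e = len(events)
    genes_any = {e.gene_id for e in events}
    for t in AS_TYPES:
        evs = [e for e in events if e.event_type == t]
        ngenes = len({e.gene_id for e in evs})
        rows.append(
            {
                "type": t,
                "n_genes": ngenes,
                "pct_genes": 100.0 * ngenes / len(genes_any) if genes_any else 0.0,
                "n_events": len(evs),
                "pct_events": 100.0 * len(evs) / total_e if total_e else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("type")
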