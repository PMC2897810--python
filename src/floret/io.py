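"""File I/O: FASTA, GFF3 gene models, PSL / GFF3 spliced alignments, TSV tables.

Internal coordinates are 0-based half-open; GFF3 files are written and
read 1-based inclusive, PSL is 0-based half-open as defined by BLAT.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mapping import GeneModel, SplicedAlignment

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs)
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon(/CDS) features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            row = [g.chrom, "floret", "gene", str(g.start + 1), str(g.end), ".", g.strand, "."]
            fh.write("\t".join(row + [f"ID={g.gene_id}"]) + "\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(
                "\t".join(
                    [g.chrom, "floret", "mRNA", str(g.start + 1), str(g.end), ".", g.strand, ".",
                     f"ID={mrna};Parent={g.gene_id}"]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        [g.chrom, "floret", "exon", str(s + 1), str(e), ".", g.strand, ".",
                         f"ID={mrna}.exon{i};Parent={mrna}"]
                    )
                    + "\n"
                )
            if g.cds_start is not None and g.cds_end is not None:
                for s, e in g.exons:
                    cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                    if cs < ce:
                        fh.write(
                            "\t".join(
                                [g.chrom, "floret", "CDS", str(cs + 1), str(ce), ".", g.strand,
                                 "0", f"ID={mrna}.cds;Parent={mrna}"]
                            )
                            + "\n"
                        )


def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3 via gffutils (in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gf in db.features_of_type("gene"):
        exons = []
        cds_start = cds_end = None
        for child in db.children(gf.id, featuretype="exon", order_by="start"):
            exons.append((child.start - 1, child.end))
        for child in db.children(gf.id, featuretype="CDS", order_by="start"):
            cds_start = child.start - 1 if cds_start is None else min(cds_start, child.start - 1)
            cds_end = child.end if cds_end is None else max(cds_end, child.end)
        if not exons:
            exons = [(gf.start - 1, gf.end)]
        genes.append(
            GeneModel(
                gene_id=gf.id,
                chrom=gf.seqid,
                strand=gf.strand if gf.strand in "+-" else "+",
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# external spliced alignments (PSL and GFF3 match/match_part)


def _psl_row_to_alignment(fields: list[str], gene_by_target) -> SplicedAlignment:
    matches, mismatches, rep = int(fields[0]), int(fields[1]), int(fields[2])
    strand = fields[8]
    qname, qsize = fields[9], int(fields[10])
    tname = fields[13]
    sizes = [int(x) for x in fields[18].rstrip(",").split(",")]
    qstarts = [int(x) for x in fields[19].rstrip(",").split(",")]
    tstarts = [int(x) for x in fields[20].rstrip(",").split(",")]
    blocks = [
        (qs, qs + sz, ts, ts + sz) for sz, qs, ts in zip(sizes, qstarts, tstarts)
    ]
    aligned = matches + mismatches + rep
    identity = matches / aligned if aligned else 0.0
    coverage = aligned / qsize if qsize else 0.0
    gene_id, chrom = gene_by_target(tname)
    library = qname.split("|", 1)[0] if "|" in qname else ""
    return SplicedAlignment(
        est_id=qname,
        library=library,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand[0] if strand else "+",
        blocks=blocks,
        identity=identity,
        coverage=coverage,
        query_length=qsize,
    )


def read_alignments(
    path: str | os.PathLike,
    fmt: str,
    genes: Sequence[GeneModel] | None = None,
    min_identity: float = 0.95,
    min_coverage: float = 0.80,
) -> tuple[list[SplicedAlignment], int]:
    """Ingest externally produced spliced alignments (PSL or GFF3).

    The same identity/coverage acceptance rule used by the internal
    aligner is applied; malformed lines are skipped and counted.
    Targets must name a known gene or chromosome of ``genes``.
    Returns (accepted alignments, number of skipped/rejected rows).
    """
    gene_ids = {g.gene_id: g for g in genes or []}
    chroms = {g.chrom for g in genes or []}

    def gene_by_target(tname: str) -> tuple[str, str]:
        if tname in gene_ids:
            return tname, gene_ids[tname].chrom
        if not genes or tname in chroms:
            return "", tname
        raise ValueError(f"unknown alignment target {tname!r}")

    accepted: list[SplicedAlignment] = []
    skipped = 0
    fmt = fmt.upper()
    if fmt == "PSL":
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or not line[0].isdigit():
                    continue  # header lines
                fields = line.split("\t")
                if len(fields) < 21:
                    skipped += 1
                    continue
                try:
                    aln = _psl_row_to_alignment(fields, gene_by_target)
                except (ValueError, IndexError) as exc:
                    if "unknown alignment target" in str(exc):
                        raise
                    skipped += 1
                    continue
                if aln.identity >= min_identity and aln.coverage >= min_coverage:
                    accepted.append(aln)
                else:
                    skipped += 1
    elif fmt == "GFF3":
        groups: dict[str, dict] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) != 9:
                    skipped += 1
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                if f[2] in ("match", "cDNA_match", "EST_match"):
                    gid = attrs.get("ID", "")
                    rec = groups.setdefault(gid, {"parts": [], "meta": None})
                    rec["meta"] = (f, attrs)
                elif f[2] == "match_part":
                    pid = attrs.get("Parent", attrs.get("ID", ""))
                    groups.setdefault(pid, {"parts": [], "meta": None})["parts"].append(
                        (f, attrs)
                    )
        for gid, rec in groups.items():
            # a match without match_part children is its own single block
            parts = rec["parts"] or ([rec["meta"]] if rec["meta"] else [])
            if not parts:
                skipped += 1
                continue
            blocks = []
            qname = qsize = None
            for f, attrs in sorted(parts, key=lambda p: int(p[0][3])):
                tname = f[0]
                ts, te = int(f[3]) - 1, int(f[4])
                tgt = attrs.get("Target", "").split()
                if len(tgt) >= 3:
                    qname = tgt[0]
                    qs, qe = int(tgt[1]) - 1, int(tgt[2])
                else:
                    qs, qe = 0, te - ts
                blocks.append((qs, qe, ts, te))
            meta_f, meta_attrs = rec["meta"] if rec["meta"] else parts[0]
            qsize = int(meta_attrs.get("qsize", max(qe for _, qe, _, _ in blocks)))
            identity = float(meta_attrs.get("identity", 1.0))
            aligned = sum(qe - qs for qs, qe, _, _ in blocks)
            coverage = aligned / qsize if qsize else 0.0
            gene_id, chrom = gene_by_target(meta_f[0])
            qname = qname or gid
            aln = SplicedAlignment(
                est_id=qname,
                library=qname.split("|", 1)[0] if "|" in qname else "",
                gene_id=gene_id,
                chrom=chrom,
                strand=meta_f[6] if meta_f[6] in "+-" else "+",
                blocks=sorted(blocks, key=lambda b: b[2]),
                identity=identity,
                coverage=coverage,
                query_length=qsize,
            )
            if aln.identity >= min_identity and aln.coverage >= min_coverage:
                accepted.append(aln)
            else:
                skipped += 1
    else:
        raise ValueError(f"unknown alignment format {fmt!r} (expected PSL or GFF3)")
    if skipped:
        log.info("read_alignments: skipped/rejected %d rows", skipped)
    return accepted, skipped
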