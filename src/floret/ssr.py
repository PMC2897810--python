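"""Microsatellite (SSR) mining with MISA-style rules.

Perfect tandem repeats of primitive 2-6 nt motifs are reported when the
repeat count reaches the class threshold (6 for dinucleotides, 5 for
tri- through hexanucleotides); mononucleotide repeats are excluded
because homopolymer miscalls dominate pyrosequencing error.  SSRs on
one sequence separated by at most ``max_gap`` nt chain into compound
microsatellites.  Motifs are reported both as found and as a canonical
class (lexicographic minimum over cyclic rotations of the motif and of
its reverse complement, e.g. CTT -> AAG).  N breaks repeats and does
not count as flanking sequence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .mapping import revcomp

DEFAULT_THRESHOLDS = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class SSRRecord:
    seq_id: str
    motif: str
    canonical: str
    unit: int
    repeats: int
    start: int  # 0-based half-open; end - start == unit * repeats
    end: int
    compound_id: str | None = None
    flanking_ok: bool | None = None


def _primitive(motif: str) -> bool:
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest cyclic rotation of the motif or its revcomp."""
    rc = revcomp(motif)
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return min(rotations)


def find_ssrs(
    seq_id: str,
    sequence: str,
    thresholds: dict[int, int] | None = None,
) -> list[SSRRecord]:
    """All maximal perfect tandem repeats of primitive 2-6 nt motifs.

    A reported tract is a maximal run of period-u self-matches truncated
    to whole motif units; maximality under single-base extension implies
    it cannot be extended by a full unit either.  N never matches.
    """
    thr = thresholds or DEFAULT_THRESHOLDS
    s = sequence.upper()
    n = len(s)
    out: list[SSRRecord] = []
    for u in sorted(thr):
        i = 0
        while i + u < n:
            if s[i] != s[i + u] or s[i] == "N":
                i += 1
                continue
            j = i
            while j + u < n and s[j + u] == s[j] and s[j] != "N":
                j += 1
            # period-u self-matching run covers [i, j + u)
            tract = j + u - i
            k = tract // u
            motif = s[i : i + u]
            if k >= thr[u] and "N" not in motif and _primitive(motif):
                out.append(
                    SSRRecord(
                        seq_id=seq_id,
                        motif=motif,
                        canonical=canonical_motif(motif),
                        unit=u,
                        repeats=k,
                        start=i,
                        end=i + u * k,
                    )
                )
            i = j + 1
    out.sort(key=lambda r: (r.start, r.unit))
    return out


def merge_compound(records: Sequence[SSRRecord], max_gap: int = 100) -> list[SSRRecord]:
    """Group SSRs on one sequence whose gaps are <= ``max_gap`` nt (transitive)."""
    by_seq: dict[str, list[SSRRecord]] = {}
    for r in records:
        by_seq.setdefault(r.seq_id, []).append(r)
    out: list[SSRRecord] = []
    for sid in sorted(by_seq):
        group = sorted(by_seq[sid], key=lambda r: (r.start, r.end))
        chains: list[list[SSRRecord]] = []
        for r in group:
            if chains and r.start - max(x.end for x in chains[-1]) <= max_gap:
                chains[-1].append(r)
            else:
                chains.append([r])
        cnum = 0
        for chain in chains:
            if len(chain) == 1:
                out.append(replace(chain[0], compound_id=None))
            else:
                cid = f"{sid}.c{cnum}"
                cnum += 1
                out.extend(replace(r, compound_id=cid) for r in chain)
    return out


def flanking_ok(record: SSRRecord, sequence: str, min_flank: int = 50) -> bool:
    """True iff >= ``min_flank`` non-N nt flank the SSR on both sides."""
    left = sequence[max(0, record.start - min_flank) : record.start]
    right = sequence[record.end : record.end + min_flank]
    return (
        len(left) >= min_flank
        and len(right) >= min_flank
        and "N" not in left.upper()
        and "N" not in right.upper()
    )


def mine(
    sequences: Iterable[tuple[str, str]],
    thresholds: dict[int, int] | None = None,
    max_gap: int = 100,
    min_flank: int = 50,
) -> list[SSRRecord]:
    """find_ssrs + compound merging + flank check over a sequence set."""
    seqs = dict(sequences)
    records: list[SSRRecord] = []
    for sid in seqs:
        records.extend(find_ssrs(sid, seqs[sid], thresholds))
    records = merge_compound(records, max_gap=max_gap)
    return [
        replace(r, flanking_ok=flanking_ok(r, seqs[r.seq_id], min_flank)) for r in records
    ]


def write_misa_table(records: Sequence[SSRRecord], path: str | os.PathLike) -> None:
    """MISA-style TSV, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("ID\tSSR nr.\tSSR type\tSSR\tsize\tstart\tend\n")
        counters: dict[str, int] = {}
        for r in records:
            counters[r.seq_id] = counters.get(r.seq_id, 0) + 1
            ssr_type = f"p{r.unit}" if r.compound_id is None else "c"
            fh.write(
                f"{r.seq_id}\t{counters[r.seq_id]}\t{ssr_type}\t"
                f"({r.motif}){r.repeats}\t{r.end - r.start}\t{r.start + 1}\t{r.end}\n"
            )
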