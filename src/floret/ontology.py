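"""GO-slim classification and hypergeometric term enrichment.

The ontology is a DAG of terms connected by is_a and part_of edges
(child -> parent).  Slim mapping finds, for each annotated term, its
*minimal* slim ancestors: slim terms reachable upward with no other
slim term strictly between.  Enrichment propagates annotations to all
ancestors and tests each term's study count against the hypergeometric
upper tail P(X >= k) with X ~ Hypergeom(N, K, n), adjusting p-values
by Benjamini-Hochberg (default) or Bonferroni.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

RELATIONS = ("is_a", "part_of")


class Ontology:
    """A term DAG with is_a/part_of edges pointing child -> parent."""

    def __init__(self, graph: nx.DiGraph, names: Mapping[str, str] | None = None):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph must be acyclic")
        self.graph = graph
        self.names = dict(names or {})

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], names: Mapping[str, str] | None = None
    ) -> "Ontology":
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        return cls(g, names)

    @classmethod
    def from_obo(cls, path: str | os.PathLike) -> "Ontology":
        """Read an OBO file via obonet, keeping is_a and part_of edges.

        Obsolete terms are dropped (obonet excludes them by default; any
        that slip through with an ``is_obsolete`` flag are removed and
        counted in the log).
        """
        import obonet

        multigraph = obonet.read_obo(str(path))
        g = nx.DiGraph()
        names: dict[str, str] = {}
        dropped = 0
        for node, data in multigraph.nodes(data=True):
            if data.get("is_obsolete") in ("true", True):
                dropped += 1
                continue
            g.add_node(node)
            names[node] = data.get("name", node)
        for child, parent, rel in multigraph.edges(keys=True):
            if rel in RELATIONS and child in g and parent in g:
                g.add_edge(child, parent)
        if dropped:
            log.info("dropped %d obsolete terms", dropped)
        return cls(g, names)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from ``term`` (excluding itself)."""
        return nx.descendants(self.graph, term)  # edges point child -> parent


def map_to_slim(term: str, ontology: Ontology, slim: set[str]) -> set[str]:
    """Minimal slim ancestors-or-self of ``term``.

    A slim term is returned iff some upward path from ``term`` reaches it
    without passing through another slim term; a term already in the slim
    maps to itself.
    """
    if term not in ontology:
        raise KeyError(f"unknown term {term!r}")
    slim_frozen = frozenset(slim)

    @lru_cache(maxsize=None)
    def nearest(t: str) -> frozenset[str]:
        if t in slim_frozen:
            return frozenset({t})
        out: set[str] = set()
        for parent in ontology.graph.successors(t):
            out |= nearest(parent)
        return frozenset(out)

    return set(nearest(term))


def classify_by_slim(
    annotations: Mapping[str, Iterable[str]],
    ontology: Ontology,
    slim: set[str],
) -> pd.Series:
    """Per-slim-term gene counts; a gene counts once per slim term."""
    counts: dict[str, set[str]] = {t: set() for t in slim}
    for gene, terms in annotations.items():
        mapped: set[str] = set()
        for t in terms:
            if t in ontology:
                mapped |= map_to_slim(t, ontology, slim)
        for s in mapped:
            counts.setdefault(s, set()).add(gene)
    return pd.Series({t: len(g) for t, g in sorted(counts.items())}, name="n_genes")


def propagate_annotations(
    annotations: Mapping[str, Iterable[str]], ontology: Ontology
) -> dict[str, set[str]]:
    """Annotate each gene with every ancestor of its direct terms."""
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        full: set[str] = set()
        for t in terms:
            if t not in ontology:
                continue
            full.add(t)
            full |= ontology.ancestors(t)
        out[gene] = full
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    study_count: int
    study_size: int
    population_count: int
    population_size: int
    p: float
    p_adjusted: float
    enriched: bool


def enrich(
    study: Iterable[str],
    population: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    ontology: Ontology,
    adjust: str = "BH",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of propagated terms in the study set.

    ``study`` must be a subset of ``population``; p = P(X >= k) with
    X ~ Hypergeom(N=len(population), K=term's population count,
    n=len(study)).  ``enriched`` requires adjusted p < alpha.
    """
    study = set(study)
    population = set(population)
    missing = study - population
    if missing:
        raise ValueError(f"study genes absent from population: {sorted(missing)[:5]}")
    ann = propagate_annotations(
        {g: ts for g, ts in annotations.items() if g in population}, ontology
    )
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene, terms in ann.items():
        for t in terms:
            term_pop[t] = term_pop.get(t, 0) + 1
            if gene in study:
                term_study[t] = term_study.get(t, 0) + 1
    N, n = len(population), len(study)
    rows = []
    terms = sorted(t for t in term_pop if term_study.get(t, 0) > 0)
    for t in terms:
        K, k = term_pop[t], term_study.get(t, 0)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((t, ontology.names.get(t, t), k, n, K, N, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(
            columns=[
                "term", "name", "study_count", "study_size", "population_count",
                "population_size", "p", "p_adjusted", "enriched",
            ]
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "name", "study_count", "study_size", "population_count",
                 "population_size", "p"],
    )
    if adjust == "BH":
        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
    elif adjust == "bonferroni":
        df["p_adjusted"] = (df["p"] * len(df)).clip(upper=1.0)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    df["enriched"] = df["p_adjusted"] < alpha
    return df.sort_values(["p_adjusted", "p", "term"]).reset_index(drop=True)


def read_gene2go(path: str | os.PathLike) -> dict[str, set[str]]:
    """Two-column gene<TAB>term TSV (or GAF 2.x) -> gene annotations."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 5 and fields[4].startswith("GO:"):  # GAF
                gene, term = fields[2] or fields[1], fields[4]
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]
            else:
                continue
            ann.setdefault(gene, set()).add(term)
    return ann
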