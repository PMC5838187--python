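"""Term enrichment and kappa-score clustering.

A generic over-representation stage in the style of ClueGO: each annotation
term is tested for enrichment in a query gene panel with the one-sided
(upper-tail) hypergeometric test, filtered by a minimum number of query genes
per term, a minimum percentage of the term's genes recovered, and a p-value
threshold.  Surviving terms are grouped by Cohen's kappa agreement of their
gene-membership vectors: terms whose pairwise kappa reaches the threshold are
linked, and the connected components of that term graph form the clusters.
(ClueGO's own iterative kappa merge is approximated by connected components —
simpler, deterministic, and identical on well-separated blocks.)

Multiple-testing correction is off by default (raw p-values are thresholded,
matching the source protocol); Bonferroni and Benjamini-Hochberg switches are
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from scipy.stats import false_discovery_control, hypergeom

from .graph_model import GenePanel, normalize_symbol

__all__ = [
    "AnnotationTable",
    "EnrichmentParameters",
    "TermRecord",
    "TermClusterSet",
    "read_annotations",
    "hypergeometric_test",
    "enrich",
    "kappa_score",
    "cluster_terms",
]


@dataclass
class AnnotationTable:
    """Gene→term annotations over a fixed gene universe.

    ``terms`` maps term_id → (term name, member gene set); every term has at
    least one member and members are a subset of the universe.
    """

    universe: frozenset[str]
    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {tid!r} has no members")
            if not members <= self.universe:
                raise ValueError(f"term {tid!r} has members outside the universe")


@dataclass(frozen=True)
class EnrichmentParameters:
    """Filter thresholds for term enrichment (ClueGO-style defaults)."""

    p_threshold: float = 0.01
    min_query_genes_per_term: int = 2
    min_percent_genes_per_term: float = 4.0
    kappa_threshold: float = 0.4
    correction: str = "none"  # none | bonferroni | bh

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_query_genes_per_term < 1:
            raise ValueError("min_query_genes_per_term must be >= 1")
        if not 0 < self.min_percent_genes_per_term <= 100:
            raise ValueError("min_percent_genes_per_term must be in (0, 100]")
        if not 0 < self.kappa_threshold < 1:
            raise ValueError("kappa_threshold must be in (0, 1)")
        if self.correction not in ("none", "bonferroni", "bh"):
            raise ValueError("correction must be 'none', 'bonferroni' or 'bh'")


@dataclass
class TermRecord:
    """One enriched term: sizes, overlap, p-value and (later) cluster id."""

    term_id: str
    name: str
    K: int  # term size
    k: int  # overlap with the query
    percent_genes: float  # 100 * k / K
    p_value: float
    genes: tuple[str, ...] = ()
    cluster_id: int | None = None


@dataclass
class TermClusterSet:
    """Partition of enriched terms into kappa-linked clusters."""

    records: list[TermRecord]
    clusters: dict[int, list[str]] = field(default_factory=dict)


def read_annotations(path: str | Path, universe_path: str | Path) -> AnnotationTable:
    """Read long-format annotation TSV (term_id, term_name, gene) plus a
    one-symbol-per-line universe file."""
    universe = set()
    with Path(universe_path).open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                universe.add(normalize_symbol(line))
    terms: dict[str, tuple[str, set[str]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            tid, name, gene = fields[0].strip(), fields[1].strip(), normalize_symbol(fields[2])
            if tid in terms:
                terms[tid][1].add(gene)
            else:
                terms[tid] = (name, {gene})
    return AnnotationTable(
        universe=frozenset(universe),
        terms={tid: (name, frozenset(members)) for tid, (name, members) in terms.items()},
    )


def hypergeometric_test(universe_size: int, term_size: int, query_size: int, overlap: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts term members in a query of ``query_size`` genes drawn without
    replacement from a universe of ``universe_size`` genes of which
    ``term_size`` belong to the term.
    """
    N, K, n, k = universe_size, term_size, query_size, overlap
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent counts: universe={N}, term={K}, query={n}, overlap={k}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: GenePanel,
    ann: AnnotationTable,
    params: EnrichmentParameters = EnrichmentParameters(),
) -> list[TermRecord]:
    """Test every annotation term for over-representation in the query panel.

    A term is reported only if it passes all three filters: overlap
    ``k >= min_query_genes_per_term``, recovered fraction
    ``100*k/K >= min_percent_genes_per_term``, and (corrected) p-value
    ``<= p_threshold``.  Records are sorted by p ascending, term_id ascending.
    """
    query_in = query.as_set() & ann.universe
    if not query_in:
        raise ValueError(f"query panel {query.label!r} is disjoint from the universe")
    N, n = len(ann.universe), len(query_in)
    raw: list[TermRecord] = []
    for tid in sorted(ann.terms):
        name, members = ann.terms[tid]
        overlap = members & query_in
        k, K = len(overlap), len(members)
        raw.append(TermRecord(
            term_id=tid, name=name, K=K, k=k,
            percent_genes=100.0 * k / K,
            p_value=hypergeometric_test(N, K, n, k),
            genes=tuple(sorted(overlap)),
        ))
    if params.correction == "bonferroni":
        m = len(raw)
        for r in raw:
            r.p_value = min(1.0, r.p_value * m)
    elif params.correction == "bh":
        adj = false_discovery_control([r.p_value for r in raw], method="bh")
        for r, p in zip(raw, adj):
            r.p_value = float(p)
    kept = [
        r for r in raw
        if r.k >= params.min_query_genes_per_term
        and r.percent_genes >= params.min_percent_genes_per_term
        and r.p_value <= params.p_threshold
    ]
    kept.sort(key=lambda r: (r.p_value, r.term_id))
    return kept


def kappa_score(term_a: frozenset[str] | set[str], term_b: frozenset[str] | set[str],
                universe: frozenset[str] | set[str]) -> float:
    """Cohen's kappa between two terms' gene-membership indicators.

    Built from the 2x2 contingency table of membership over the universe:
    observed agreement po = (both + neither) / N, chance agreement pe from the
    marginals, kappa = (po - pe) / (1 - pe).  Returns 1.0 at perfect agreement
    (po = 1), where the ratio is 0/0.
    """
    if not term_a or not term_b:
        raise ValueError("both terms must be non-empty")
    if not (set(term_a) | set(term_b)) <= set(universe):
        raise ValueError("universe smaller than the union of term members")
    N = len(universe)
    a = len(set(term_a) & set(term_b))         # in both
    b = len(term_a) - a                        # only in A
    c = len(term_b) - a                        # only in B
    d = N - a - b - c                          # in neither
    po = (a + d) / N
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    if po == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def cluster_terms(
    records: list[TermRecord],
    ann: AnnotationTable,
    params: EnrichmentParameters = EnrichmentParameters(),
) -> TermClusterSet:
    """Group enriched terms into kappa-linked clusters.

    Terms are nodes of a graph with an edge wherever pairwise kappa (over the
    annotation universe) reaches ``kappa_threshold``; clusters are the
    connected components, so singleton terms form singleton clusters.
    Cluster ids are assigned by descending cluster size, ties by smallest
    term_id, starting at 1.
    """
    if not records:
        raise ValueError("no term records to cluster")
    G = nx.Graph()
    G.add_nodes_from(r.term_id for r in records)
    ids = sorted(r.term_id for r in records)
    for i, ta in enumerate(ids):
        for tb in ids[i + 1:]:
            kap = kappa_score(ann.terms[ta][1], ann.terms[tb][1], ann.universe)
            if kap >= params.kappa_threshold:
                G.add_edge(ta, tb)
    comps = [sorted(c) for c in nx.connected_components(G)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    clusters: dict[int, list[str]] = {}
    assign: dict[str, int] = {}
    for cid, comp in enumerate(comps, start=1):
        clusters[cid] = comp
        for tid in comp:
            assign[tid] = cid
    for r in records:
        r.cluster_id = assign[r.term_id]
    return TermClusterSet(records=records, clusters=clusters)
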