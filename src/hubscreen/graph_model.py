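"""Graph and gene-set data types with file I/O.

Networks are plain :class:`networkx.Graph` objects whose nodes are normalized
(uppercased, stripped) gene symbols.  Edges are undirected and simple; an
optional ``confidence`` edge attribute carries interaction scores in [0, 1]
but is never used by the centrality math.  Gene panels are ordered,
deduplicated symbol lists with a provenance label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger("hubscreen")

__all__ = [
    "GenePanel",
    "normalize_symbol",
    "read_network",
    "write_network",
    "read_gene_set",
    "connected_components",
    "expand_with_neighbors",
]


def normalize_symbol(raw: str) -> str:
    """Uppercase and strip a gene symbol; reject empty or whitespace-bearing tokens."""
    sym = raw.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    if any(c.isspace() for c in sym):
        raise ValueError(f"gene symbol contains whitespace: {raw!r}")
    return sym


@dataclass
class GenePanel:
    """An ordered, deduplicated list of gene symbols with a provenance label."""

    label: str
    genes: list[str] = field(default_factory=list)

    @classmethod
    def from_symbols(cls, label: str, symbols: Iterable[str]) -> "GenePanel":
        """Build a panel, normalizing symbols and collapsing duplicates (logged)."""
        seen: dict[str, None] = {}
        n_dup = 0
        for raw in symbols:
            sym = normalize_symbol(raw)
            if sym in seen:
                n_dup += 1
            else:
                seen[sym] = None
        if n_dup:
            logger.warning("panel %r: collapsed %d duplicate symbol(s)", label, n_dup)
        return cls(label=label, genes=list(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, symbol: object) -> bool:
        return symbol in set(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def _parse_confidence(token: str) -> float | None:
    """Parse a third-column score; values > 1 are treated as STRING-style
    0-1000 scores and divided by 1000."""
    try:
        val = float(token)
    except ValueError:
        return None
    if val > 1.0:
        val /= 1000.0
    return val


def read_network(path: str | Path, format: str = "edge_tsv", label: str | None = None) -> nx.Graph:
    """Read an undirected PPI network from an edge-list TSV or a Cytoscape SIF file.

    Parameters
    ----------
    path
        File to read.
    format
        ``"edge_tsv"`` — two or three tab-separated columns ``node_a  node_b
        [score]``, '#' comments allowed, a header row auto-detected when the
        third column of the first row is non-numeric.  ``"sif"`` — Cytoscape
        simple-interaction format ``A <relation> B [C ...]``; relation tokens
        are ignored and multi-target rows expand to pairwise edges.
    label
        Network label stored in ``G.graph["label"]``; defaults to the file stem.

    Returns
    -------
    networkx.Graph
        Simple undirected graph over normalized symbols.  Self-loops are
        dropped (count logged); numeric third columns become a ``confidence``
        edge attribute in [0, 1] (STRING-style 0-1000 scores are rescaled).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("edge_tsv", "sif"):
        raise ValueError(f"unknown network format: {format!r}")

    G = nx.Graph()
    G.graph["label"] = label if label is not None else path.stem
    n_self_loops = 0
    n_rows = 0

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if format == "edge_tsv":
                fields = line.split("\t")
                if len(fields) not in (2, 3):
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 or 3 tab-separated columns, "
                        f"got {len(fields)}"
                    )
                # header detection: first data row with a non-numeric 3rd column
                if n_rows == 0 and len(fields) == 3 and _parse_confidence(fields[2]) is None:
                    n_rows += 1
                    continue
                n_rows += 1
                try:
                    a, b = normalize_symbol(fields[0]), normalize_symbol(fields[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                if a == b:
                    n_self_loops += 1
                    G.add_node(a)
                    continue
                conf = _parse_confidence(fields[2]) if len(fields) == 3 else None
                if conf is not None:
                    G.add_edge(a, b, confidence=conf)
                else:
                    G.add_edge(a, b)
            else:  # sif
                tokens = line.split("\t") if "\t" in line else line.split()
                tokens = [t for t in tokens if t.strip()]
                n_rows += 1
                if len(tokens) == 1:
                    G.add_node(normalize_symbol(tokens[0]))
                    continue
                if len(tokens) == 2:
                    raise ValueError(
                        f"{path}:{lineno}: SIF row needs 1 or >=3 fields "
                        "(source, relation, targets...)"
                    )
                try:
                    src = normalize_symbol(tokens[0])
                    targets = [normalize_symbol(t) for t in tokens[2:]]
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                for tgt in targets:
                    if src == tgt:
                        n_self_loops += 1
                        G.add_node(src)
                    else:
                        G.add_edge(src, tgt)

    if n_rows == 0:
        raise ValueError(f"{path}: no interaction rows found")
    if n_self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_self_loops)
    return G


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Write a network as edge-list TSV (``node_a  node_b  [confidence]``).

    Isolated nodes are emitted as ``A<TAB>A`` rows, which :func:`read_network`
    interprets as a node without edges, so a write→read round-trip preserves
    the node set, edge set and confidences exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# edge list: node_a\tnode_b[\tconfidence]\n")
        for a, b, data in sorted(net.edges(data=True)):
            conf = data.get("confidence")
            if conf is not None:
                fh.write(f"{a}\t{b}\t{conf:g}\n")
            else:
                fh.write(f"{a}\t{b}\n")
        for v in sorted(net.nodes):
            if net.degree(v) == 0:
                fh.write(f"{v}\t{v}\n")


def read_gene_set(path: str | Path, label: str | None = None) -> GenePanel:
    """Read a one-symbol-per-line gene set ('#' lines are comments).

    The panel label defaults to the file stem.  Duplicate symbols after
    normalization are collapsed with a logged warning; an empty set after
    filtering is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    symbols = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.append(line)
    if not symbols:
        raise ValueError(f"{path}: no gene symbols found")
    return GenePanel.from_symbols(label if label is not None else path.stem, symbols)


def connected_components(net: nx.Graph) -> list[nx.Graph]:
    """Split a network into its connected components.

    Components are returned as induced subgraph copies, sorted by size
    descending with ties broken by smallest member symbol, and labeled
    ``<parent>/component-<i>`` so that "component-1" is always the largest.
    """
    comps = [set(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    out = []
    parent = net.graph.get("label", "network")
    for i, nodes in enumerate(comps, start=1):
        sub = net.subgraph(nodes).copy()
        sub.graph["label"] = f"{parent}/component-{i}"
        out.append(sub)
    return out


def expand_with_neighbors(net: nx.Graph, seeds: GenePanel, depth: int = 1) -> nx.Graph:
    """Induced subgraph on the seed genes plus their network neighbors.

    This builds the "seed genes + related genes" network: starting from the
    seeds found in ``net``, the node set is expanded ``depth`` times by direct
    neighbors and the subgraph induced on the result is returned.  Seeds absent
    from the network are logged, not fatal; no seed present at all is an error.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    present = [s for s in seeds if net.has_node(s)]
    missing = [s for s in seeds if not net.has_node(s)]
    if missing:
        logger.warning(
            "panel %r: %d seed(s) absent from network (e.g. %s)",
            seeds.label, len(missing), ", ".join(missing[:5]),
        )
    if not present:
        raise ValueError(f"no seed from panel {seeds.label!r} found in network")
    nodes = set(present)
    frontier = set(present)
    for _ in range(depth):
        frontier = {nbr for v in frontier for nbr in net[v]} - nodes
        nodes |= frontier
    sub = net.subgraph(nodes).copy()
    sub.graph["label"] = f"{net.graph.get('label', 'network')}+neighbors"
    return sub
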