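"""Seeded generators for networks, gene-set pairs and annotation tables.

Every stage of the screening pipeline can be exercised without downloads:
the generators emulate the statistical structure the analysis assumes —
scale-free (preferential-attachment) degree distributions, a network split
into two connected components of very different sizes, two disease gene sets
with a fixed overlap, planted high-degree hubs with known identity, and
annotation tables with planted enriched terms.

Two parameter presets are named in :data:`PRESETS`:

* ``study_scale`` — the sizes reported for the original UC/COAC study
  (disease sets of 843 and 376 genes overlapping in 65; components of 3581
  and 809 nodes);
* ``desk_scale`` — scaled-down defaults for interactive work and testing
  (components of 300 and 60 nodes).

All generators are driven by a single seeded pseudorandom stream per call and
are bit-reproducible for a fixed seed.  Generated symbols are synthetic
tokens (``G000001`` ...) so they can never be confused with the packaged
reference gene panels.
"""

from __future__ import annotations

import random

import networkx as nx

from .enrichment import AnnotationTable
from .graph_model import GenePanel

__all__ = [
    "PRESETS",
    "gen_preferential_attachment",
    "gen_planted_hubs",
    "gen_two_component",
    "gen_disease_pair",
    "gen_annotations",
]

#: named parameter presets (see module docstring)
PRESETS = {
    "study_scale": {
        "two_component_sizes": [3581, 809],
        "disease_pair": {"n_a": 843, "n_b": 376, "n_common": 65},
    },
    "desk_scale": {
        "two_component_sizes": [300, 60],
        "disease_pair": {"n_a": 843, "n_b": 376, "n_common": 65},
    },
}


def _symbol(i: int, prefix: str = "G") -> str:
    return f"{prefix}{i:06d}"


def _relabel(G: nx.Graph, prefix: str, offset: int = 0) -> nx.Graph:
    mapping = {v: _symbol(v + 1 + offset, prefix) for v in G.nodes}
    return nx.relabel_nodes(G, mapping)


def gen_preferential_attachment(n: int, m: int, seed: int, prefix: str = "G") -> nx.Graph:
    """Barabási–Albert scale-free network grown from an m-clique.

    Each of the ``n - m`` arriving nodes attaches to ``m`` existing nodes with
    probability proportional to their degree, so the result is a simple
    undirected graph with exactly ``(n - m) * m + C(m, 2)`` edges and a
    heavy-tailed degree distribution.
    """
    if not 1 <= m < n:
        raise ValueError(f"need 1 <= m < n, got m={m}, n={n}")
    G = nx.barabasi_albert_graph(
        n, m, seed=random.Random(seed), initial_graph=nx.complete_graph(m)
    )
    G = _relabel(G, prefix)
    G.graph["label"] = f"pa(n={n},m={m},seed={seed})"
    return G


def gen_planted_hubs(
    n: int, m: int, n_hubs: int, hub_extra_degree: int, seed: int, prefix: str = "G"
) -> tuple[nx.Graph, GenePanel]:
    """Scale-free background plus designated hubs wired far above it.

    ``n_hubs`` nodes are chosen at random and each is connected to
    ``hub_extra_degree`` additional random partners, pushing its degree well
    past the background mean + 2 SD cutoff.  Returns the network and the
    ground-truth panel of planted hub symbols.
    """
    if hub_extra_degree >= n:
        raise ValueError("hub_extra_degree must be smaller than n")
    if n_hubs > n:
        raise ValueError("cannot plant more hubs than nodes")
    rng = random.Random(seed)
    G = nx.barabasi_albert_graph(n, m, seed=rng, initial_graph=nx.complete_graph(m))
    nodes = list(G.nodes)
    planted = sorted(rng.sample(nodes, n_hubs))
    for hub in planted:
        candidates = [v for v in nodes if v != hub and not G.has_edge(hub, v)]
        extra = min(hub_extra_degree, len(candidates))
        for v in rng.sample(candidates, extra):
            G.add_edge(hub, v)
    G = _relabel(G, prefix)
    G.graph["label"] = f"planted-hubs(n={n},m={m},hubs={n_hubs},seed={seed})"
    panel = GenePanel(
        label="planted-hubs", genes=[_symbol(v + 1, prefix) for v in planted]
    )
    return G, panel


def gen_two_component(sizes: list[int], m: int, seed: int, prefix: str = "G") -> nx.Graph:
    """Disjoint union of independent scale-free graphs, one per requested size.

    Emulates a network organized in connected components of very different
    sizes; component sizes are exact by construction and no edge spans
    components.
    """
    for s in sizes:
        if s < m + 1:
            raise ValueError(f"component size {s} must be >= m + 1 = {m + 1}")
    rng = random.Random(seed)
    G = nx.Graph()
    offset = 0
    for s in sizes:
        comp = nx.barabasi_albert_graph(s, m, seed=rng, initial_graph=nx.complete_graph(m))
        G.update(_relabel(comp, prefix, offset=offset))
        offset += s
    G.graph["label"] = f"two-component(sizes={sizes},m={m},seed={seed})"
    return G


def gen_disease_pair(
    n_a: int = 843,
    n_b: int = 376,
    n_common: int = 65,
    symbol_prefix: str = "G",
    seed: int = 0,
) -> tuple[GenePanel, GenePanel]:
    """Two gene panels with an exact shared overlap.

    Defaults mirror the sizes of the original UC/COAC disease gene sets:
    843 and 376 genes sharing exactly 65.  The overlap is exact, not in
    expectation.
    """
    if n_common > min(n_a, n_b):
        raise ValueError(
            f"overlap {n_common} infeasible for panel sizes {n_a} and {n_b}"
        )
    rng = random.Random(seed)
    total = n_a + n_b - n_common
    symbols = [_symbol(i + 1, symbol_prefix) for i in range(total)]
    rng.shuffle(symbols)
    common = symbols[:n_common]
    a_only = symbols[n_common:n_common + (n_a - n_common)]
    b_only = symbols[n_common + (n_a - n_common):]
    panel_a = GenePanel(label="disease-A", genes=sorted(common + a_only))
    panel_b = GenePanel(label="disease-B", genes=sorted(common + b_only))
    return panel_a, panel_b


def gen_annotations(
    universe_size: int,
    n_terms: int,
    planted: list[tuple[int, int]],
    seed: int,
    query_size: int = 20,
    background_term_size: tuple[int, int] = (5, 30),
    prefix: str = "G",
) -> tuple[AnnotationTable, GenePanel]:
    """Annotation table with planted enriched terms and a matching query panel.

    ``planted`` lists ``(term_size, overlap)`` pairs: each planted term gets
    exactly ``overlap`` members drawn from the query panel and the remainder
    from outside it.  The remaining ``n_terms - len(planted)`` background
    terms draw members uniformly from the whole universe, with sizes uniform
    in ``background_term_size``.
    """
    if query_size > universe_size:
        raise ValueError("query_size must not exceed universe_size")
    for K, k in planted:
        if K > universe_size or k > K or k > query_size:
            raise ValueError(f"infeasible planted term (size={K}, overlap={k})")
    if len(planted) > n_terms:
        raise ValueError("more planted terms than n_terms")
    rng = random.Random(seed)
    universe = [_symbol(i + 1, prefix) for i in range(universe_size)]
    query = rng.sample(universe, query_size)
    outside = [g for g in universe if g not in set(query)]
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i, (K, k) in enumerate(planted, start=1):
        members = rng.sample(query, k) + rng.sample(outside, K - k)
        tid = f"PLANT{i:04d}"
        terms[tid] = (f"planted term {i}", frozenset(members))
    for i in range(len(planted) + 1, n_terms + 1):
        size = rng.randint(*background_term_size)
        tid = f"BG{i:04d}"
        terms[tid] = (f"background term {i}", frozenset(rng.sample(universe, size)))
    ann = AnnotationTable(universe=frozenset(universe), terms=terms)
    return ann, GenePanel(label=f"query(seed={seed})", genes=sorted(query))
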