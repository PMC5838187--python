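"""Hub / bottleneck / hub-bottleneck selection and component-aware screening.

The screening rules are the classic distribution-based criteria used for PPI
network analysis:

* **hubs** — genes whose degree strictly exceeds mean + ``hub_sd_multiplier``
  x SD of the network's degree distribution (default multiplier 2, population
  SD);
* **bottlenecks** — the top ``bottleneck_fraction`` of genes by betweenness
  (default 5%, count rounded up, ties broken lexicographically);
* **hub-bottlenecks** — the intersection, i.e. the network's central genes.

Because degree statistics are component-size dependent (pooling a large and a
small component lowers the mean and SD, so small-component nodes can swamp the
cutoff while large-component top nodes vanish), the component-aware screen
applies the rules separately inside every sufficiently large connected
component and merges the per-component hub-bottleneck panels by union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .centrality import centrality_table
from .graph_model import GenePanel, connected_components

__all__ = [
    "ScreenParameters",
    "ScreenResult",
    "select_hubs",
    "select_bottlenecks",
    "screen_network",
    "component_aware_screen",
    "merge_component_screens",
]


@dataclass(frozen=True)
class ScreenParameters:
    """Tunable thresholds of the screening rules.

    hub_sd_multiplier
        Number of degree-distribution SDs above the mean a hub must exceed.
    bottleneck_fraction
        Fraction of top-betweenness genes selected as bottlenecks, in (0, 1).
    sd_kind
        ``"population"`` (ddof=0, default) or ``"sample"`` (ddof=1).
    min_component_size
        Smallest connected component screened on its own in the
        component-aware procedure.
    """

    hub_sd_multiplier: float = 2.0
    bottleneck_fraction: float = 0.05
    sd_kind: str = "population"
    min_component_size: int = 20

    def __post_init__(self) -> None:
        if self.hub_sd_multiplier < 0:
            raise ValueError("hub_sd_multiplier must be >= 0")
        if not 0 < self.bottleneck_fraction < 1:
            raise ValueError("bottleneck_fraction must be in (0, 1)")
        if self.sd_kind not in ("population", "sample"):
            raise ValueError("sd_kind must be 'population' or 'sample'")
        if self.min_component_size < 3:
            raise ValueError("min_component_size must be >= 3")

    @property
    def ddof(self) -> int:
        return 0 if self.sd_kind == "population" else 1


@dataclass
class ScreenResult:
    """Screening output for one network, with the thresholds that produced it."""

    label: str
    hubs: GenePanel
    bottlenecks: GenePanel
    hub_bottlenecks: GenePanel
    degree_mean: float
    degree_sd: float
    degree_cutoff: float
    bottleneck_rank_cutoff: int
    centrality: pd.DataFrame = field(repr=False, default=None)


def select_hubs(ct: pd.DataFrame, params: ScreenParameters = ScreenParameters()) -> GenePanel:
    """Genes with degree strictly greater than mean + multiplier x SD.

    Strict inequality means a zero-spread degree distribution (e.g. a cycle)
    yields no hubs.  The panel is ordered by degree descending, symbol
    ascending.
    """
    if ct.empty:
        raise ValueError("empty centrality table")
    degrees = ct["degree"].to_numpy(dtype=float)
    cutoff = degrees.mean() + params.hub_sd_multiplier * degrees.std(ddof=params.ddof)
    hubs = ct.loc[ct["degree"] > cutoff, "degree"]
    ordered = sorted(hubs.items(), key=lambda kv: (-kv[1], kv[0]))
    return GenePanel(label=f"{ct.attrs.get('label', 'network')}/hubs",
                     genes=[g for g, _ in ordered])


def select_bottlenecks(ct: pd.DataFrame, params: ScreenParameters = ScreenParameters()) -> GenePanel:
    """Top ``ceil(fraction x n)`` genes by betweenness.

    Sorting is (betweenness descending, symbol ascending) so ties resolve
    deterministically.
    """
    if ct.empty:
        raise ValueError("empty centrality table")
    k = math.ceil(params.bottleneck_fraction * len(ct))
    ranked = sorted(ct["betweenness"].items(), key=lambda kv: (-kv[1], kv[0]))
    return GenePanel(label=f"{ct.attrs.get('label', 'network')}/bottlenecks",
                     genes=[g for g, _ in ranked[:k]])


def screen_network(net: nx.Graph, params: ScreenParameters = ScreenParameters()) -> ScreenResult:
    """Run the full hub / bottleneck / hub-bottleneck screen on one network."""
    if net.number_of_nodes() < 3:
        raise ValueError(f"network too small to screen ({net.number_of_nodes()} nodes)")
    ct = centrality_table(net)
    hubs = select_hubs(ct, params)
    bottlenecks = select_bottlenecks(ct, params)
    hub_set = hubs.as_set()
    bn_set = bottlenecks.as_set()
    label = net.graph.get("label", "network")
    hb = GenePanel(label=f"{label}/hub-bottlenecks",
                   genes=[g for g in hubs if g in bn_set])
    degrees = ct["degree"].to_numpy(dtype=float)
    mean = float(degrees.mean())
    sd = float(np.std(degrees, ddof=params.ddof))
    assert hb.as_set() == hub_set & bn_set
    return ScreenResult(
        label=label,
        hubs=hubs,
        bottlenecks=bottlenecks,
        hub_bottlenecks=hb,
        degree_mean=mean,
        degree_sd=sd,
        degree_cutoff=mean + params.hub_sd_multiplier * sd,
        bottleneck_rank_cutoff=len(bottlenecks),
        centrality=ct,
    )


def merge_component_screens(per_component: list[GenePanel]) -> GenePanel:
    """Deduplicated union of per-component panels, ordered by first appearance.

    This is the rule that reconciles per-component hub-bottleneck lists into a
    single final panel: a gene is central if it is central in any component it
    belongs to.  The operation is associative and, as a set, order-insensitive.
    """
    if not per_component:
        raise ValueError("no panels to merge")
    seen: dict[str, None] = {}
    for panel in per_component:
        for g in panel:
            seen.setdefault(g, None)
    label = "merged(" + "+".join(p.label for p in per_component) + ")"
    return GenePanel(label=label, genes=list(seen))


def component_aware_screen(
    net: nx.Graph, params: ScreenParameters = ScreenParameters()
) -> tuple[list[ScreenResult], GenePanel]:
    """Screen each large connected component separately, plus the whole network.

    Every component with at least ``params.min_component_size`` nodes is
    screened on its own (smaller ones are skipped, logged); the pooled network
    is screened as well for audit.  Returns all :class:`ScreenResult` objects
    — per-component results first, pooled result last — together with the
    merged hub-bottleneck panel, the union of the per-component panels.
    """
    import logging

    comps = connected_components(net)
    big = [c for c in comps if c.number_of_nodes() >= params.min_component_size]
    if not big:
        raise ValueError(
            f"no connected component reaches min_component_size="
            f"{params.min_component_size}"
        )
    skipped = len(comps) - len(big)
    if skipped:
        logging.getLogger("hubscreen").info(
            "component-aware screen: skipped %d component(s) below %d nodes",
            skipped, params.min_component_size,
        )
    results = [screen_network(c, params) for c in big]
    merged = merge_component_screens([r.hub_bottlenecks for r in results])
    results.append(screen_network(net, params))
    return results, merged
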