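"""Cross-disease panel algebra and the packaged reference gene tables.

The package ships the curated hub-bottleneck gene panels published by the
original ulcerative-colitis / colon-adenocarcinoma network screening study
(its Tables 1-5), so the cross-disease comparisons can be reproduced exactly:

==========  ============================================================  =====
table id    contents                                                      genes
==========  ============================================================  =====
T1          combined common-genes network screen (29 rows, 1 duplicate)     28
T2_comp1    larger main connected component of that network                 18
T2_comp2    smaller main connected component                                 4
T3          colon-adenocarcinoma (COAC) network                             11
T4          ulcerative-colitis (UC) network                                 25
T5          final merged common-genes panel (union of the T2 columns)       20
==========  ============================================================  =====

The study's "Table 6" (the cross-disease common hub-bottlenecks) was
referenced but never printed; it is reconstructed here as
``intersect_panels(T3, T4)`` and labeled ``reconstructed-T6``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .graph_model import GenePanel

__all__ = [
    "PanelComparison",
    "load_reference_table",
    "reconstructed_t6",
    "intersect_panels",
    "consensus_key_genes",
    "count_gene_family",
    "INTERLEUKIN_PATTERN",
]

#: default anchored pattern for the interleukin gene family (IL6, IL1B, ...)
INTERLEUKIN_PATTERN = r"^IL[0-9]+[A-Z]?$"

_TABLE_FILES = {
    "T1": ("table1.tsv", "Table 1 / common network"),
    "T2_comp1": ("table2_comp1.tsv", "Table 2 / component-1"),
    "T2_comp2": ("table2_comp2.tsv", "Table 2 / component-2"),
    "T3": ("table3.tsv", "Table 3 / COAC"),
    "T4": ("table4.tsv", "Table 4 / UC"),
    "T5": ("table5.tsv", "Table 5 / merged common network"),
}


@dataclass
class PanelComparison:
    """Set algebra of two panels: shared genes and each side's private genes."""

    label_a: str
    label_b: str
    common: GenePanel
    only_a: GenePanel
    only_b: GenePanel


def load_reference_table(table_id: str) -> GenePanel:
    """Load one of the packaged reference hub-bottleneck panels.

    ``table_id`` is one of T1, T2_comp1, T2_comp2, T3, T4, T5.  Duplicate rows
    in the source (T1 lists CDKN2A twice) are collapsed with a logged warning.
    """
    try:
        fname, label = _TABLE_FILES[table_id]
    except KeyError:
        raise ValueError(
            f"unknown table id {table_id!r}; valid ids: {sorted(_TABLE_FILES)}"
        ) from None
    text = resources.files("hubscreen.data").joinpath(fname).read_text()
    symbols = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        symbols.append(fields[1])
    return GenePanel.from_symbols(label, symbols)


def intersect_panels(a: GenePanel, b: GenePanel) -> PanelComparison:
    """Exact set algebra on two normalized panels.

    ``common`` keeps panel a's ordering; ``only_a`` / ``only_b`` keep their own
    panel's ordering.  The three parts partition a ∪ b.
    """
    if not len(a) or not len(b):
        raise ValueError("both panels must be non-empty")
    set_b, set_a = b.as_set(), a.as_set()
    return PanelComparison(
        label_a=a.label,
        label_b=b.label,
        common=GenePanel(f"common({a.label}, {b.label})", [g for g in a if g in set_b]),
        only_a=GenePanel(f"only({a.label})", [g for g in a if g not in set_b]),
        only_b=GenePanel(f"only({b.label})", [g for g in b if g not in set_a]),
    )


def reconstructed_t6() -> PanelComparison:
    """The unprinted 'Table 6': COAC panel (T3) intersected with UC panel (T4)."""
    cmp = intersect_panels(load_reference_table("T3"), load_reference_table("T4"))
    cmp.common.label = "reconstructed-T6"
    return cmp


def consensus_key_genes(method1_common: GenePanel, method2_panel: GenePanel) -> GenePanel:
    """Genes supported by both analytic routes.

    Route 1 screens each disease network separately and intersects the
    hub-bottleneck panels; route 2 screens the joint common-genes network.
    The consensus is the intersection, ordered by route 1's panel.  An empty
    consensus is a valid result, not an error.
    """
    if not len(method1_common) or not len(method2_panel):
        raise ValueError("both panels must be non-empty")
    m2 = method2_panel.as_set()
    return GenePanel(
        label=f"consensus({method1_common.label}, {method2_panel.label})",
        genes=[g for g in method1_common if g in m2],
    )


def count_gene_family(panel: GenePanel, pattern: str = INTERLEUKIN_PATTERN) -> tuple[int, GenePanel]:
    """Count panel symbols matching an anchored regular expression.

    Returns the count and the matching sub-panel (panel order preserved).
    The default pattern captures the interleukin family.
    """
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid pattern {pattern!r}: {exc}") from exc
    members = [g for g in panel if rx.fullmatch(g)]
    sub = GenePanel(label=f"{panel.label}/family({pattern})", genes=members)
    return len(sub), sub
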