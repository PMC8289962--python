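"""Stage 3: gene-panel overlap annotation.

A gene is "affected" by a call when its interval overlaps the call span by
at least 1 bp (strandless, any-overlap).  Interchromosomal translocations
have no span; each breakpoint is treated as a zero-length window, so the
genes containing either breakpoint count.  Panels are pre-collapsed to one
interval per symbol on load, so a gene counts once per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .datamodel import GenePanel, SVCall

__all__ = [
    "CallAnnotation",
    "count_affected_genes",
    "affected_genes",
    "annotate_calls",
    "panel_category_fractions",
]


@dataclass(frozen=True)
class CallAnnotation:
    """Per-call affected-gene counts and symbols, one entry per panel."""

    call_id: str
    counts: dict  # panel name -> int
    symbols: dict  # panel name -> tuple of sorted gene symbols

    def __post_init__(self) -> None:
        for panel, count in self.counts.items():
            if count != len(self.symbols[panel]):
                raise ValueError(f"{self.call_id}: count/symbol mismatch for panel {panel}")


_TREE_CACHE: dict = {}


def _panel_trees(panel: GenePanel) -> dict:
    """chrom -> IntervalTree of (start, end+1) half-open gene intervals."""
    key = id(panel)
    cached = _TREE_CACHE.get(key)
    if cached is not None and cached[0] is panel:
        return cached[1]
    trees: dict = {}
    for chrom, start, end, symbol in panel.genes:
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, symbol)
    _TREE_CACHE[key] = (panel, trees)
    return trees


def affected_genes(call: SVCall, panel: GenePanel) -> tuple:
    """Sorted symbols of panel genes overlapping the call by >= 1 bp."""
    trees = _panel_trees(panel)
    hits: set = set()
    if call.bp_a.chrom == call.bp_b.chrom:
        chrom, lo, hi = call.interval()
        tree = trees.get(chrom)
        if tree is not None:
            hits.update(iv.data for iv in tree.overlap(lo, hi + 1))
    else:  # translocation: point overlap at each breakpoint
        for bp in (call.bp_a, call.bp_b):
            tree = trees.get(bp.chrom)
            if tree is not None:
                hits.update(iv.data for iv in tree.at(bp.pos))
    return tuple(sorted(hits))


def count_affected_genes(call: SVCall, panel: GenePanel) -> int:
    """Number of panel genes whose interval overlaps the call span by >= 1 bp."""
    return len(affected_genes(call, panel))


def annotate_calls(calls: Iterable[SVCall], panels: Iterable[GenePanel]) -> list:
    """One :class:`CallAnnotation` per call, one count per panel, in input order."""
    panels = list(panels)
    if not panels:
        raise ValueError("annotate_calls needs at least one panel")
    annotations = []
    for call in calls:
        symbols = {p.name: affected_genes(call, p) for p in panels}
        annotations.append(
            CallAnnotation(
                call_id=call.call_id,
                counts={name: len(syms) for name, syms in symbols.items()},
                symbols=symbols,
            )
        )
    return annotations


def panel_category_fractions(
    calls: Iterable[SVCall],
    annotations: Iterable[CallAnnotation],
    panels: Iterable[GenePanel],
) -> dict:
    """Per-panel fraction of the affected-gene universe.

    fraction(panel) = |union of affected genes in that panel| / |union of
    affected genes in any panel|.  Panels overlap, so fractions need not sum
    to one.  When no gene is affected the fractions are undefined and an
    empty dict is returned.
    """
    panels = list(panels)
    per_panel: dict = {p.name: set() for p in panels}
    for ann in annotations:
        for name, syms in ann.symbols.items():
            if name in per_panel:
                per_panel[name].update(syms)
    universe = set().union(*per_panel.values()) if per_panel else set()
    if not universe:
        return {}
    return {name: len(genes) / len(universe) for name, genes in per_panel.items()}


def annotations_to_frame(annotations: Iterable[CallAnnotation]):
    """Tidy per-call table of panel counts, joined on call_id."""
    import pandas as pd

    rows = []
    for ann in annotations:
        row = {"call_id": ann.call_id}
        row.update(ann.counts)
        rows.append(row)
    return pd.DataFrame(rows)
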