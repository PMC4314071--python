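"""Neighbour-disruption analysis for deletion targets.

Yeast genomes are compact: deleting one locus frequently removes part of a
neighbouring gene or ncRNA.  Overlap is assessed on closed 1-based intervals
against the feature span only (the homology arms are regenerated by
recombination, so they do not count), and is strand-agnostic because an
antisense feature is physically destroyed by the deletion regardless of
strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .catalog import GenomicFeature


@dataclass(frozen=True)
class OverlapReport:
    """Neighbours whose spans intersect one deletion target's span."""

    feature: str
    neighbors: tuple[str, ...]
    count: int

    def __post_init__(self) -> None:
        if self.count != len(self.neighbors):
            raise ValueError("count must equal len(neighbors)")


class OverlapIndex:
    """Interval index over the overlap universe (CDS + ncRNA catalogs)."""

    def __init__(self, universe: Iterable[GenomicFeature]):
        self._trees: dict[str, IntervalTree] = {}
        for feat in universe:
            tree = self._trees.setdefault(feat.chrom_id, IntervalTree())
            # half-open interval end+1 so closed-interval adjacency is NOT overlap
            tree.addi(feat.start, feat.end + 1, feat)

    def neighbors(self, target: GenomicFeature) -> OverlapReport:
        tree = self._trees.get(target.chrom_id)
        hits: list[GenomicFeature] = []
        if tree is not None:
            for iv in tree.overlap(target.start, target.end + 1):
                other: GenomicFeature = iv.data
                if other.systematic_name != target.systematic_name:
                    hits.append(other)
        hits.sort(key=lambda f: (f.start, f.systematic_name))
        names = tuple(f.systematic_name for f in hits)
        return OverlapReport(feature=target.systematic_name, neighbors=names, count=len(names))


def find_disrupted_neighbors(
    target: GenomicFeature, universe: Sequence[GenomicFeature]
) -> OverlapReport:
    """One-off overlap query; batch callers should reuse an OverlapIndex."""
    return OverlapIndex(universe).neighbors(target)
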