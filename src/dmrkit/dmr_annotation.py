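"""Categorisation of DMRs against annotations and DMR-set overlap.

A DMR is assigned to exactly one category: TE if it shares at least one base
with any transposable element (TE precedence reflects that TEs are the
primary RdDM targets, and keeps TEs inside genes in the TE class), else gene
if it overlaps any gene, else intergenic.  Intergenic DMRs get a signed
distance from their midpoint to the nearest gene start codon (negative =
upstream of the gene in the gene's own orientation), summarised by the
fraction lying within a 1.5-kb promoter window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .methylome_io import FeatureSet, GenomicFeature

Interval3 = tuple[str, int, int]


def _as_intervals(items: Iterable) -> list[Interval3]:
    """Coerce DMRs / features / (chrom, start, end) tuples to plain intervals."""
    out = []
    for it in items:
        if hasattr(it, "chrom") and hasattr(it, "start") and hasattr(it, "end"):
            out.append((it.chrom, int(it.start), int(it.end)))
        else:
            chrom, start, end = it[0], int(it[1]), int(it[2])
            out.append((chrom, start, end))
    return out


def _build_trees(features: Iterable) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in _as_intervals(features):
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


@dataclass
class DMRCategorySummary:
    """Counts, fractions and membership of the gene / TE / intergenic classes."""

    counts: dict[str, int]
    fractions: dict[str, float]
    members: dict[str, list]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": [self.fractions[c] for c in self.counts],
            }
        )


def categorize_dmrs(
    dmrs: Sequence,
    genes: FeatureSet,
    tes: FeatureSet,
    precedence: Sequence[str] = ("TE", "gene"),
) -> DMRCategorySummary:
    """Assign each DMR to TE, gene or intergenic by >= 1 bp overlap.

    ``precedence`` orders the overlap checks for DMRs touching both a TE and
    a gene (default: TE wins).
    """
    trees = {"gene": _build_trees(genes), "TE": _build_trees(tes)}
    counts = {"gene": 0, "TE": 0, "intergenic": 0}
    members: dict[str, list] = {"gene": [], "TE": [], "intergenic": []}
    for dmr, (chrom, start, end) in zip(dmrs, _as_intervals(dmrs)):
        category = "intergenic"
        for cat in precedence:
            tree = trees[cat].get(chrom)
            if tree is not None and tree.overlap(start, end):
                category = cat
                break
        counts[category] += 1
        members[category].append(dmr)
    total = max(sum(counts.values()), 1)
    fractions = {c: n / total for c, n in counts.items()}
    return DMRCategorySummary(counts, fractions, members)


def distance_to_start(
    dmrs: Sequence, genes: FeatureSet, promoter_span: int = 1500
) -> tuple[list[float], float]:
    """Signed midpoint distances of (intergenic) DMRs to the nearest gene
    start codon.

    The start codon sits at feature.start for + genes and feature.end - 1
    for - genes.  Distance is signed in the gene's orientation: negative
    when the DMR lies upstream (promoter side).  Returns the distances and
    the fraction falling within ``promoter_span`` bp upstream.
    """
    if not len(genes):
        raise ValueError("distance_to_start requires a non-empty gene set")
    starts: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        codon = g.start if g.strand == "+" else g.end - 1
        starts.setdefault(g.chrom, []).append((codon, g.strand))
    distances = []
    for chrom, start, end in _as_intervals(dmrs):
        mid = (start + end - 1) / 2.0
        best = None
        for codon, strand in starts.get(chrom, []):
            signed = mid - codon if strand == "+" else codon - mid
            if best is None or abs(signed) < abs(best):
                best = signed
        if best is None:
            continue  # no gene on this chromosome
        distances.append(float(best))
    arr = np.asarray(distances)
    in_promoter = float(((arr >= -promoter_span) & (arr < 0)).mean()) if arr.size else 0.0
    return distances, in_promoter


@dataclass
class OverlapResult:
    """Directional overlap of DMR set A with DMR set B."""

    n_a: int
    n_b: int
    n_a_overlapping_b: int
    fraction_a_in_b: float
    non_overlapping_a: list

    def __post_init__(self):
        assert self.n_a_overlapping_b <= self.n_a


def overlap_dmr_sets(set_a: Sequence, set_b: Sequence, min_overlap: int = 1) -> OverlapResult:
    """Count members of A sharing >= ``min_overlap`` bp with any member of B.

    The call is directional (fraction of A covered); swap the arguments for
    the fraction of B in A.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees = _build_trees(set_b)
    a_items = list(set_a)
    n_hit = 0
    misses = []
    for item, (chrom, start, end) in zip(a_items, _as_intervals(a_items)):
        tree = trees.get(chrom)
        shared = 0
        if tree is not None:
            for iv in tree.overlap(start, end):
                shared = max(shared, min(end, iv.end) - max(start, iv.begin))
        if shared >= min_overlap:
            n_hit += 1
        else:
            misses.append(item)
    n_a = len(a_items)
    return OverlapResult(
        n_a=n_a,
        n_b=len(list(set_b)),
        n_a_overlapping_b=n_hit,
        fraction_a_in_b=(n_hit / n_a) if n_a else 0.0,
        non_overlapping_a=misses,
    )


def write_category_summary(summary: DMRCategorySummary, path: str | Path) -> None:
    summary.to_frame().to_csv(path, sep="\t", index=False)


def write_distances_tsv(
    distances: Sequence[float], promoter_fraction: float, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fraction_within_1.5kb_promoter\t{promoter_fraction:.4f}\n")
        fh.write("distance_bp\n")
        for d in distances:
            fh.write(f"{d:.1f}\n")
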