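"""Differentially methylated cytosine (DMC) and region (DMR) calling.

The procedure compares two single methylomes (no replicates):

1. Per cytosine, a two-tailed Fisher's exact test on the 2x2 table of
   methylated/unmethylated read counts; a cytosine with p < 0.05 is a DMC.
   Only cytosines covered by at least ``min_cov`` reads in both samples are
   tested.
2. 200-bp windows slid at 50-bp steps over the DMCs of one chromosome,
   context and direction; a window holding more than 2 DMCs is an anchor.
   Overlapping qualifying windows are unioned and each union is trimmed to
   the first and last DMC it contains.
3. Anchor regions separated by less than 100 bp are merged.
4. A merged region is a DMR if it spans >= 100 bp, holds >= 5 DMCs and the
   absolute difference in weighted methylation between the samples reaches
   the context threshold (0.30 CG / 0.15 CHG / 0.10 CHH).

Hypo- and hypermethylated cytosines are windowed separately, so every DMR
has a direction (of sample B relative to sample A).

The two-tailed Fisher p-value is defined by point-probability summation:
the sum of hypergeometric probabilities of all tables with the observed
margins whose point probability does not exceed that of the observed table
(with a 1e-12 relative slack for floating-point ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .methylome_io import CONTEXTS, MethylomeTable

_TIE_SLACK = 1e-12

DMC_COLUMNS = ["chrom", "pos", "strand", "context", "p_value", "delta", "direction"]


# ---------------------------------------------------------------------------
# Thresholds and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DMRThresholds:
    """All tunable parameters of the DMR procedure.

    Defaults are the published thresholds; ``min_cov`` (minimum read depth in
    both samples for a cytosine to be tested) and ``delta_mode`` are
    additional knobs the published description leaves open.
    """

    alpha: float = 0.05
    window: int = 200
    step: int = 50
    min_anchor_dmcs: int = 3  # "more than 2 DMCs"
    merge_gap: int = 100  # merge when gap is strictly less than this
    min_length: int = 100
    min_dmcs: int = 5
    min_abs_delta: Mapping[str, float] | None = None
    min_cov: int = 4
    delta_mode: str = "weighted"  # or "dmc": region delta over DMCs only

    def __post_init__(self):
        if self.min_abs_delta is None:
            object.__setattr__(
                self, "min_abs_delta", {"CG": 0.30, "CHG": 0.15, "CHH": 0.10}
            )
        for name in ("alpha", "window", "step", "min_anchor_dmcs", "merge_gap",
                     "min_length", "min_dmcs", "min_cov"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta_mode not in ("weighted", "dmc"):
            raise ValueError("delta_mode must be 'weighted' or 'dmc'")
        missing = [c for c in CONTEXTS if c not in self.min_abs_delta]
        if missing:
            raise ValueError(f"min_abs_delta missing contexts {missing}")


@dataclass(frozen=True)
class AnchorRegion:
    """A run of densely spaced DMCs, trimmed to its first and last DMC."""

    chrom: str
    start: int
    end: int  # last DMC position + 1
    dmc_count: int
    context: str
    direction: str  # 'hyper' or 'hypo' (sample B vs A)


@dataclass(frozen=True)
class DMR:
    chrom: str
    start: int
    end: int
    context: str
    direction: str
    dmc_count: int
    meth_a: float
    meth_b: float
    abs_delta: float

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Fisher's exact test (two-tailed, point-probability summation)
# ---------------------------------------------------------------------------

def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_tailed(a11: int, a12: int, a21: int, a22: int) -> float:
    """Two-tailed Fisher's exact p for a 2x2 table.

    Sums hypergeometric probabilities of every table with the observed
    margins whose point probability is <= that of the observed table
    (relative slack 1e-12 for float ties).  The hypergeometric pmf is
    evaluated in log space over the whole support.
    """
    for v in (a11, a12, a21, a22):
        if v < 0:
            raise ValueError("negative count in 2x2 table")
    total = a11 + a12 + a21 + a22
    if total == 0:
        raise ValueError("Fisher test undefined for an all-zero table")
    row1 = a11 + a12
    col1 = a11 + a21
    k_min = max(0, row1 - (total - col1))
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = np.exp(
        _log_binom(col1, support)
        + _log_binom(total - col1, row1 - support)
        - _log_binom(total, row1)
    )
    p_obs = pmf[a11 - k_min]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + _TIE_SLACK)].sum()))


def _fisher_pvalues(
    meth_a: np.ndarray, cov_a: np.ndarray, meth_b: np.ndarray, cov_b: np.ndarray
) -> np.ndarray:
    """Vectorised two-tailed Fisher p-values for many sites.

    Count tables repeat heavily at typical sequencing depths, so p-values
    are computed once per unique table and broadcast back.
    """
    tables = np.column_stack([meth_a, cov_a - meth_a, meth_b, cov_b - meth_b])
    uniq, inverse = np.unique(tables, axis=0, return_inverse=True)
    pvals = np.empty(len(uniq))
    for i, (a, b, c, d) in enumerate(uniq):
        pvals[i] = fisher_exact_two_tailed(int(a), int(b), int(c), int(d))
    return pvals[inverse]


# ---------------------------------------------------------------------------
# DMC calling
# ---------------------------------------------------------------------------

def call_dmcs(
    table_a: MethylomeTable,
    table_b: MethylomeTable,
    context: str,
    thresholds: DMRThresholds = DMRThresholds(),
) -> pd.DataFrame:
    """Call differentially methylated cytosines of one context.

    Returns a DataFrame with columns chrom, pos, strand, context, p_value,
    delta (methylation in B minus A) and direction ('hyper'/'hypo' of B),
    sorted by (chrom, pos).  Only cytosines covered >= ``min_cov`` in both
    samples are tested; a cytosine is a DMC when p < alpha.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    a = table_a.context_subset(context)
    b = table_b.context_subset(context)
    merged = a.merge(
        b, on=["chrom", "pos", "strand", "context"], suffixes=("_a", "_b")
    )
    cov_a = (merged["n_meth_a"] + merged["n_unmeth_a"]).to_numpy()
    cov_b = (merged["n_meth_b"] + merged["n_unmeth_b"]).to_numpy()
    tested = (cov_a >= thresholds.min_cov) & (cov_b >= thresholds.min_cov)
    merged = merged[tested]
    if not len(merged):
        return pd.DataFrame(columns=DMC_COLUMNS)
    cov_a, cov_b = cov_a[tested], cov_b[tested]
    ma = merged["n_meth_a"].to_numpy()
    mb = merged["n_meth_b"].to_numpy()
    p = _fisher_pvalues(ma, cov_a, mb, cov_b)
    delta = mb / cov_b - ma / cov_a
    keep = p < thresholds.alpha
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"].to_numpy()[keep],
            "pos": merged["pos"].to_numpy()[keep],
            "strand": merged["strand"].to_numpy()[keep],
            "context": context,
            "p_value": p[keep],
            "delta": delta[keep],
            "direction": np.where(delta[keep] > 0, "hyper", "hypo"),
        }
    )
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Windows, anchors, merging
# ---------------------------------------------------------------------------

def scan_anchor_regions(
    positions: Sequence[int],
    chrom: str,
    context: str,
    direction: str,
    window: int = 200,
    step: int = 50,
    min_dmc: int = 3,
) -> list[AnchorRegion]:
    """Slide fixed windows over sorted DMC positions of one chromosome,
    context and direction; union overlapping qualifying windows and trim each
    union to its first and last DMC.

    Windows start at multiples of ``step`` from the chromosome origin.
    """
    pos = np.asarray(sorted(positions), dtype=np.int64)
    if pos.size == 0:
        return []
    starts = np.arange(0, pos[-1] + 1, step, dtype=np.int64)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window, side="left")
    qual = (hi - lo) >= min_dmc
    q_starts = starts[qual]
    if q_starts.size == 0:
        return []
    # union overlapping qualifying windows
    unions: list[list[int]] = []
    for s in q_starts:
        e = int(s) + window
        if unions and s < unions[-1][1]:
            unions[-1][1] = e
        else:
            unions.append([int(s), e])
    anchors = []
    for s, e in unions:
        i0 = int(np.searchsorted(pos, s, side="left"))
        i1 = int(np.searchsorted(pos, e, side="left"))
        anchors.append(
            AnchorRegion(
                chrom=chrom,
                start=int(pos[i0]),
                end=int(pos[i1 - 1]) + 1,
                dmc_count=i1 - i0,
                context=context,
                direction=direction,
            )
        )
    return anchors


def merge_anchor_regions(
    anchors: Sequence[AnchorRegion], merge_gap: int = 100
) -> list[AnchorRegion]:
    """Merge sorted, disjoint anchors whose gap is strictly less than
    ``merge_gap`` bp; DMC counts are summed.  Idempotent."""
    if not anchors:
        return []
    ordered = sorted(anchors, key=lambda a: a.start)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start < prev.end:
            raise ValueError("anchor regions overlap; merge expects disjoint input")
        if (nxt.chrom, nxt.context, nxt.direction) != (prev.chrom, prev.context, prev.direction):
            raise ValueError("anchors to merge must share chromosome, context and direction")
    merged = [ordered[0]]
    for nxt in ordered[1:]:
        prev = merged[-1]
        if nxt.start - prev.end < merge_gap:
            merged[-1] = replace(
                prev, end=nxt.end, dmc_count=prev.dmc_count + nxt.dmc_count
            )
        else:
            merged.append(nxt)
    return merged


# ---------------------------------------------------------------------------
# Region methylation and final filters
# ---------------------------------------------------------------------------

def weighted_methylation(
    region: tuple[str, int, int], table: MethylomeTable, context: str
) -> float:
    """Coverage-weighted methylation level of one context over a region:
    sum(n_meth) / sum(n_meth + n_unmeth) over the covered cytosines of that
    context inside [start, end)."""
    chrom, start, end = region
    sub = table.context_subset(context)
    sub = sub[(sub["chrom"] == chrom) & (sub["pos"] >= start) & (sub["pos"] < end)]
    total = int(sub["n_meth"].sum() + sub["n_unmeth"].sum())
    if total == 0:
        raise ValueError(f"no covered {context} cytosines in {chrom}:{start}-{end}")
    return float(sub["n_meth"].sum() / total)


class _RegionSums:
    """Prefix-sum index over one sample's context cytosines for fast
    per-region methylation sums."""

    def __init__(self, frame: pd.DataFrame):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            meth = sub["n_meth"].to_numpy()[order].cumsum()
            tot = (sub["n_meth"] + sub["n_unmeth"]).to_numpy()[order].cumsum()
            self.by_chrom[str(chrom)] = (pos, meth, tot)

    def sums(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        if chrom not in self.by_chrom:
            return 0, 0
        pos, meth, tot = self.by_chrom[chrom]
        i0 = np.searchsorted(pos, start, side="left")
        i1 = np.searchsorted(pos, end, side="left")
        if i1 == i0:
            return 0, 0
        m = meth[i1 - 1] - (meth[i0 - 1] if i0 else 0)
        t = tot[i1 - 1] - (tot[i0 - 1] if i0 else 0)
        return int(m), int(t)


def finalize_dmrs(
    merged_anchors: Sequence[AnchorRegion],
    table_a: MethylomeTable,
    table_b: MethylomeTable,
    thresholds: DMRThresholds = DMRThresholds(),
    dmcs: pd.DataFrame | None = None,
) -> list[DMR]:
    """Apply the final DMR filters to merged anchor regions.

    A region is kept when it spans >= ``min_length`` bp, holds >=
    ``min_dmcs`` DMCs, and the absolute difference of the two samples'
    weighted methylation reaches the context threshold.  In ``delta_mode ==
    'weighted'`` the levels pool every covered context cytosine in the
    region; in ``'dmc'`` mode only the DMC positions themselves (``dmcs``
    required).
    """
    if not merged_anchors:
        return []
    context = merged_anchors[0].context
    if context not in thresholds.min_abs_delta:
        raise ValueError(f"thresholds missing context {context!r}")
    if thresholds.delta_mode == "dmc":
        if dmcs is None:
            raise ValueError("delta_mode='dmc' requires the DMC table")
        keys = dmcs[dmcs["context"] == context][["chrom", "pos", "strand"]]
        frame_a = table_a.context_subset(context).merge(keys, on=["chrom", "pos", "strand"])
        frame_b = table_b.context_subset(context).merge(keys, on=["chrom", "pos", "strand"])
    else:
        frame_a = table_a.context_subset(context)
        frame_b = table_b.context_subset(context)
    sums_a = _RegionSums(frame_a)
    sums_b = _RegionSums(frame_b)
    min_delta = thresholds.min_abs_delta[context]
    out = []
    for anchor in merged_anchors:
        if anchor.end - anchor.start < thresholds.min_length:
            continue
        if anchor.dmc_count < thresholds.min_dmcs:
            continue
        ma_m, ma_t = sums_a.sums(anchor.chrom, anchor.start, anchor.end)
        mb_m, mb_t = sums_b.sums(anchor.chrom, anchor.start, anchor.end)
        if ma_t == 0 or mb_t == 0:
            continue  # no covered cytosines: level undefined
        level_a = ma_m / ma_t
        level_b = mb_m / mb_t
        abs_delta = abs(level_b - level_a)
        if abs_delta < min_delta:
            continue
        out.append(
            DMR(
                chrom=anchor.chrom,
                start=anchor.start,
                end=anchor.end,
                context=anchor.context,
                direction=anchor.direction,
                dmc_count=anchor.dmc_count,
                meth_a=level_a,
                meth_b=level_b,
                abs_delta=abs_delta,
            )
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def call_dmrs(
    table_a: MethylomeTable,
    table_b: MethylomeTable,
    thresholds: DMRThresholds = DMRThresholds(),
    contexts: Sequence[str] = CONTEXTS,
) -> list[DMR]:
    """Run the full DMC -> window -> anchor -> merge -> filter pipeline.

    Contexts are analysed independently and hypo/hyper directions are
    windowed separately; the returned DMRs are sorted by (chrom, start).
    """
    dmrs: list[DMR] = []
    for context in contexts:
        dmcs = call_dmcs(table_a, table_b, context, thresholds)
        if not len(dmcs):
            continue
        merged_all: list[AnchorRegion] = []
        for (chrom, direction), sub in dmcs.groupby(["chrom", "direction"], sort=True):
            anchors = scan_anchor_regions(
                sub["pos"].to_numpy(),
                chrom=str(chrom),
                context=context,
                direction=str(direction),
                window=thresholds.window,
                step=thresholds.step,
                min_dmc=thresholds.min_anchor_dmcs,
            )
            merged_all.extend(merge_anchor_regions(anchors, thresholds.merge_gap))
        dmrs.extend(finalize_dmrs(merged_all, table_a, table_b, thresholds, dmcs=dmcs))
    return sorted(dmrs, key=lambda d: (d.chrom, d.start, d.context, d.direction))


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_dmrs_bed(dmrs: Sequence[DMR], path: str | Path) -> None:
    """BED6+ output: chrom, start, end, name, abs_delta x 1000 as score, '.'
    strand, then context, dmc_count, meth_a, meth_b, direction."""
    with open(path, "w") as fh:
        for i, d in enumerate(dmrs):
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\tDMR_{i + 1}\t"
                f"{int(round(d.abs_delta * 1000))}\t.\t{d.context}\t{d.dmc_count}\t"
                f"{d.meth_a:.4f}\t{d.meth_b:.4f}\t{d.direction}\n"
            )


def read_dmrs_bed(path: str | Path) -> list[DMR]:
    dmrs = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            dmrs.append(
                DMR(f[0], int(f[1]), int(f[2]), f[6], f[10], int(f[7]),
                    float(f[8]), float(f[9]), abs(float(f[9]) - float(f[8])))
            )
    return dmrs


def write_dmcs_tsv(dmcs: pd.DataFrame, path: str | Path) -> None:
    dmcs.to_csv(path, sep="\t", index=False)
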