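"""Metagene / meta-TE methylation profiles.

Averages weighted methylation over feature bodies (rescaled to a fixed
number of fractional bins) and 2-kb flanks (fixed-width bins), per sequence
context, with features stratified into five size groups.  Minus-strand
features are orientation-flipped so the upstream flank is always the 5' side.

Pooling is count-weighted by default: each bin's level is
sum(methylated reads) / sum(total reads) over every contributing cytosine of
every feature, which is robust at low per-feature coverage.  A
mean-of-feature-means mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylome_io import CONTEXTS, FeatureSet, GenomicFeature, MethylomeTable


@dataclass(frozen=True)
class SizeGroupSpec:
    """Ascending length breakpoints (bp) splitting features into groups.

    The default (1, 2, 3, 4 kb) yields five groups: <1 kb, 1-2 kb, 2-3 kb,
    3-4 kb and >4 kb.  A feature of length exactly equal to a breakpoint
    falls in the upper group (breakpoints are "< length" boundaries).
    """

    breakpoints: tuple[int, ...] = (1000, 2000, 3000, 4000)

    def __post_init__(self):
        bp = tuple(self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly ascending")
        if any(b <= 0 for b in bp):
            raise ValueError("breakpoints must be positive")
        object.__setattr__(self, "breakpoints", bp)

    @property
    def n_groups(self) -> int:
        return len(self.breakpoints) + 1

    @classmethod
    def from_quantiles(cls, features: FeatureSet, n_groups: int = 5) -> "SizeGroupSpec":
        """Breakpoints at length quantiles so groups are equally populated."""
        lengths = np.array([f.length for f in features])
        qs = np.quantile(lengths, np.linspace(0, 1, n_groups + 1)[1:-1])
        bp, last = [], 0
        for q in np.ceil(qs).astype(int):
            if q > last:
                bp.append(int(q))
                last = int(q)
        return cls(tuple(bp))


def assign_size_groups(
    features: FeatureSet, spec: SizeGroupSpec = SizeGroupSpec()
) -> dict[str, int]:
    """Map feature_id -> size group 1..n.

    Group 1 holds features strictly shorter than the first breakpoint (the
    "<1 kb" class under the defaults); a feature exactly at a breakpoint
    falls in the upper group.
    """
    return {
        f.feature_id: 1 + sum(b <= f.length for b in spec.breakpoints)
        for f in features
    }


@dataclass
class MetaProfile:
    """Binned methylation over bodies and flanks of one context/size group.

    Per zone the profile stores pooled methylated/total read sums, the
    per-bin mean (NaN where no cytosine was covered — zero-coverage bins are
    flagged, not zero-filled) and the number of contributing features.
    """

    context: str
    size_group: int
    n_features: int
    flank: int
    flank_bin: int
    body_bins: int
    upstream_meth: np.ndarray
    upstream_total: np.ndarray
    upstream_n: np.ndarray
    body_meth: np.ndarray
    body_total: np.ndarray
    body_n: np.ndarray
    downstream_meth: np.ndarray
    downstream_total: np.ndarray
    downstream_n: np.ndarray
    # mean-of-feature-means accumulators (used when pooling='features')
    feature_mean_sums: dict | None = None

    def _mean(self, meth: np.ndarray, total: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, meth / np.maximum(total, 1), np.nan)

    @property
    def upstream_mean(self) -> np.ndarray:
        return self._mean(self.upstream_meth, self.upstream_total)

    @property
    def body_mean(self) -> np.ndarray:
        return self._mean(self.body_meth, self.body_total)

    @property
    def downstream_mean(self) -> np.ndarray:
        return self._mean(self.downstream_meth, self.downstream_total)


def _bin_indices(
    pos: np.ndarray, feature: GenomicFeature, flank: int, flank_bin: int, body_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Zone (0 up / 1 body / 2 down) and bin index for cytosine positions of
    one feature, in the feature's own 5'->3' orientation."""
    length = feature.length
    if feature.strand == "+":
        offset = pos - feature.start
    else:
        offset = (feature.end - 1) - pos
    zone = np.full(pos.shape, -1, dtype=np.int8)
    binidx = np.zeros(pos.shape, dtype=np.int64)
    up = (offset < 0) & (offset >= -flank)
    zone[up] = 0
    binidx[up] = (offset[up] + flank) // flank_bin
    body = (offset >= 0) & (offset < length)
    zone[body] = 1
    binidx[body] = np.minimum(offset[body] * body_bins // length, body_bins - 1)
    down = (offset >= length) & (offset < length + flank)
    zone[down] = 2
    binidx[down] = (offset[down] - length) // flank_bin
    return zone, binidx


def compute_metaprofile(
    features: FeatureSet,
    table: MethylomeTable,
    context: str,
    spec: SizeGroupSpec = SizeGroupSpec(),
    flank: int = 2000,
    body_bins: int = 40,
    flank_bin: int = 100,
    pooling: str = "counts",
) -> dict[int, MetaProfile]:
    """Compute per-size-group methylation profiles over bodies and flanks.

    Returns a dict size_group -> MetaProfile; size groups with no features
    are omitted.  ``pooling='counts'`` (default) pools reads across features;
    ``'features'`` averages per-feature bin levels.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if pooling not in ("counts", "features"):
        raise ValueError("pooling must be 'counts' or 'features'")
    if flank % flank_bin:
        raise ValueError("flank must be a multiple of flank_bin")
    n_flank_bins = flank // flank_bin

    sub = table.context_subset(context)
    sub = sub[(sub["n_meth"] + sub["n_unmeth"]) > 0]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, s in sub.groupby("chrom", sort=False):
        pos = s["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        by_chrom[str(chrom)] = (
            pos[order],
            s["n_meth"].to_numpy()[order],
            (s["n_meth"] + s["n_unmeth"]).to_numpy()[order],
        )

    groups = assign_size_groups(features, spec)
    profiles: dict[int, MetaProfile] = {}
    # per-group accumulators for the 'features' pooling mode
    fm_sum: dict[int, dict[int, np.ndarray]] = {}
    fm_n: dict[int, dict[int, np.ndarray]] = {}
    zone_sizes = (n_flank_bins, body_bins, n_flank_bins)

    def _get_profile(g: int) -> MetaProfile:
        if g not in profiles:
            profiles[g] = MetaProfile(
                context=context, size_group=g, n_features=0,
                flank=flank, flank_bin=flank_bin, body_bins=body_bins,
                upstream_meth=np.zeros(n_flank_bins), upstream_total=np.zeros(n_flank_bins),
                upstream_n=np.zeros(n_flank_bins, dtype=int),
                body_meth=np.zeros(body_bins), body_total=np.zeros(body_bins),
                body_n=np.zeros(body_bins, dtype=int),
                downstream_meth=np.zeros(n_flank_bins), downstream_total=np.zeros(n_flank_bins),
                downstream_n=np.zeros(n_flank_bins, dtype=int),
            )
            fm_sum[g] = {z: np.zeros(n) for z, n in enumerate(zone_sizes)}
            fm_n[g] = {z: np.zeros(n, dtype=int) for z, n in enumerate(zone_sizes)}
        return profiles[g]

    for feature in features:
        if feature.chrom not in by_chrom:
            continue
        pos, meth, tot = by_chrom[feature.chrom]
        lo = np.searchsorted(pos, feature.start - flank, side="left")
        hi = np.searchsorted(pos, feature.end + flank, side="left")
        g = groups[feature.feature_id]
        prof = _get_profile(g)
        prof.n_features += 1
        if hi == lo:
            continue
        p, m, t = pos[lo:hi], meth[lo:hi], tot[lo:hi]
        zone, binidx = _bin_indices(p, feature, flank, flank_bin, body_bins)
        for z, (tgt_m, tgt_t, tgt_n) in enumerate(
            (
                (prof.upstream_meth, prof.upstream_total, prof.upstream_n),
                (prof.body_meth, prof.body_total, prof.body_n),
                (prof.downstream_meth, prof.downstream_total, prof.downstream_n),
            )
        ):
            sel = zone == z
            if not sel.any():
                continue
            nbins = zone_sizes[z]
            bm = np.bincount(binidx[sel], weights=m[sel], minlength=nbins)
            bt = np.bincount(binidx[sel], weights=t[sel], minlength=nbins)
            tgt_m += bm
            tgt_t += bt
            covered = bt > 0
            tgt_n += covered.astype(int)
            with np.errstate(invalid="ignore", divide="ignore"):
                fl = np.where(covered, bm / np.maximum(bt, 1), 0.0)
            fm_sum[g][z] += fl
            fm_n[g][z] += covered.astype(int)

    if pooling == "features":
        for g, prof in profiles.items():
            for z, (attr_m, attr_t) in enumerate(
                (
                    ("upstream_meth", "upstream_total"),
                    ("body_meth", "body_total"),
                    ("downstream_meth", "downstream_total"),
                )
            ):
                n = fm_n[g][z]
                mean = np.where(n > 0, fm_sum[g][z] / np.maximum(n, 1), np.nan)
                # store so that meth/total reproduces the feature-mean
                setattr(prof, attr_m, np.where(n > 0, mean, 0.0))
                setattr(prof, attr_t, (n > 0).astype(float))
    return profiles


def metaprofile_frame(profiles: Mapping[int, MetaProfile]) -> pd.DataFrame:
    """Long-format table: context, group, zone, bin_index, mean, n."""
    rows = []
    for g in sorted(profiles):
        prof = profiles[g]
        for zone, mean, n in (
            ("upstream", prof.upstream_mean, prof.upstream_n),
            ("body", prof.body_mean, prof.body_n),
            ("downstream", prof.downstream_mean, prof.downstream_n),
        ):
            for i, (m, k) in enumerate(zip(mean, n)):
                rows.append((prof.context, g, zone, i, m, int(k)))
    return pd.DataFrame(rows, columns=["context", "group", "zone", "bin_index", "mean", "n"])


def write_metaprofile_tsv(profiles: Mapping[int, MetaProfile], path: str | Path) -> None:
    metaprofile_frame(profiles).to_csv(path, sep="\t", index=False)


def plot_metaprofile(profiles: Mapping[int, MetaProfile], path: str | Path) -> None:
    """Render the profiles (one line per size group) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for g in sorted(profiles):
        prof = profiles[g]
        y = np.concatenate([prof.upstream_mean, prof.body_mean, prof.downstream_mean])
        ax.plot(np.arange(y.size), y, label=f"group {g} (n={prof.n_features})")
    nf = next(iter(profiles.values())).upstream_mean.size
    nb = next(iter(profiles.values())).body_mean.size
    ax.axvline(nf - 0.5, color="grey", lw=0.5)
    ax.axvline(nf + nb - 0.5, color="grey", lw=0.5)
    ax.set_ylabel("weighted methylation")
    ax.set_xlabel("upstream | body | downstream bins")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
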