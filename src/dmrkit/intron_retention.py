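"""Intron-retention calling from per-intron RNA-seq read counts.

Two libraries are compared intron by intron with the Audic–Claverie
statistic, a Poisson-based test for digital count data that normalises for
library size: given x reads on an intron in library 1 (size N1), the
probability of seeing y reads in library 2 (size N2) is

    p(y | x) = (N2/N1)^y * (x + y)! / ( x! * y! * (1 + N2/N1)^(x + y + 1) )

which is a negative-binomial distribution in y.  The two-sided p-value is
twice the smaller tail, capped at 1.  Benjamini–Hochberg FDR is applied
across all tested introns, and an intron is called retained when more than
95% of its bases are read-covered, FDR < 0.01, and the library-size
normalised count is higher in the second (mutant) sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests


class IntronRecord(NamedTuple):
    gene_id: str
    intron_index: int  # 1-based within gene
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str


@dataclass
class IntronCountTable:
    """Per-intron read counts for two libraries.

    ``x``/``y`` are raw counts in sample 1 (reference) and sample 2
    (mutant); ``n1``/``n2`` the library sizes (total mapped reads);
    ``covered_frac`` the fraction of intron bases covered by at least one
    read in sample 2.
    """

    introns: list[IntronRecord]
    x: np.ndarray
    y: np.ndarray
    n1: float
    n2: float
    covered_frac: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.covered_frac = np.asarray(self.covered_frac, dtype=float)
        if not (len(self.introns) == self.x.size == self.y.size == self.covered_frac.size):
            raise ValueError("intron table arrays have mismatched lengths")
        if (self.x < 0).any() or (self.y < 0).any():
            raise ValueError("negative intron counts")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library sizes must be positive")
        if ((self.covered_frac < 0) | (self.covered_frac > 1)).any():
            raise ValueError("covered_frac outside [0, 1]")

    def __len__(self) -> int:
        return len(self.introns)


@dataclass(frozen=True)
class RetentionEvent:
    intron: IntronRecord
    x: int
    y: int
    p_value: float
    q_value: float
    covered_frac: float
    direction: str = "sample2_up"


# ---------------------------------------------------------------------------
# Audic–Claverie statistic
# ---------------------------------------------------------------------------

def _log_point(y: np.ndarray, x: int, ratio: float) -> np.ndarray:
    """log p(y | x) at library-size ratio N2/N1, vectorised over y."""
    y = np.asarray(y, dtype=np.int64)
    return (
        y * np.log(ratio)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(ratio)
    )


def audic_claverie_point(x: int, y: int, n1: float, n2: float) -> float:
    """Point probability p(y | x) of the Audic–Claverie model, computed in
    log space for numerical stability."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    return float(np.exp(_log_point(np.array([y]), x, n2 / n1))[0])


def audic_claverie_test(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic–Claverie p-value: twice the smaller of the lower and
    upper tail sums of p(. | x), capped at 1.

    The (infinite) upper tail is summed in blocks until additional terms
    fall below 1e-15 of the running sum.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    ratio = n2 / n1
    lower = float(np.exp(_log_point(np.arange(0, y + 1), x, ratio)).sum())
    # upper tail from y upward; mean of the distribution is ~ (x + 1) * ratio
    upper = 0.0
    k = y
    block = max(256, int(4 * (x + 1) * max(ratio, 1.0)))
    while True:
        terms = np.exp(_log_point(np.arange(k, k + block), x, ratio))
        upper += float(terms.sum())
        k += block
        if terms[-1] < 1e-15 * max(upper, 1e-300) and k > (x + 1) * ratio:
            break
    return min(1.0, 2.0 * min(lower, upper))


# ---------------------------------------------------------------------------
# FDR and event calling
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_intron_retention(
    table: IntronCountTable, cov_min: float = 0.95, fdr_max: float = 0.01
) -> list[RetentionEvent]:
    """Call retained introns: covered_frac > ``cov_min``, BH q < ``fdr_max``
    and normalised count higher in sample 2.

    Every intron in the table is tested and enters the FDR correction;
    the coverage and direction filters apply only to event selection.
    """
    if not len(table):
        return []
    p = np.array(
        [
            audic_claverie_test(int(x), int(y), table.n1, table.n2)
            for x, y in zip(table.x, table.y)
        ]
    )
    q = bh_fdr(p)
    up = table.y / table.n2 > table.x / table.n1
    events = []
    for i in np.nonzero((table.covered_frac > cov_min) & (q < fdr_max) & up)[0]:
        events.append(
            RetentionEvent(
                intron=table.introns[i],
                x=int(table.x[i]),
                y=int(table.y[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                covered_frac=float(table.covered_frac[i]),
            )
        )
    return events


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COLS = ["gene_id", "intron_index", "chrom", "start", "end", "strand", "x", "y", "covered_frac"]


def read_intron_counts(path: str | Path) -> IntronCountTable:
    """Read a per-intron count TSV with library sizes in '# N1=..' / '# N2=..'
    header lines."""
    n1 = n2 = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            token = line[1:].strip()
            if token.startswith("N1="):
                n1 = float(token[3:])
            elif token.startswith("N2="):
                n2 = float(token[3:])
    if n1 is None or n2 is None:
        raise ValueError(f"{path}: missing '# N1=' / '# N2=' header lines")
    frame = pd.read_csv(path, sep="\t", comment="#", names=_COLS, header=None)
    introns = [
        IntronRecord(str(r.gene_id), int(r.intron_index), str(r.chrom),
                     int(r.start), int(r.end), str(r.strand))
        for r in frame.itertuples(index=False)
    ]
    return IntronCountTable(
        introns=introns,
        x=frame["x"].to_numpy(),
        y=frame["y"].to_numpy(),
        n1=n1,
        n2=n2,
        covered_frac=frame["covered_frac"].to_numpy(),
    )


def write_intron_counts(table: IntronCountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# N1={table.n1:.0f}\n# N2={table.n2:.0f}\n")
        for rec, x, y, cf in zip(table.introns, table.x, table.y, table.covered_frac):
            fh.write(
                f"{rec.gene_id}\t{rec.intron_index}\t{rec.chrom}\t{rec.start}\t"
                f"{rec.end}\t{rec.strand}\t{x}\t{y}\t{cf:.4f}\n"
            )


def write_retention_events(events: Sequence[RetentionEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tintron_index\tchrom\tstart\tend\tstrand\tx\ty\tp_value\tq_value\tcovered_frac\n")
        for e in events:
            r = e.intron
            fh.write(
                f"{r.gene_id}\t{r.intron_index}\t{r.chrom}\t{r.start}\t{r.end}\t"
                f"{r.strand}\t{e.x}\t{e.y}\t{e.p_value:.3e}\t{e.q_value:.3e}\t{e.covered_frac:.4f}\n"
            )
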