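"""Chi-square goodness-of-fit tests for Mendelian segregation ratios.

Pearson's chi-square without continuity correction is the conventional test
for segregation counts against an expected ratio (e.g. 1:3 for a recessive
single-locus trait in an F2, or 1:2 for transmission through a heterozygote
with one lethal homozygous class).  A Yates-corrected variant is available
for the two-class case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[float, ...]
    expected: tuple[float, ...]
    ratio: tuple[float, ...]
    chi2: float
    df: int
    p_value: float

    def __str__(self) -> str:
        obs = ":".join(f"{o:g}" for o in self.observed)
        rat = ":".join(f"{r:g}" for r in self.ratio)
        return (
            f"observed {obs} vs ratio {rat}: chi2 = {self.chi2:.4f}, "
            f"df = {self.df}, p = {self.p_value:.4f}"
        )


def segregation_chisq(
    observed: Sequence[float],
    ratio: Sequence[float],
    yates: bool = False,
) -> SegregationResult:
    """Test observed class counts against an expected segregation ratio.

    ``expected_i = total * ratio_i / sum(ratio)``; the statistic is
    ``sum((obs - exp)^2 / exp)`` with df = classes - 1.  ``yates`` applies
    the continuity correction ``(|obs - exp| - 0.5)^2 / exp`` (two-class
    case).
    """
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(ratio, dtype=float)
    if obs.size != w.size or obs.size < 2:
        raise ValueError("observed and ratio must have equal length >= 2")
    if (obs < 0).any():
        raise ValueError("negative observed counts")
    if (w <= 0).any():
        raise ValueError("ratio weights must be positive")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")
    expected = total * w / w.sum()
    if yates:
        adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
        chi2 = float((adj**2 / expected).sum())
        df = obs.size - 1
        p = float(stats.chi2.sf(chi2, df))
    else:
        chi2, p = stats.chisquare(obs, f_exp=expected)
        chi2, p = float(chi2), float(p)
        df = obs.size - 1
    return SegregationResult(
        observed=tuple(obs),
        expected=tuple(expected),
        ratio=tuple(w),
        chi2=chi2,
        df=df,
        p_value=p,
    )
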