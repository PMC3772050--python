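"""Ground-truthed synthetic data for every pipeline stage.

The methylome simulator emulates the count-level structure of a plant
whole-genome bisulfite experiment: per-cytosine binomial counts at a mean
depth of 15 reads (matching the 15-18x range of typical single-methylome
studies), a bisulfite non-conversion floor of 0.4% (within the usual
0.3-0.5% error band), context-specific baseline methylation for genomic
background and for TE intervals, and planted differential regions of stated
effect size for one sample.  Non-conversion raises the observed methylation
probability to m' = m + (1 - m) * err — bisulfite failure can only inflate
apparent methylation.

The intron simulator draws per-intron Poisson counts at two library sizes
with planted retention events at a given fold change.

All draws come from one seeded numpy Generator, so the same configuration
and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .intron_retention import IntronCountTable, IntronRecord
from .methylome_io import (
    CONTEXTS,
    FeatureSet,
    Genome,
    GenomicFeature,
    MethylomeTable,
    context_frame,
)

DEFAULT_BACKGROUND = {"CG": 0.20, "CHG": 0.05, "CHH": 0.02}
DEFAULT_TE_LEVELS = {"CG": 0.80, "CHG": 0.50, "CHH": 0.10}


class PlantedDMR(NamedTuple):
    chrom: str
    start: int
    end: int
    context: str
    delta: float
    direction: str  # 'hyper' or 'hypo' of sample B


@dataclass(frozen=True)
class TruthSet:
    """What the simulator planted, for recall/precision scoring."""

    dmrs: tuple[PlantedDMR, ...] = ()
    retained_introns: tuple[int, ...] = ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dmrs": [list(d) for d in self.dmrs],
            "retained_introns": list(self.retained_introns),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            dmrs=tuple(PlantedDMR(*d) for d in payload["dmrs"]),
            retained_introns=tuple(payload["retained_introns"]),
        )


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethylomeSimConfig:
    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    gc_fraction: float = 0.36
    mean_depth: float = 15.0
    error_rate: float = 0.004
    background: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    te_levels: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TE_LEVELS))
    te_intervals: tuple[tuple[str, int, int], ...] = ()
    planted_dmrs: tuple[PlantedDMR, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.genome_length < self.n_chromosomes or self.n_chromosomes < 1:
            raise ValueError("invalid genome_length / n_chromosomes")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        for levels in (self.background, self.te_levels):
            for ctx in CONTEXTS:
                if ctx not in levels:
                    raise ValueError(f"baseline methylation missing context {ctx}")
                if not 0 <= levels[ctx] <= 1:
                    raise ValueError("baseline methylation outside [0, 1]")
        lengths = self.chrom_lengths
        object.__setattr__(self, "planted_dmrs", tuple(PlantedDMR(*d) for d in self.planted_dmrs))
        object.__setattr__(self, "te_intervals", tuple(tuple(t) for t in self.te_intervals))
        for d in self.planted_dmrs:
            if d.chrom not in lengths or not 0 <= d.start < d.end <= lengths[d.chrom]:
                raise ValueError(f"planted DMR {d} outside the genome")
            if d.context not in CONTEXTS:
                raise ValueError(f"planted DMR {d} has invalid context")
            if d.direction not in ("hyper", "hypo"):
                raise ValueError(f"planted DMR {d} has invalid direction")
            base = self._baseline_at(d.chrom, d.start, d.end, d.context)
            shifted = base + d.delta if d.direction == "hyper" else base - d.delta
            if not 0 <= shifted <= 1:
                raise ValueError(
                    f"planted DMR {d}: shifted methylation {shifted:.3f} outside [0, 1]"
                )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        per = self.genome_length // self.n_chromosomes
        lengths = {f"Chr{i + 1}": per for i in range(self.n_chromosomes)}
        lengths[f"Chr{self.n_chromosomes}"] += self.genome_length - per * self.n_chromosomes
        return lengths

    def _baseline_at(self, chrom: str, start: int, end: int, context: str) -> float:
        for tc, ts, te in self.te_intervals:
            if tc == chrom and start < te and end > ts:
                return self.te_levels[context]
        return self.background[context]


def _random_genome(rng: np.random.Generator, lengths: Mapping[str, int], gc: float) -> Genome:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for chrom, L in lengths.items():
        arr = rng.choice(bases, size=L, p=probs)
        seqs[chrom] = arr.tobytes().decode()
    return Genome(seqs)


def simulate_methylome_pair(
    config: MethylomeSimConfig,
) -> tuple[Genome, MethylomeTable, MethylomeTable, TruthSet]:
    """Simulate a genome and two per-cytosine count tables (samples A and B).

    Sample A carries the baseline methylation everywhere; sample B is shifted
    by each planted DMR's delta inside its interval (for cytosines of the
    planted context).  Per cytosine and sample, coverage ~ Poisson(depth)
    and n_meth ~ Binomial(coverage, m + (1 - m) * error_rate).
    """
    rng = np.random.default_rng(config.seed)
    genome = _random_genome(rng, config.chrom_lengths, config.gc_fraction)
    sites = context_frame(genome)
    n = len(sites)
    chrom_arr = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    ctx = sites["context"].to_numpy()

    m_a = np.empty(n)
    for context, level in config.background.items():
        m_a[ctx == context] = level
    for tc, ts, te in config.te_intervals:
        inside = (chrom_arr == tc) & (pos >= ts) & (pos < te)
        for context, level in config.te_levels.items():
            m_a[inside & (ctx == context)] = level
    m_b = m_a.copy()
    for d in config.planted_dmrs:
        sel = (chrom_arr == d.chrom) & (pos >= d.start) & (pos < d.end) & (ctx == d.context)
        m_b[sel] = m_b[sel] + d.delta if d.direction == "hyper" else m_b[sel] - d.delta

    tables = []
    for sample_id, m in (("sample_A", m_a), ("sample_B", m_b)):
        cov = rng.poisson(config.mean_depth, size=n)
        m_obs = np.clip(m + (1 - m) * config.error_rate, 0.0, 1.0)
        n_meth = rng.binomial(cov, m_obs)
        frame = pd.DataFrame(
            {
                "chrom": chrom_arr,
                "pos": pos,
                "strand": sites["strand"].to_numpy(),
                "context": ctx,
                "n_meth": n_meth,
                "n_unmeth": cov - n_meth,
            }
        )
        tables.append(MethylomeTable(sample_id, frame))
    truth = TruthSet(dmrs=config.planted_dmrs)
    return genome, tables[0], tables[1], truth


def plant_dmrs_uniform(
    config_lengths: Mapping[str, int],
    n_dmrs: int,
    dmr_length: int,
    context: str = "CG",
    delta: float = 0.4,
    direction: str = "hyper",
    min_gap: int = 2000,
    seed: int = 0,
) -> tuple[PlantedDMR, ...]:
    """Lay out ``n_dmrs`` non-overlapping intervals of ``dmr_length`` bp,
    separated by at least ``min_gap``, spread evenly across chromosomes."""
    rng = np.random.default_rng(seed)
    chroms = list(config_lengths)
    per_chrom = int(np.ceil(n_dmrs / len(chroms)))
    dmrs: list[PlantedDMR] = []
    for chrom in chroms:
        L = config_lengths[chrom]
        slot = L // per_chrom
        if slot < dmr_length + min_gap:
            raise ValueError("genome too small for the requested planted DMRs")
        for i in range(per_chrom):
            if len(dmrs) == n_dmrs:
                break
            lo = i * slot
            start = int(rng.integers(lo, lo + slot - dmr_length - min_gap + 1))
            dmrs.append(PlantedDMR(chrom, start, start + dmr_length, context, delta, direction))
    return tuple(dmrs)


# ---------------------------------------------------------------------------
# Feature simulation
# ---------------------------------------------------------------------------

def _default_gene_sizes(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.clip(rng.lognormal(np.log(1800), 0.7, n), 200, 15000).astype(int)


def _default_te_sizes(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.clip(rng.lognormal(np.log(900), 1.0, n), 100, 12000).astype(int)


def simulate_features(
    genome: Genome,
    n_genes: int = 200,
    n_tes: int = 100,
    gene_sizes: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    te_sizes: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    max_tries: int = 1000,
) -> tuple[FeatureSet, FeatureSet]:
    """Place non-overlapping gene and TE intervals with random strands.

    Sizes come from the supplied samplers (log-normal defaults roughly
    matching plant gene/TE length distributions).  Raises when the genome
    cannot host the requested features.
    """
    rng = np.random.default_rng(seed)
    gene_sizes = gene_sizes or _default_gene_sizes
    te_sizes = te_sizes or _default_te_sizes
    lengths = genome.lengths
    chroms = list(lengths)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def _place(size: int) -> tuple[str, int] | None:
        for _ in range(max_tries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = lengths[chrom]
            if L <= size:
                continue
            start = int(rng.integers(0, L - size))
            if all(start + size <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, start + size))
                return chrom, start
        return None

    def _make(n: int, sizes: np.ndarray, prefix: str, kind: str) -> FeatureSet:
        feats = []
        for i in range(n):
            spot = _place(int(sizes[i]))
            if spot is None:
                raise ValueError("genome too small to place the requested features")
            chrom, start = spot
            strand = "+" if rng.random() < 0.5 else "-"
            feats.append(
                GenomicFeature(f"{prefix}{i + 1}", chrom, start, start + int(sizes[i]), strand, kind)
            )
        return FeatureSet(tuple(feats), kind=kind)

    genes = _make(n_genes, gene_sizes(rng, n_genes), "gene", "gene")
    tes = _make(n_tes, te_sizes(rng, n_tes), "TE", "TE")
    return genes, tes


# ---------------------------------------------------------------------------
# Intron count simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntronSimConfig:
    n_introns: int = 5000
    mean_count: float = 50.0
    # defaults emulate a pair of ~50M-read plant RNA-seq libraries
    n1: float = 48_300_000.0
    n2: float = 49_600_000.0
    planted: tuple[tuple[int, float, float], ...] = ()  # (index, fold_change, covered_frac)
    intron_length: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_introns <= 0 or self.mean_count <= 0:
            raise ValueError("n_introns and mean_count must be positive")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library sizes must be positive")
        object.__setattr__(self, "planted", tuple(tuple(p) for p in self.planted))
        for idx, fold, cf in self.planted:
            if not 0 <= idx < self.n_introns:
                raise ValueError(f"planted intron index {idx} out of range")
            if fold <= 1:
                raise ValueError("planted fold_change must exceed 1")
            if not 0 <= cf <= 1:
                raise ValueError("covered_frac outside [0, 1]")


def simulate_intron_counts(config: IntronSimConfig) -> tuple[IntronCountTable, TruthSet]:
    """Draw per-intron Poisson counts for two libraries.

    Null introns: x, y ~ Poisson(mu) and Poisson(mu * N2/N1); planted
    introns multiply the sample-2 rate by their fold change and carry their
    configured covered fraction (null coverage ~ Uniform(0.2, 1)).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_introns
    fold = np.ones(n)
    covered = rng.uniform(0.2, 1.0, size=n)
    planted_idx = []
    for idx, fc, cf in config.planted:
        fold[idx] = fc
        covered[idx] = cf
        planted_idx.append(int(idx))
    mu = np.full(n, config.mean_count)
    x = rng.poisson(mu)
    y = rng.poisson(mu * fold * (config.n2 / config.n1))
    introns = [
        IntronRecord(f"gene{i + 1}", 1, "Chr1",
                     i * (config.intron_length + 100),
                     i * (config.intron_length + 100) + config.intron_length, "+")
        for i in range(n)
    ]
    table = IntronCountTable(
        introns=introns, x=x, y=y, n1=config.n1, n2=config.n2, covered_frac=covered
    )
    return table, TruthSet(retained_introns=tuple(planted_idx))
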