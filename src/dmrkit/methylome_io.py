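"""Genome, cytosine-report, annotation and SNP-table I/O.

This module holds the data containers the rest of the package operates on:
a :class:`Genome` (plain nucleotide strings keyed by chromosome), a
:class:`MethylomeTable` (per-cytosine methylated/unmethylated read counts for
one sample, the in-memory form of a Bismark-style cytosine report), and
:class:`FeatureSet` (gene/TE/intron intervals read from BED or GFF3).

All internal coordinates are 0-based half-open.  The 1-based conventions of
cytosine reports and GFF3 are converted at the file boundary.

Sequence context follows the plant convention: a cytosine is CG if followed
by G, CHG if followed by H,G and CHH if followed by H,H where H is A, T or C.
Minus-strand cytosines (G on the forward strand) are read on the reverse
complement.  Symmetric CG sites are kept as two strand-specific records, as
in per-cytosine reports, because the differential test downstream is applied
per cytosine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("dmrkit")

CONTEXTS = ("CG", "CHG", "CHH")
_VALID_BASES = frozenset(b"ACGTN")

_TABLE_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genome:
    """A genome as uppercase nucleotide strings keyed by chromosome name."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome has no chromosomes")
        clean = {}
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            seq = seq.upper()
            bad = set(seq.encode()) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-nucleotide characters: "
                    f"{sorted(chr(b) for b in bad)}"
                )
            clean[name] = seq
        object.__setattr__(self, "sequences", clean)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Cytosine records and context annotation
# ---------------------------------------------------------------------------

class CytosineRecord(NamedTuple):
    chrom: str
    pos: int  # 0-based
    strand: str  # '+' or '-'
    context: str  # CG / CHG / CHH
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


def _context_codes_for_sequence(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (pos, strand_is_plus, context_code) arrays for one chromosome.

    context codes: 0 = CG, 1 = CHG, 2 = CHH.  Cytosines whose context cannot
    be resolved (adjacent N or truncated by the chromosome end) are omitted.
    """
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(a)
    C, G, N = ord("C"), ord("G"), ord("N")

    # plus strand: context read left-to-right from the base after the C
    n1 = np.full(L, N, np.uint8)
    n2 = np.full(L, N, np.uint8)
    if L > 1:
        n1[:-1] = a[1:]
    if L > 2:
        n2[:-2] = a[2:]
    is_c = a == C
    plus_cg = is_c & (n1 == G)
    h1 = is_c & (n1 != G) & (n1 != N)
    plus_chg = h1 & (n2 == G)
    plus_chh = h1 & (n2 != G) & (n2 != N)

    # minus strand: a C on the reverse complement is a G here; its context
    # bases are the preceding forward-strand bases, complemented
    p1 = np.full(L, N, np.uint8)
    p2 = np.full(L, N, np.uint8)
    if L > 1:
        p1[1:] = a[:-1]
    if L > 2:
        p2[2:] = a[:-2]
    is_g = a == G
    minus_cg = is_g & (p1 == C)
    h1m = is_g & (p1 != C) & (p1 != N)
    minus_chg = h1m & (p2 == C)
    minus_chh = h1m & (p2 != C) & (p2 != N)

    pos_parts, plus_parts, code_parts = [], [], []
    for mask, plus, code in (
        (plus_cg, True, 0),
        (plus_chg, True, 1),
        (plus_chh, True, 2),
        (minus_cg, False, 0),
        (minus_chg, False, 1),
        (minus_chh, False, 2),
    ):
        idx = np.nonzero(mask)[0]
        pos_parts.append(idx)
        plus_parts.append(np.full(idx.size, plus, bool))
        code_parts.append(np.full(idx.size, code, np.int8))
    pos = np.concatenate(pos_parts)
    order = np.argsort(pos, kind="stable")
    return (
        pos[order],
        np.concatenate(plus_parts)[order],
        np.concatenate(code_parts)[order],
    )


def context_frame(genome: Genome) -> pd.DataFrame:
    """All resolvable cytosines of a genome as a (chrom, pos, strand, context)
    DataFrame sorted by (chrom, pos)."""
    parts = []
    for chrom, seq in genome.sequences.items():
        pos, plus, code = _context_codes_for_sequence(seq)
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": np.where(plus, "+", "-"),
                    "context": np.asarray(CONTEXTS)[code],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def annotate_contexts(genome: Genome) -> dict[tuple[str, int, str], str]:
    """Map every resolvable cytosine (chrom, pos, strand) to its CG/CHG/CHH
    context.

    Cytosines whose one or two context bases fall off the chromosome end or
    hit an N are skipped: their context is undefined.
    """
    frame = context_frame(genome)
    return {
        (c, int(p), s): ctx
        for c, p, s, ctx in zip(
            frame["chrom"], frame["pos"], frame["strand"], frame["context"]
        )
    }


# ---------------------------------------------------------------------------
# SNPs and pseudo-genome
# ---------------------------------------------------------------------------

class SNPRecord(NamedTuple):
    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str


def read_snp_table(path: str | Path) -> list[SNPRecord]:
    """Read a 4-column SNP TSV (chrom, 1-based pos, ref, alt)."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "ref", "alt"],
        dtype={"chrom": str, "pos": np.int64, "ref": str, "alt": str},
        comment="#",
    )
    return [
        SNPRecord(str(c), int(p) - 1, str(r).upper(), str(a).upper())
        for c, p, r, a in frame.itertuples(index=False)
    ]


def build_pseudo_genome(genome: Genome, snps: Sequence[SNPRecord]) -> Genome:
    """Substitute strain-specific SNP alleles into a reference genome.

    The result is the input genome with each SNP position carrying the
    alternate base; the input is not modified.  A mismatch between the SNP's
    stated reference base and the genome, or two SNPs at the same position,
    is an error.
    """
    seqs = {c: bytearray(s.encode()) for c, s in genome.sequences.items()}
    seen: set[tuple[str, int]] = set()
    for snp in snps:
        if snp.chrom not in seqs:
            raise ValueError(f"SNP on unknown chromosome {snp.chrom!r}")
        if len(snp.ref_base) != 1 or len(snp.alt_base) != 1:
            raise ValueError(f"SNP at {snp.chrom}:{snp.pos} is not a single-base substitution")
        if snp.ref_base == snp.alt_base:
            raise ValueError(f"SNP at {snp.chrom}:{snp.pos} has identical ref and alt")
        seq = seqs[snp.chrom]
        if not 0 <= snp.pos < len(seq):
            raise ValueError(f"SNP position {snp.chrom}:{snp.pos} outside chromosome")
        key = (snp.chrom, snp.pos)
        if key in seen:
            raise ValueError(f"duplicate SNP at {snp.chrom}:{snp.pos}")
        seen.add(key)
        if chr(seq[snp.pos]) != snp.ref_base:
            raise ValueError(
                f"reference mismatch at {snp.chrom}:{snp.pos}: genome has "
                f"{chr(seq[snp.pos])!r}, SNP table says {snp.ref_base!r}"
            )
        seq[snp.pos] = ord(snp.alt_base)
    return Genome({c: bytes(s).decode() for c, s in seqs.items()})


# ---------------------------------------------------------------------------
# MethylomeTable
# ---------------------------------------------------------------------------

@dataclass
class MethylomeTable:
    """Per-cytosine methylated/unmethylated read counts for one sample.

    Backed by a DataFrame with columns chrom, pos (0-based), strand, context,
    n_meth, n_unmeth, sorted by (chrom, pos, strand) with unique keys.
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"methylome table missing columns {missing}")
        frame = self.data[_TABLE_COLUMNS].copy()
        if len(frame):
            if (frame["n_meth"] < 0).any() or (frame["n_unmeth"] < 0).any():
                raise ValueError("negative read counts in methylome table")
            bad_ctx = ~frame["context"].isin(CONTEXTS)
            if bad_ctx.any():
                raise ValueError(
                    f"invalid contexts: {sorted(frame.loc[bad_ctx, 'context'].unique())}"
                )
            if frame.duplicated(["chrom", "pos", "strand"]).any():
                raise ValueError("duplicate (chrom, pos, strand) keys")
        frame = frame.sort_values(["chrom", "pos", "strand"], kind="stable")
        self.data = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[CytosineRecord]:
        for row in self.data.itertuples(index=False):
            yield CytosineRecord(
                row.chrom, int(row.pos), row.strand, row.context,
                int(row.n_meth), int(row.n_unmeth),
            )

    @property
    def coverage(self) -> pd.Series:
        return self.data["n_meth"] + self.data["n_unmeth"]

    def context_subset(self, context: str) -> pd.DataFrame:
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        return self.data[self.data["context"] == context]

    @classmethod
    def from_records(cls, sample_id: str, records: Sequence[CytosineRecord]) -> "MethylomeTable":
        frame = pd.DataFrame(records, columns=CytosineRecord._fields)
        return cls(sample_id, frame)


def read_cytosine_table(
    path: str | Path,
    genome: Genome | None = None,
    sample_id: str | None = None,
    strict_context: bool = False,
) -> MethylomeTable:
    """Read a Bismark-style cytosine report.

    File columns (tab-separated, no header): chrom, 1-based position, strand,
    methylated count, unmethylated count, context, trinucleotide.  Positions
    are converted to 0-based internally.  When a genome is supplied, the file
    contexts are cross-checked against :func:`annotate_contexts`; mismatches
    are logged (or raised when ``strict_context``).
    """
    path = Path(path)
    names = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"]
    try:
        frame = pd.read_csv(
            path, sep="\t", header=None, names=names, comment="#",
            dtype={"chrom": str, "strand": str, "context": str, "tri": str},
        )
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=names)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed cytosine report {path}: {exc}") from exc

    if len(frame):
        for col in ("pos", "n_meth", "n_unmeth"):
            numeric = pd.to_numeric(frame[col], errors="coerce")
            bad = numeric.isna()
            if bad.any():
                line = int(np.nonzero(bad.to_numpy())[0][0]) + 1
                raise ValueError(f"{path}: malformed {col!r} field at line {line}")
            frame[col] = numeric.astype(np.int64)
        neg = (frame["n_meth"] < 0) | (frame["n_unmeth"] < 0)
        if neg.any():
            line = int(np.nonzero(neg.to_numpy())[0][0]) + 1
            raise ValueError(f"{path}: negative count at line {line}")
        bad_strand = ~frame["strand"].isin(["+", "-"])
        if bad_strand.any():
            line = int(np.nonzero(bad_strand.to_numpy())[0][0]) + 1
            raise ValueError(f"{path}: invalid strand at line {line}")
        frame["pos"] = frame["pos"] - 1  # to 0-based

    table = MethylomeTable(sample_id or path.stem, frame.drop(columns=["tri"]))

    if genome is not None and len(table):
        ref = context_frame(genome)
        merged = table.data.merge(
            ref, on=["chrom", "pos", "strand"], how="left", suffixes=("", "_ref")
        )
        mismatch = merged["context_ref"].notna() & (
            merged["context"] != merged["context_ref"]
        )
        if mismatch.any():
            n = int(mismatch.sum())
            examples = merged.loc[mismatch, ["chrom", "pos", "context", "context_ref"]].head(5)
            msg = (
                f"{path}: {n} context mismatches against the genome, e.g.\n"
                f"{examples.to_string(index=False)}"
            )
            if strict_context:
                raise ValueError(msg)
            log.warning(msg)
    return table


def write_cytosine_table(
    table: MethylomeTable, path: str | Path, genome: Genome | None = None
) -> None:
    """Write a table in the cytosine-report dialect read back by
    :func:`read_cytosine_table` (1-based positions).

    The trinucleotide column is taken from the genome when given, else a
    placeholder derived from the context.
    """
    frame = table.data.copy()
    if genome is not None:
        tris = []
        for row in frame.itertuples(index=False):
            seq = genome[row.chrom]
            if row.strand == "+":
                tri = seq[row.pos : row.pos + 3]
            else:
                tri = str(Seq(seq[max(row.pos - 2, 0) : row.pos + 1]).reverse_complement())
            tris.append(tri.ljust(3, "N"))
        frame["tri"] = tris
    else:
        frame["tri"] = frame["context"].map({"CG": "CGN", "CHG": "CNG", "CHH": "CNN"})
    frame["pos"] = frame["pos"] + 1
    frame[["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

FEATURE_KINDS = ("gene", "TE", "intron", "other")

_GFF_KIND_MAP = {
    "gene": "gene",
    "mrna": "gene",
    "protein_coding_gene": "gene",
    "transposable_element": "TE",
    "transposable_element_gene": "TE",
    "transposon_fragment": "TE",
    "te": "TE",
    "intron": "intron",
}


class GenomicFeature(NamedTuple):
    feature_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    kind: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FeatureSet:
    """A homogeneous or mixed collection of genomic intervals."""

    features: tuple[GenomicFeature, ...]
    kind: str = "mixed"

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature_ids in FeatureSet")
        for f in self.features:
            if f.start >= f.end:
                raise ValueError(f"feature {f.feature_id}: start >= end")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GenomicFeature]:
        return iter(self.features)

    def of_kind(self, kind: str) -> "FeatureSet":
        return FeatureSet(
            tuple(f for f in self.features if f.kind == kind), kind=kind
        )


def read_features(path: str | Path, kind: str | None = None) -> FeatureSet:
    """Read gene/TE/intron intervals from BED (0-based half-open, native) or
    GFF3 (1-based closed, converted).

    For GFF3 the feature kind is mapped from the type column (gene-like types
    to "gene", transposable-element types to "TE"); ``kind`` then filters.
    BED carries no type column, so ``kind`` labels all records.
    """
    import pyranges as pr

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        df = pr.read_bed(str(path)).df
        label = kind or "other"
        feats = []
        for i, row in enumerate(df.itertuples(index=False)):
            name = getattr(row, "Name", None) or f"feature_{i}"
            strand = getattr(row, "Strand", "+")
            if strand not in ("+", "-"):
                strand = "+"
            feats.append(
                GenomicFeature(str(name), str(row.Chromosome), int(row.Start),
                               int(row.End), strand, label)
            )
        return FeatureSet(tuple(feats), kind=label)
    if suffix in (".gff", ".gff3"):
        df = pr.read_gff3(str(path)).df
        feats = []
        for i, row in enumerate(df.itertuples(index=False)):
            mapped = _GFF_KIND_MAP.get(str(row.Feature).lower(), "other")
            if kind is not None and mapped != kind:
                continue
            name = getattr(row, "ID", None)
            if name is None or (isinstance(name, float) and np.isnan(name)):
                name = f"{row.Feature}_{i}"
            strand = row.Strand if row.Strand in ("+", "-") else "+"
            if int(row.Start) >= int(row.End):
                raise ValueError(f"{path}: feature {name} has start >= end after conversion")
            feats.append(
                GenomicFeature(str(name), str(row.Chromosome), int(row.Start),
                               int(row.End), strand, mapped)
            )
        return FeatureSet(tuple(feats), kind=kind or "mixed")
    raise ValueError(f"unknown annotation format {suffix!r} (expected .bed/.gff/.gff3)")


def write_features_bed(features: FeatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t.\t{f.strand}\n")
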