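"""Genome coordinate system, window grids, and gene annotation.

All coordinates are 0-based, half-open (BED convention). Fixed window
grids drop partial terminal windows so every window has constant width;
TSS-anchored windows are instead clipped at chromosome boundaries and
normalized by their actual width downstream, so promoter-proximal genes
near chromosome ends are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


class ChromTable:
    """Ordered chromosome-name -> length (bp) table.

    Names must be unique and lengths strictly positive.
    """

    def __init__(self, entries) -> None:
        entries = [(str(c), int(n)) for c, n in entries]
        names = [c for c, _ in entries]
        if len(set(names)) != len(names):
            dupes = sorted({c for c in names if names.count(c) > 1})
            raise ValueError(f"duplicate chromosome name(s): {', '.join(dupes)}")
        for c, n in entries:
            if n <= 0:
                raise ValueError(f"non-positive length for {c}: {n}")
        self._lengths: dict[str, int] = dict(entries)

    @property
    def chroms(self) -> list[str]:
        return list(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromTable) and self._lengths == other._lengths

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def items(self):
        return self._lengths.items()

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for c, n in self._lengths.items():
                fh.write(f"{c}\t{n}\n")


def load_chrom_table(path) -> ChromTable:
    """Load a two-column tab-separated chrom.sizes file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    return ChromTable(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))


@dataclass
class WindowGrid:
    """Fixed-width window grid over a genome.

    Windows start at multiples of ``step`` per chromosome; a window whose
    end would exceed the chromosome length is dropped. ``step < width``
    produces overlapping windows (e.g. 2 kb windows at 1 kb intervals).
    """

    width: int
    step: int
    chrom_table: ChromTable
    starts: dict[str, np.ndarray] = field(repr=False)

    @property
    def n_windows(self) -> int:
        return sum(len(s) for s in self.starts.values())

    def chrom_slices(self) -> dict[str, slice]:
        """Slices of each chromosome's windows in the flattened layout."""
        out, offset = {}, 0
        for chrom in self.chrom_table.chroms:
            n = len(self.starts.get(chrom, ()))
            out[chrom] = slice(offset, offset + n)
            offset += n
        return out

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for chrom in self.chrom_table.chroms:
            s = self.starts.get(chrom)
            if s is None or len(s) == 0:
                continue
            frames.append(
                pd.DataFrame({"chrom": chrom, "start": s, "end": s + self.width})
            )
        if not frames:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(frames, ignore_index=True)

    def to_bed(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)

    def same_layout(self, other: "WindowGrid") -> bool:
        if (self.width, self.step) != (other.width, other.step):
            return False
        if self.chrom_table.chroms != other.chrom_table.chroms:
            return False
        return all(
            np.array_equal(self.starts[c], other.starts[c])
            for c in self.starts
        )


def tile_genome(chroms: ChromTable, width: int, step: int) -> WindowGrid:
    """Tile every chromosome with fixed windows of ``width`` every ``step`` bp.

    ``step > width`` (gapped grids) is rejected; ``step < width`` yields
    overlapping windows with overlap fraction (width − step)/width.
    """
    if width <= 0:
        raise ValueError(f"width must be > 0, got {width}")
    if step <= 0 or step > width:
        raise ValueError(f"require 0 < step <= width, got step={step} width={width}")
    starts = {}
    for chrom, length in chroms.items():
        if length >= width:
            n = (length - width) // step + 1
            starts[chrom] = np.arange(n, dtype=np.int64) * step
        else:
            starts[chrom] = np.empty(0, dtype=np.int64)
    return WindowGrid(width=width, step=step, chrom_table=chroms, starts=starts)


def load_bed_intervals(path) -> pd.DataFrame:
    """Read a BED3+ file into a (chrom, start, end) frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df.astype({"chrom": str, "start": np.int64, "end": np.int64})


@dataclass(frozen=True)
class GeneAnnotation:
    """One TSS-anchored gene model.

    ``tss``/``tes`` are point coordinates; for a minus-strand gene the TSS
    is the rightmost base, so tss >= tes.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: + strand requires tss <= tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: - strand requires tss >= tes")


def tss_window(gene: GeneAnnotation, flank: int, chroms: ChromTable) -> GenomicInterval:
    """Symmetric window [tss − flank, tss + flank), clipped to the chromosome.

    The window is strand-agnostic: a symmetric window around a point is
    the same interval on either strand.
    """
    if flank <= 0:
        raise ValueError(f"flank must be > 0, got {flank}")
    if gene.chrom not in chroms:
        raise KeyError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom!r}")
    length = chroms.length(gene.chrom)
    start = max(0, gene.tss - flank)
    end = min(length, gene.tss + flank)
    return GenomicInterval(gene.chrom, start, end)


def load_gene_bed(path) -> list[GeneAnnotation]:
    """Load gene models from BED6 (chrom, start, end, gene_id, score, strand).

    TSS is the interval start for + genes and end − 1 for − genes; TES is
    the opposite extremity. Gene ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED6 with name and strand columns required")
    genes = []
    seen = set()
    for row in df.itertuples(index=False):
        chrom, start, end, gene_id, _score, strand = (
            str(row[0]), int(row[1]), int(row[2]), str(row[3]), row[4], str(row[5]),
        )
        if strand not in STRANDS:
            raise ValueError(f"{path}: gene {gene_id}: invalid strand {strand!r}")
        if gene_id in seen:
            raise ValueError(f"{path}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        if strand == "+":
            tss, tes = start, end - 1
        else:
            tss, tes = end - 1, start
        genes.append(GeneAnnotation(gene_id, chrom, strand, tss, tes))
    return genes


def write_gene_bed(genes: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = (g.tss, g.tes + 1) if g.strand == "+" else (g.tes, g.tss + 1)
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


@dataclass
class GeneSet:
    """A named collection of gene ids (e.g. SKM, HK, CBL)."""

    name: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"gene set {self.name}: duplicate gene ids")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def resolve(self, annotation: list[GeneAnnotation]) -> list[str]:
        """Return member ids present in the annotation; log and skip the rest."""
        known = {g.gene_id for g in annotation}
        missing = [g for g in self.gene_ids if g not in known]
        if missing:
            logger.warning(
                "gene set %s: %d id(s) not in annotation, skipped: %s",
                self.name, len(missing), ", ".join(missing[:5]),
            )
        return [g for g in self.gene_ids if g in known]
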