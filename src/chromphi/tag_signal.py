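"""Tag loading, window counting, RPKM, signal intensity, and tracks.

The counting unit is the "tag": a uniquely aligned read reduced to its
(chrom, 5' position, strand) triple. All densities are RPKM, normalized
per sample by its total unique-tag count, and the signal intensity of a
window is

    SI = RPKM(IP) - RPKM(input)

i.e. input-subtracted tag density, which can be negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chromphi.genome_model import (
    ChromTable,
    GenomicInterval,
    WindowGrid,
    tile_genome,
)

logger = logging.getLogger(__name__)

INPUT_MARK = "input"


@dataclass
class TagSet:
    """Aligned tags for one sample, stored per chromosome, sorted by position.

    ``strands`` holds 0 for '+' and 1 for '-', aligned with ``positions``.
    ``n_unique`` equals the number of stored tags (after deduplication
    when the set was loaded or built with dedup on).
    """

    sample_id: str
    mark: str
    chrom_table: ChromTable
    positions: dict[str, np.ndarray] = field(repr=False)
    strands: dict[str, np.ndarray] = field(repr=False)
    n_unique: int = 0

    @classmethod
    def from_arrays(cls, sample_id, mark, chrom_table, chrom_pos_strand, dedup=True):
        """Build from {chrom: (pos array, strand array)} with optional dedup.

        Tags are sorted by (position, strand) per chromosome; duplicates in
        (chrom, pos, strand) collapse to one when ``dedup``.
        """
        positions, strands, n = {}, {}, 0
        for chrom in chrom_table.chroms:
            if chrom not in chrom_pos_strand:
                positions[chrom] = np.empty(0, dtype=np.int64)
                strands[chrom] = np.empty(0, dtype=np.int8)
                continue
            pos, strand = chrom_pos_strand[chrom]
            pos = np.asarray(pos, dtype=np.int64)
            strand = np.asarray(strand, dtype=np.int8)
            key = pos * 2 + strand  # positions are non-negative, key is unique per (pos, strand)
            key = np.unique(key) if dedup else np.sort(key)
            positions[chrom] = key >> 1
            strands[chrom] = (key & 1).astype(np.int8)
            n += len(key)
        return cls(sample_id, mark, chrom_table, positions, strands, n)

    def pos(self, chrom: str) -> np.ndarray:
        return self.positions.get(chrom, np.empty(0, dtype=np.int64))

    def to_bed_frame(self) -> pd.DataFrame:
        frames = []
        for chrom in self.chrom_table.chroms:
            p = self.positions[chrom]
            if len(p) == 0:
                continue
            s = np.where(self.strands[chrom] == 0, "+", "-")
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": p, "end": p + 1,
                     "name": ".", "score": 0, "strand": s}
                )
            )
        if not frames:
            return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
        return pd.concat(frames, ignore_index=True)

    def to_bed(self, path) -> None:
        self.to_bed_frame().to_csv(path, sep="\t", header=False, index=False)


def load_tags(path, chroms: ChromTable, dedup: bool = True,
              sample_id: str | None = None, mark: str = "") -> TagSet:
    """Load tags from a BED file (BED6, or BED3 with strand defaulting to +).

    A tag's 5' position is the interval start on the + strand and end − 1
    on the − strand. Rows on chromosomes absent from ``chroms`` are
    rejected with their row number.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty tag file", path)
        return TagSet.from_arrays(sample_id or str(path), mark, chroms, {}, dedup)
    chrom_col = df.iloc[:, 0].astype(str)
    known = chrom_col.isin(set(chroms.chroms))
    if not known.all():
        row = int(np.flatnonzero(~known.to_numpy())[0])
        raise ValueError(
            f"{path}: row {row + 1}: unknown chromosome {chrom_col.iloc[row]!r}"
        )
    start = df.iloc[:, 1].astype(np.int64)
    end = df.iloc[:, 2].astype(np.int64)
    if df.shape[1] >= 6:
        strand_col = df.iloc[:, 5].astype(str)
        bad = ~strand_col.isin(["+", "-"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: row {row + 1}: invalid strand {strand_col.iloc[row]!r}")
        strand = (strand_col == "-").to_numpy().astype(np.int8)
    else:
        strand = np.zeros(len(df), dtype=np.int8)
    pos5 = np.where(strand == 0, start.to_numpy(), end.to_numpy() - 1)
    per_chrom = {}
    for chrom, idx in pd.Series(np.arange(len(df))).groupby(chrom_col).groups.items():
        idx = np.asarray(idx)
        per_chrom[str(chrom)] = (pos5[idx], strand[idx])
    tags = TagSet.from_arrays(sample_id or str(path), mark, chroms, per_chrom, dedup)
    if tags.n_unique == 0:
        logger.warning("%s: no tags loaded", path)
    return tags


@dataclass
class SignalTrack:
    """Per-window values (RPKM or SI) on a window grid for one sample."""

    grid: WindowGrid
    mark: str
    sample_id: str
    values: np.ndarray
    kind: str  # "rpkm" | "si"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_windows:
            raise ValueError(
                f"track length {len(self.values)} != grid windows {self.grid.n_windows}"
            )
        if self.kind == "rpkm" and (self.values < 0).any():
            raise ValueError("rpkm values must be >= 0")

    def to_bedgraph(self, path) -> None:
        df = self.grid.to_frame()
        df["value"] = self.values
        df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


@dataclass
class SamplePair:
    """An IP sample and its matched input control on the same genome."""

    ip: TagSet
    input: TagSet

    def __post_init__(self) -> None:
        if self.ip.chrom_table != self.input.chrom_table:
            raise ValueError("IP and input must share a chromosome table")
        if self.input.mark != INPUT_MARK:
            raise ValueError(f"control sample must have mark {INPUT_MARK!r}")
        if self.ip.mark == INPUT_MARK:
            raise ValueError("IP sample may not be an input")


def count_in_windows(tags: TagSet, grid: WindowGrid) -> np.ndarray:
    """Tags per window (a tag counts in every window containing its pos5)."""
    if tags.chrom_table != grid.chrom_table:
        raise ValueError("tags and grid must share a chromosome table")
    out = []
    for chrom in grid.chrom_table.chroms:
        starts = grid.starts.get(chrom)
        if starts is None or len(starts) == 0:
            continue
        pos = tags.pos(chrom)  # sorted ascending
        out.append(
            np.searchsorted(pos, starts + grid.width, side="left")
            - np.searchsorted(pos, starts, side="left")
        )
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(out).astype(np.int64)


def count_in_interval(tags: TagSet, region: GenomicInterval) -> int:
    pos = tags.pos(region.chrom)
    return int(
        np.searchsorted(pos, region.end, side="left")
        - np.searchsorted(pos, region.start, side="left")
    )


def rpkm(counts, window_widths, n_total: int) -> np.ndarray:
    """Reads per kb per million: count / ((width/1e3) * (n_total/1e6))."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0 (empty library)")
    counts = np.asarray(counts, dtype=float)
    widths = np.asarray(window_widths, dtype=float)
    return counts / ((widths / 1e3) * (n_total / 1e6))


def signal_intensity(pair: SamplePair, grid: WindowGrid) -> SignalTrack:
    """Per-window SI = RPKM(IP) − RPKM(input), each sample self-normalized."""
    if pair.ip.n_unique == 0 or pair.input.n_unique == 0:
        raise ValueError("both IP and input must contain tags")
    widths = np.full(grid.n_windows, grid.width)
    si = rpkm(count_in_windows(pair.ip, grid), widths, pair.ip.n_unique) - rpkm(
        count_in_windows(pair.input, grid), widths, pair.input.n_unique
    )
    return SignalTrack(grid, pair.ip.mark, pair.ip.sample_id, si, "si")


def region_si(pair: SamplePair, region: GenomicInterval) -> float:
    """SI over a single region, normalized by its actual (possibly clipped) width."""
    if pair.ip.n_unique == 0 or pair.input.n_unique == 0:
        raise ValueError("both IP and input must contain tags")
    w = region.width
    ip = rpkm([count_in_interval(pair.ip, region)], [w], pair.ip.n_unique)[0]
    ctrl = rpkm([count_in_interval(pair.input, region)], [w], pair.input.n_unique)[0]
    return float(ip - ctrl)


def sliding_track(pair: SamplePair, chroms: ChromTable,
                  width: int = 2000, step: int = 1000) -> SignalTrack:
    """Genome-wide SI track on overlapping windows (default 2 kb / 1 kb),
    ready for bedGraph export."""
    grid = tile_genome(chroms, width, step)
    return signal_intensity(pair, grid)


def replicate_correlation(tracks: list[SignalTrack]):
    """Pairwise Pearson correlation of replicate tracks on one grid.

    Returns (correlation matrix as a DataFrame indexed by sample id,
    mean of the upper-triangle entries). Constant tracks are rejected
    (their correlation is undefined).
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    ref = tracks[0].grid
    for t in tracks[1:]:
        if not t.grid.same_layout(ref):
            raise ValueError("all tracks must share one window grid")
    mat = np.vstack([t.values for t in tracks])
    if (mat.std(axis=1) == 0).any():
        raise ValueError("constant track: correlation undefined")
    corr = np.corrcoef(mat)
    ids = [t.sample_id for t in tracks]
    df = pd.DataFrame(corr, index=ids, columns=ids)
    iu = np.triu_indices(len(tracks), k=1)
    return df, float(corr[iu].mean())
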