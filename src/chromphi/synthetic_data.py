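"""Synthetic multi-mark ChIP-seq study generator with known gene classes.

Emulates the statistical structure of promoter chromatin around four
gene classes:

- ``active``   — strong H3K4me3, background H3K27me3, high H3.3;
- ``poised``   — balanced H3K4me3/H3K27me3 (bivalent), high H3.3;
- ``repressed``— strong H3K27me3, background H3K4me3, background H3.3;
- ``silent``   — background everything.

Genes are placed on a regular lattice with jitter over a toy genome.
Each sample draws tag counts per 200 bp cell from independent Poisson
distributions whose mean is a uniform background rate multiplied by the
(mark, class) enrichment fold inside TSS +/- flank, rescaled so the
total expected tag count equals the configured depth; tag positions are
uniform within their cell and strands are assigned uniformly. Everything
is reproducible from the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from chromphi.genome_model import (
    ChromTable,
    GeneAnnotation,
    load_chrom_table,
    load_gene_bed,
    write_gene_bed,
)
from chromphi.tag_signal import INPUT_MARK, SamplePair, TagSet, load_tags

CLASSES = ("active", "poised", "repressed", "silent")
PHI_REGIME = {"active": "low", "poised": "mid", "repressed": "high", "silent": "none"}

DEFAULT_FOLDS = {
    "H3K4me3": {"active": 8.0, "poised": 4.0, "repressed": 1.0, "silent": 1.0},
    "H3K27me3": {"active": 1.0, "poised": 4.0, "repressed": 8.0, "silent": 1.0},
    "H3.3": {"active": 6.0, "poised": 6.0, "repressed": 1.0, "silent": 1.0},
}

MIN_GENE_SPACING = 10_000


def _default_counts() -> dict:
    return {c: 50 for c in CLASSES}


@dataclass
class SimulationConfig:
    """Parameters of a simulated study (defaults run in well under a minute)."""

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 5_000_000
    n_genes_per_class: dict = field(default_factory=_default_counts)
    lambda_bg: float = 0.2       # expected input tags per bp before depth rescaling
    depth: int = 2_000_000       # expected total tags per sample
    folds: dict = field(default_factory=lambda: {m: dict(d) for m, d in DEFAULT_FOLDS.items()})
    n_replicates: int = 3
    flank: int = 2_000           # promoter enrichment half-width, matches analysis flank
    cell: int = 200              # Poisson sampling cell, mono-nucleosome scale
    gene_length: int = 5_000
    per_replicate_input: bool = False
    dedup: bool = True               # collapse (chrom, pos5, strand) collisions

    def validate(self) -> None:
        if self.n_chrom < 1 or self.chrom_len <= 0:
            raise ValueError("need n_chrom >= 1 and chrom_len > 0")
        if self.chrom_len % self.cell != 0:
            raise ValueError(f"chrom_len must be a multiple of cell ({self.cell} bp)")
        if self.flank % self.cell != 0:
            raise ValueError("flank must be a multiple of the sampling cell")
        if self.depth <= 0 or self.lambda_bg <= 0:
            raise ValueError("depth and lambda_bg must be positive")
        if self.n_replicates < 1:
            raise ValueError("need n_replicates >= 1")
        for mark, per_class in self.folds.items():
            for cls, f in per_class.items():
                if cls not in CLASSES:
                    raise ValueError(f"unknown gene class {cls!r}")
                if f < 0:
                    raise ValueError(f"negative fold for ({mark}, {cls})")
        n_total = sum(int(n) for n in self.n_genes_per_class.values())
        if n_total < 1:
            raise ValueError("need at least one gene")
        per_chrom = -(-n_total // self.n_chrom)  # ceil
        spacing = self.chrom_len // (per_chrom + 1)
        if spacing < MIN_GENE_SPACING:
            need = (per_chrom + 1) * MIN_GENE_SPACING
            raise ValueError(
                f"genome too small for {n_total} genes without promoter overlap: "
                f"need chrom_len >= {need} bp (spacing >= {MIN_GENE_SPACING})"
            )

    @property
    def marks(self) -> list[str]:
        return list(self.folds)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimulatedStudy:
    """A complete in-memory study: genome, genes, tag sets, and ground truth."""

    chrom_table: ChromTable
    genes: list[GeneAnnotation]
    truth: pd.DataFrame            # gene_id, gene_class, expected_phi_regime
    tagsets: dict                  # (mark, replicate 1-based) -> TagSet
    inputs: dict                   # replicate -> TagSet (shared object unless per-replicate)
    raw_counts: dict               # sample_id -> tag count before deduplication
    config: SimulationConfig

    def pair(self, mark: str, replicate: int) -> SamplePair:
        return SamplePair(ip=self.tagsets[(mark, replicate)], input=self.inputs[replicate])

    @property
    def gene_classes(self) -> dict:
        return dict(zip(self.truth["gene_id"], self.truth["gene_class"]))


def _place_genes(config: SimulationConfig, rng: np.random.Generator,
                 chrom_table: ChromTable):
    n_total = sum(int(n) for n in config.n_genes_per_class.values())
    chroms = chrom_table.chroms
    per_chrom = -(-n_total // len(chroms))
    spacing = config.chrom_len // (per_chrom + 1)
    jitter_cells = config.flank // config.cell

    labels = np.concatenate(
        [np.repeat(c, int(config.n_genes_per_class.get(c, 0))) for c in CLASSES]
    )
    labels = rng.permutation(labels)

    genes, rows = [], []
    i = 0
    for chrom in chroms:
        for slot in range(per_chrom):
            if i >= n_total:
                break
            base = ((slot + 1) * spacing // config.cell) * config.cell
            tss = base + int(rng.integers(-jitter_cells, jitter_cells + 1)) * config.cell
            tss = min(max(tss, config.flank), config.chrom_len - config.flank)
            strand = "+" if rng.integers(2) == 0 else "-"
            if strand == "+":
                tes = min(tss + config.gene_length - 1, config.chrom_len - 1)
            else:
                tes = max(tss - config.gene_length + 1, 0)
            gid = f"g{i + 1:04d}"
            genes.append(GeneAnnotation(gid, chrom, strand, tss, tes))
            rows.append({"gene_id": gid, "gene_class": str(labels[i]),
                         "expected_phi_regime": PHI_REGIME[str(labels[i])]})
            i += 1
    truth = pd.DataFrame(rows)
    return genes, truth


def _fold_cells(config: SimulationConfig, chrom_table: ChromTable,
                genes: list[GeneAnnotation], gene_class: dict,
                per_class_fold: dict) -> dict:
    """Per-chromosome array of the enrichment fold of each sampling cell."""
    n_cells = config.chrom_len // config.cell
    folds = {c: np.ones(n_cells) for c in chrom_table.chroms}
    for g in genes:
        f = float(per_class_fold.get(gene_class[g.gene_id], 1.0))
        lo = max(0, (g.tss - config.flank)) // config.cell
        hi = min(config.chrom_len, g.tss + config.flank) // config.cell
        folds[g.chrom][lo:hi] = f
    return folds


def _sample_tags(config: SimulationConfig, chrom_table: ChromTable,
                 fold_cells: dict, sample_id: str, mark: str,
                 seed_seq: np.random.SeedSequence):
    rng = np.random.default_rng(seed_seq)
    cell = config.cell
    rates = {c: config.lambda_bg * cell * fold_cells[c] for c in chrom_table.chroms}
    total = sum(r.sum() for r in rates.values())
    scale = config.depth / total
    per_chrom, raw = {}, 0
    for chrom in chrom_table.chroms:
        counts = rng.poisson(rates[chrom] * scale)
        n = int(counts.sum())
        raw += n
        starts = np.repeat(np.arange(len(counts), dtype=np.int64) * cell, counts)
        pos = starts + rng.integers(0, cell, size=n)
        strand = rng.integers(0, 2, size=n).astype(np.int8)
        per_chrom[chrom] = (pos, strand)
    tags = TagSet.from_arrays(sample_id, mark, chrom_table, per_chrom,
                              dedup=config.dedup)
    return tags, raw


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full multi-mark study from a :class:`SimulationConfig`."""
    config.validate()
    chrom_table = ChromTable(
        (f"chr{i + 1}", config.chrom_len) for i in range(config.n_chrom)
    )
    root = np.random.SeedSequence(config.seed)
    n_inputs = config.n_replicates if config.per_replicate_input else 1
    streams = root.spawn(1 + n_inputs + len(config.marks) * config.n_replicates)

    genes, truth = _place_genes(config, np.random.default_rng(streams[0]), chrom_table)
    gene_class = dict(zip(truth["gene_id"], truth["gene_class"]))

    flat = {c: np.ones(config.chrom_len // config.cell) for c in chrom_table.chroms}
    raw_counts, inputs = {}, {}
    k = 1
    if config.per_replicate_input:
        for rep in range(1, config.n_replicates + 1):
            sid = f"input_rep{rep}"
            tags, raw = _sample_tags(config, chrom_table, flat, sid, INPUT_MARK, streams[k])
            inputs[rep] = tags
            raw_counts[sid] = raw
            k += 1
    else:
        tags, raw = _sample_tags(config, chrom_table, flat, "input", INPUT_MARK, streams[k])
        raw_counts["input"] = raw
        inputs = {rep: tags for rep in range(1, config.n_replicates + 1)}
        k += 1

    tagsets = {}
    for mark in config.marks:
        cells = _fold_cells(config, chrom_table, genes, gene_class, config.folds[mark])
        for rep in range(1, config.n_replicates + 1):
            sid = f"{mark}_rep{rep}"
            tags, raw = _sample_tags(config, chrom_table, cells, sid, mark, streams[k])
            tagsets[(mark, rep)] = tags
            raw_counts[sid] = raw
            k += 1

    return SimulatedStudy(chrom_table, genes, truth, tagsets, inputs, raw_counts, config)


def write_study(study: SimulatedStudy, outdir, overwrite: bool = False) -> None:
    """Persist a study as the plain-text formats the analysis consumes.

    Emits chrom.sizes, genes.bed (BED6), tags_<mark>_rep<k>.bed (BED6),
    input tag file(s), truth.tsv, and a config.yaml echo. Refuses to
    write into an existing non-empty directory unless ``overwrite``.
    """
    os.makedirs(outdir, exist_ok=True)
    if os.listdir(outdir) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty (pass overwrite=True)")
    study.chrom_table.to_file(os.path.join(outdir, "chrom.sizes"))
    write_gene_bed(study.genes, os.path.join(outdir, "genes.bed"))
    study.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    study.config.to_yaml(os.path.join(outdir, "config.yaml"))
    for (mark, rep), tags in study.tagsets.items():
        tags.to_bed(os.path.join(outdir, f"tags_{mark}_rep{rep}.bed"))
    if study.config.per_replicate_input:
        for rep, tags in study.inputs.items():
            tags.to_bed(os.path.join(outdir, f"tags_input_rep{rep}.bed"))
    else:
        study.inputs[1].to_bed(os.path.join(outdir, "tags_input.bed"))


def load_study(indir) -> SimulatedStudy:
    """Reload a study written by :func:`write_study` through the standard loaders."""
    config = SimulationConfig.from_yaml(os.path.join(indir, "config.yaml"))
    chrom_table = load_chrom_table(os.path.join(indir, "chrom.sizes"))
    genes = load_gene_bed(os.path.join(indir, "genes.bed"))
    truth = pd.read_csv(os.path.join(indir, "truth.tsv"), sep="\t")
    tagsets = {}
    for mark in config.marks:
        for rep in range(1, config.n_replicates + 1):
            path = os.path.join(indir, f"tags_{mark}_rep{rep}.bed")
            tagsets[(mark, rep)] = load_tags(path, chrom_table, dedup=config.dedup,
                                             sample_id=f"{mark}_rep{rep}", mark=mark)
    if config.per_replicate_input:
        inputs = {
            rep: load_tags(os.path.join(indir, f"tags_input_rep{rep}.bed"), chrom_table,
                           dedup=config.dedup, sample_id=f"input_rep{rep}", mark=INPUT_MARK)
            for rep in range(1, config.n_replicates + 1)
        }
    else:
        shared = load_tags(os.path.join(indir, "tags_input.bed"), chrom_table,
                           dedup=config.dedup, sample_id="input", mark=INPUT_MARK)
        inputs = {rep: shared for rep in range(1, config.n_replicates + 1)}
    return SimulatedStudy(chrom_table, genes, truth, tagsets, inputs, {}, config)
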