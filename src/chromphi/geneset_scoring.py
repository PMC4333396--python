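"""Promoter-level SI aggregation, Z-scores, and tissue-specific gene selection.

The per-gene Z-score measures how far a gene's promoter SI sits from the
all-gene mean in units of the population standard deviation of all
genes. The gene-set Z-score compares a set's mean to the all-gene mean
in units of the standard error sd_all/sqrt(n) (default), or the set's
own SEM in ``mode="set_sem"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromphi.genome_model import GeneAnnotation, GeneSet, GenomicInterval, tss_window
from chromphi.tag_signal import SamplePair, SignalTrack, region_si
from chromphi.genome_model import ChromTable, WindowGrid

logger = logging.getLogger(__name__)


def promoter_si_table(pair: SamplePair, genes: list[GeneAnnotation],
                      flank: int = 2000) -> pd.DataFrame:
    """Per-gene SI at TSS ± flank; frame with columns (gene_id, si_tss).

    Genes on chromosomes absent from the sample's genome are skipped with
    a log entry, not fatal.
    """
    if not genes:
        raise ValueError("gene list is empty")
    chroms = pair.ip.chrom_table
    ids, sis = [], []
    for g in genes:
        if g.chrom not in chroms:
            logger.warning("gene %s on unknown chromosome %s: skipped", g.gene_id, g.chrom)
            continue
        ids.append(g.gene_id)
        sis.append(region_si(pair, tss_window(g, flank, chroms)))
    return pd.DataFrame({"gene_id": ids, "si_tss": sis})


def per_gene_z(scores) -> np.ndarray:
    """Standard score of each gene against the all-gene background.

    Uses the population SD (divide by N). Rejects degenerate inputs
    (fewer than 2 genes, or zero spread).
    """
    x = np.asarray(scores, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 genes")
    sd = x.std()  # population SD
    if sd == 0:
        raise ValueError("zero global SD: Z-scores undefined")
    return (x - x.mean()) / sd


@dataclass
class GeneSetZ:
    """Gene-set Z: set-mean departure from the all-gene mean in SE units."""

    set_name: str
    mark: str
    n: int
    z_set: float


def geneset_z(scores: pd.Series, gene_set: GeneSet, mark: str = "",
              mode: str = "global_se") -> GeneSetZ:
    """Z of a gene set's mean SI against the all-gene background.

    ``scores`` is the full gene universe indexed by gene_id. Default
    standard error is sd_all/sqrt(n); ``mode="set_sem"`` uses the set's
    own standard error of the mean instead.
    """
    if mode not in ("global_se", "set_sem"):
        raise ValueError(f"unknown mode {mode!r}")
    members = [g for g in gene_set.gene_ids if g in scores.index]
    skipped = len(gene_set.gene_ids) - len(members)
    if skipped:
        logger.warning("gene set %s: %d member(s) without scores, skipped",
                       gene_set.name, skipped)
    n = len(members)
    if n < 2:
        raise ValueError(f"gene set {gene_set.name}: need >= 2 scored members, got {n}")
    x = scores.to_numpy(dtype=float)
    sd_all = x.std()
    if sd_all == 0:
        raise ValueError("zero global SD: gene-set Z undefined")
    set_vals = scores.loc[members].to_numpy(dtype=float)
    diff = set_vals.mean() - x.mean()
    if mode == "global_se":
        se = sd_all / np.sqrt(n)
    else:
        se = set_vals.std(ddof=1) / np.sqrt(n)
        if se == 0:
            raise ValueError(f"gene set {gene_set.name}: zero within-set spread")
    return GeneSetZ(gene_set.name, mark, n, float(diff / se))


def gene_body_profile(pair: SamplePair, gene: GeneAnnotation,
                      width: int = 200) -> np.ndarray:
    """SI in consecutive fixed windows across the gene body, 5'→3'.

    Windows run from the gene's leftmost to rightmost coordinate; a
    partial terminal window is dropped unless the gene is shorter than
    one window, in which case a single clipped window is used. The
    profile is reversed for − strand genes so index 0 is always the TSS
    end.
    """
    left, right = min(gene.tss, gene.tes), max(gene.tss, gene.tes) + 1
    length = right - left
    if length < width:
        vals = np.array([region_si(pair, GenomicInterval(gene.chrom, left, right))])
    else:
        n = length // width
        vals = np.array([
            region_si(pair, GenomicInterval(gene.chrom, left + i * width,
                                            left + (i + 1) * width))
            for i in range(n)
        ])
    return vals[::-1] if gene.strand == "-" else vals


def load_expression_table(path) -> pd.DataFrame:
    """TSV with columns gene_id, fpkm_growth, fpkm_diff, spm."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "fpkm_growth", "fpkm_diff", "spm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if ((df["spm"] < 0) | (df["spm"] > 1)).any():
        raise ValueError("SPM values must lie in [0, 1]")
    if (df[["fpkm_growth", "fpkm_diff"]] < 0).to_numpy().any():
        raise ValueError("FPKM values must be non-negative")
    return df


def select_tissue_genes(expr: pd.DataFrame, rule: str,
                        skm_clause: str = "or") -> GeneSet:
    """Select a tissue-specific gene set from expression + specificity.

    Rules (SPM band 0.7–1.0 inclusive in both):

    - ``skm`` (expressed-on-differentiation): FPKM < 100 in growth OR
      differentiated FPKM >= 3x growth FPKM (``skm_clause="and"``
      switches the disjunction to a conjunction);
    - ``cbl`` (silent): FPKM < 0.5 in both growth and differentiated
      states.

    An empty result is allowed with a warning.
    """
    if expr.empty:
        raise ValueError("expression table is empty")
    spm_ok = (expr["spm"] >= 0.7) & (expr["spm"] <= 1.0)
    if rule == "skm":
        a = expr["fpkm_growth"] < 100
        b = expr["fpkm_diff"] >= 3 * expr["fpkm_growth"]
        fpkm_ok = (a | b) if skm_clause == "or" else (a & b)
    elif rule == "cbl":
        fpkm_ok = (expr["fpkm_growth"] < 0.5) & (expr["fpkm_diff"] < 0.5)
    else:
        raise ValueError(f"unknown rule {rule!r} (expected 'skm' or 'cbl')")
    ids = sorted(expr.loc[spm_ok & fpkm_ok, "gene_id"].astype(str))
    if not ids:
        logger.warning("rule %s selected no genes", rule)
    return GeneSet(rule.upper(), ids)
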