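"""End-to-end orchestration: simulate/load -> signal -> scores -> bivalency.

A run is driven by a :class:`RunConfig` (self-contained simulation or a
study directory on disk), persists every per-unit table as TSV/BED/
bedGraph, and summarizes the numbers in a :class:`RunReport` whose every
entry is recomputable from the persisted tables. Two runs with the same
config and seed produce byte-identical text outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from chromphi.bivalency import (
    angle_scatter_table,
    call_enrichment,
    colocalization_summary,
)
from chromphi.genome_model import GeneSet, tile_genome
from chromphi.geneset_scoring import geneset_z, per_gene_z, promoter_si_table
from chromphi.tag_signal import replicate_correlation, signal_intensity, SignalTrack
from chromphi.synthetic_data import SimulationConfig, load_study, simulate_study

logger = logging.getLogger(__name__)

STUDY_FILES = ("chrom.sizes", "genes.bed", "truth.tsv", "config.yaml")
FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run; defaults are the standard analysis
    choices (200 bp genome grid, 2 kb/1 kb sliding windows, TSS +/- 2 kb)."""

    simulation: SimulationConfig | None = None
    study_dir: str | None = None
    window: int = 200
    sliding_width: int = 2_000
    sliding_step: int = 1_000
    corr_window: int = 2_000
    flank: int = 2_000
    dedup: bool = True
    binarization: str = "si"          # "si" | "log_ratio" (equivalent sign rules)
    geneset_z_mode: str = "global_se"  # or "set_sem"
    write_bedgraph: bool = True
    write_tags: bool = False

    def __post_init__(self) -> None:
        if self.simulation is None and self.study_dir is None:
            self.simulation = SimulationConfig()

    def validate(self) -> None:
        if self.study_dir is not None:
            for name in STUDY_FILES:
                path = os.path.join(self.study_dir, name)
                if not os.path.exists(path):
                    raise PipelineError(f"stage validate: missing input file {path}")
        elif self.simulation is not None:
            self.simulation.validate()

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.echo(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig(**d["simulation"])
        return cls(**d)


@dataclass
class RunReport:
    """Summary of one run; every numeric entry is recomputable from the
    persisted per-unit tables in the run directory."""

    data: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunReport":
        with open(path) as fh:
            return cls(json.load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, outdir, seed: int | None = None) -> RunReport:
    """Execute all stages in dependency order and persist every table.

    ``seed`` overrides the simulation seed for self-contained runs.
    Returns the :class:`RunReport`, also written to ``report.json``.
    """
    from chromphi import __version__

    config.validate()
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"version": __version__, "config": config.echo()}

    with _stage("study"):
        if config.study_dir is not None:
            study = load_study(config.study_dir)
            report["inputs"] = {
                name: _sha256(os.path.join(config.study_dir, name))
                for name in sorted(os.listdir(config.study_dir))
            }
        else:
            sim = config.simulation
            if seed is not None:
                sim = dataclasses.replace(sim, seed=int(seed))
                report["config"]["simulation"]["seed"] = int(seed)
            study = simulate_study(sim)
            report["inputs"] = "simulated"
        marks = study.config.marks
        report["n_unique"] = {
            **{f"{m}_rep{r}": study.tagsets[(m, r)].n_unique
               for m in marks for r in range(1, study.config.n_replicates + 1)},
            **{t.sample_id: t.n_unique
               for t in {id(t): t for t in study.inputs.values()}.values()},
        }
        if config.write_tags:
            from chromphi.synthetic_data import write_study
            write_study(study, os.path.join(outdir, "study"), overwrite=True)

    n_rep = study.config.n_replicates
    chrom_table = study.chrom_table

    with _stage("signal"):
        fine = tile_genome(chrom_table, config.window, config.window)
        corr_grid = tile_genome(chrom_table, config.corr_window, config.corr_window)
        mark_si: dict[str, np.ndarray] = {}
        corr_means: dict[str, float] = {}
        for mark in marks:
            fine_tracks = [signal_intensity(study.pair(mark, r), fine)
                          for r in range(1, n_rep + 1)]
            mark_si[mark] = np.mean([t.values for t in fine_tracks], axis=0)
            if n_rep >= 2:
                corr_tracks = [signal_intensity(study.pair(mark, r), corr_grid)
                               for r in range(1, n_rep + 1)]
                corr_df, corr_mean = replicate_correlation(corr_tracks)
                corr_df.to_csv(os.path.join(outdir, f"correlation_{mark}.tsv"),
                               sep="\t", float_format=FLOAT_FMT)
                corr_means[mark] = corr_mean
            if config.write_bedgraph:
                sl_grid = tile_genome(chrom_table, config.sliding_width, config.sliding_step)
                sl = np.mean(
                    [signal_intensity(study.pair(mark, r), sl_grid).values
                     for r in range(1, n_rep + 1)], axis=0)
                SignalTrack(sl_grid, mark, f"{mark}_mean", sl, "si").to_bedgraph(
                    os.path.join(outdir, f"sliding_{mark}.bedGraph"))
        report["replicate_correlation_mean"] = corr_means

    with _stage("scores"):
        promoter: dict[str, pd.Series] = {}
        frames = []
        for mark in marks:
            per_rep = [
                promoter_si_table(study.pair(mark, r), study.genes, config.flank)
                .set_index("gene_id")["si_tss"]
                for r in range(1, n_rep + 1)
            ]
            si = pd.concat(per_rep, axis=1).mean(axis=1)
            promoter[mark] = si
            frames.append(pd.DataFrame({
                "gene_id": si.index, "mark": mark,
                "si_tss": si.to_numpy(), "z": per_gene_z(si.to_numpy()),
            }))
        scores = pd.concat(frames, ignore_index=True)
        scores.to_csv(os.path.join(outdir, "gene_scores.tsv"), sep="\t",
                      index=False, float_format=FLOAT_FMT)

        gene_sets = [
            GeneSet(cls, sorted(g["gene_id"]))
            for cls, g in study.truth.groupby("gene_class")
        ]
        pd.concat(
            [pd.DataFrame({"set_name": s.name, "gene_id": s.gene_ids}) for s in gene_sets],
            ignore_index=True,
        ).to_csv(os.path.join(outdir, "gene_sets.tsv"), sep="\t", index=False)
        zrows = []
        for s in gene_sets:
            for mark in marks:
                gz = geneset_z(promoter[mark], s, mark, mode=config.geneset_z_mode)
                zrows.append({"set_name": gz.set_name, "mark": gz.mark,
                              "n": gz.n, "z_set": gz.z_set})
        zdf = pd.DataFrame(zrows)
        zdf.to_csv(os.path.join(outdir, "geneset_z.tsv"), sep="\t",
                   index=False, float_format=FLOAT_FMT)
        report["geneset_z"] = {
            f"{r.set_name}|{r.mark}": r.z_set for r in zdf.itertuples()
        }

    with _stage("bivalency"):
        calls = {m: call_enrichment(mark_si[m], mode=config.binarization) for m in marks}
        grid_frame = fine.to_frame()
        for mark in marks:
            out = grid_frame.copy()
            out["state"] = np.where(calls[mark], "enriched", "depleted")
            out.to_csv(os.path.join(outdir, f"calls_{mark}.bed"), sep="\t",
                       header=False, index=False)
        needed = {"H3.3", "H3K4me3", "H3K27me3"}
        if needed <= set(marks):
            summary = colocalization_summary(
                calls["H3.3"], calls["H3K4me3"], calls["H3K27me3"])
            summary.to_frame().to_csv(os.path.join(outdir, "colocalization.tsv"),
                                      sep="\t", index=False, float_format=FLOAT_FMT)
            summary.counts.to_csv(os.path.join(outdir, "colocalization_counts.tsv"),
                                  sep="\t", index=False)
            report["colocalization"] = {
                "n_windows": summary.n_windows,
                "frac_h33_enriched": summary.frac_h33_enriched,
                "frac_bivalent_given_h33_enriched": summary.frac_bivalent_given_h33_enriched,
                "frac_bivalent_given_h33_depleted": summary.frac_bivalent_given_h33_depleted,
            }
            scatter = angle_scatter_table(
                promoter["H3K4me3"], promoter["H3K27me3"], promoter["H3.3"])
            scatter = scatter.merge(study.truth[["gene_id", "gene_class"]], on="gene_id")
            scatter[scatter["included"]].drop(columns="included").to_csv(
                os.path.join(outdir, "scatter.tsv"), sep="\t", index=False,
                float_format=FLOAT_FMT)
            report["scatter_n_included"] = int(scatter["included"].sum())
        else:
            logger.warning("marks %s lack the H3.3/K4/K27 trio; co-localization skipped",
                           sorted(marks))

    rep = RunReport(report)
    rep.to_json(os.path.join(outdir, "report.json"))
    return rep


def compare_conditions(run_a, run_b, gene_set: str, mark: str,
                       test: str = "welch") -> pd.DataFrame:
    """Two-condition contrast of a gene set's promoter SI for one mark.

    ``run_a``/``run_b`` are run output directories. Returns a one-row
    frame with the difference of set means (a − b) and a standard
    two-sample location test ("welch" t-test or "mannwhitney").
    """
    vals = []
    for d in (run_a, run_b):
        sets_path = os.path.join(d, "gene_sets.tsv")
        scores_path = os.path.join(d, "gene_scores.tsv")
        if not (os.path.exists(sets_path) and os.path.exists(scores_path)):
            raise PipelineError(f"stage compare: {d} is not a completed run directory")
        sets = pd.read_csv(sets_path, sep="\t")
        members = sets.loc[sets["set_name"] == gene_set, "gene_id"]
        if members.empty:
            raise PipelineError(f"stage compare: gene set {gene_set!r} absent in {d}")
        scores = pd.read_csv(scores_path, sep="\t")
        sel = scores[(scores["mark"] == mark) & scores["gene_id"].isin(set(members))]
        if sel.empty:
            raise PipelineError(f"stage compare: mark {mark!r} absent in {d}")
        vals.append(sel["si_tss"].to_numpy(dtype=float))
    a, b = vals
    if test == "welch":
        stat, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame({
        "gene_set": [gene_set], "mark": [mark], "n_a": [len(a)], "n_b": [len(b)],
        "mean_a": [a.mean()], "mean_b": [b.mean()], "diff": [a.mean() - b.mean()],
        "test": [test], "statistic": [float(stat)], "p_value": [float(p)],
    })
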