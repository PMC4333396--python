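# Methods

## Signal model

The counting unit is the *tag*: a uniquely aligned read reduced to its
(chromosome, 5′ position, strand) triple. By default tags identical in
that triple are collapsed ("unique tags"); deduplication is a flag on
every loader and on the simulator. A tag is assigned to a window by
point containment of its 5′ position (not fragment overlap): this is
deterministic, requires no fragment-length model, and matches a
tag-count definition of density. With half-open windows, boundary
membership is unambiguous.

Densities are RPKM, normalized per sample by its own unique-tag total,
and signal intensity is the input-subtracted density

SI(w) = RPKM_IP(w) − RPKM_input(w),

which is unbounded in sign. Negative SI means the IP is locally sparser
than the input; per-library normalization makes this the *expected*
state of unenriched background in a successful IP, because enrichment
concentrates a fixed read budget into enriched regions (see
"Synthetic data" below). SI is computed on three window schemes:

- 200 bp tiled windows genome-wide (mono-nucleosome scale) for
  binarization and co-localization;
- 2 kb windows at 1 kb intervals (50% overlap) for browser tracks
  (bedGraph export);
- TSS ± 2 kb promoter windows for per-gene summaries.

Coordinates are 0-based half-open throughout. Fixed grids drop partial
terminal windows so widths are constant; TSS windows are instead clipped
at chromosome boundaries and normalized by their actual width, keeping
genes near chromosome ends. The TSS of a −-strand gene is its BED
end − 1 coordinate; a symmetric TSS window is strand-agnostic. Gene ids
appearing in an analysis but not in the annotation are logged and
skipped rather than fatal.

## Z-scores

Per-gene: z_g = (SI_g − mean_all)/sd_all with the population SD
(divide by N); the gene universe therefore standardizes to mean 0, SD 1
exactly. Per gene set: z_set = (mean_set − mean_all)/(sd_all/√n). The
"standard error" here is deliberately the global SD scaled by the set
size; a `set_sem` mode using the set's own SEM is provided for
sensitivity analysis. Zero global SD (all genes identical) is rejected
rather than returning infinities. Negative promoter SIs are retained in
all Z computations; the positive-part filter applies only to the angle.

## Bivalency angle

φ = 2·arctan[+(SI_K27)/+(SI_K4)] in degrees, with +(x) = max(x, 0).
Conventions: +(K4) = 0 with +(K27) > 0 gives φ = 180° exactly; both
zero gives a missing value (NaN) and the unit is excluded from exported
scatters. φ is scale-invariant, monotone in each argument, and obeys
φ(a,b) + φ(b,a) = 180° for positive a, b. Degrees are used everywhere
externally; radians only inside the arctangent. No φ band is hard-coded
as "bivalent"; the 60–120° band used in the recovery tests is an
internal convention for checking class separation, not a claim about a
biological threshold.

## Binarization and co-localization

Each 200 bp window is scored enriched iff SI > 0, else depleted; SI
exactly 0 is depleted (no evidence of enrichment). A `log_ratio`
binarization mode is accepted for completeness: sign(log(RPKM_IP /
RPKM_input)) equals sign(SI) wherever both are defined, so the two modes
are the same rule and are asserted equal in a test. A window is bivalent
when both H3K4me3 and H3K27me3 are enriched; the co-localization summary
reports the H3.3-enriched fraction of windows and the bivalent fraction
within each H3.3 stratum, plus the full 2×2×2 count table so every
fraction is recomputable from the exported calls. An empty stratum
yields a missing conditional fraction.

## Replicate correlation

Pearson correlation of SI tracks on a 2 kb non-overlapping genome-wide
grid, all windows included (no zero-signal filtering); the summary
statistic is the mean of the upper-triangle entries. Constant tracks are
rejected (undefined correlation).

## Tissue-specific gene selection

From a table of (gene, FPKM in growth, FPKM after differentiation, SPM
specificity in [0,1]): lineage-specific ("skm") genes require SPM in
[0.7, 1.0] (inclusive) and (growth FPKM < 100 OR differentiated FPKM ≥
3× growth); the disjunction is configurable to a conjunction. Silent
("cbl") genes require the same SPM band and FPKM < 0.5 in *both*
states — a gene silent in the assayed cell line should be silent
regardless of differentiation state. Housekeeping sets are supplied as
explicit lists, not computed. Selection is deterministic, idempotent and
order-independent (output sorted by gene id).

## Synthetic data

The generator emulates the *statistical* structure the analysis is
sensitive to, nothing finer. Genes are placed on a per-chromosome
lattice (spacing ≥ 10 kb enforced, so promoter windows never overlap)
with ±2 kb jitter in 200 bp steps; classes {active, poised, repressed,
silent} are assigned by seeded permutation. For each sample, tag counts
per 200 bp cell are independent Poisson draws with mean
λ_bg·fold(mark, class) inside TSS ± 2 kb and λ_bg elsewhere, rescaled so
the total expectation equals the configured depth; positions are uniform
within the cell, strands uniform. Default folds: H3K4me3 8/4/1/1,
H3K27me3 1/4/8/1, H3.3 6/6/1/1 over active/poised/repressed/silent —
chosen so poised promoters are balanced (φ ≈ 90°) and H3.3 co-occupies
active and poised promoters. Defaults: 2 chromosomes × 5 Mb, 50 genes
per class, depth 2×10⁶ tags per sample, 3 replicates sharing one input
sample (the common ChIP-seq design; per-replicate inputs are an option).
At this size a full pipeline run takes on the order of ten seconds.

Two consequences of the fixed-depth rescaling are worth knowing:

- unenriched (fold-1) promoters and background have *slightly negative*
  expected SI, because adding enrichment mass at fixed depth depresses
  the IP background below the input density — exactly as in real
  ChIP-seq with per-library normalization; the tests therefore compare
  silent promoters against matched background regions rather than
  against zero;
- deduplication saturates the densest windows, so the post-dedup
  promoter/background density ratio underestimates the configured fold
  (≈6 of 8 at default densities). The generator's fold is recovered
  unbiasedly from raw tags (`dedup=False`), which is how the
  estimator-consistency test measures it.

What the generator does **not** model: sequence content and
mappability, fragment-length variation, nucleosome positioning,
copy-number and GC biases, overlapping genes and alternative TSSs, and
inter-replicate batch effects (replicates differ only by sampling
noise, so simulated replicate correlations are optimistic; the >0.5
acceptance bound is a floor, not a calibration). Passing recovery tests
therefore demonstrate correctness of the statistics under the stated
sampling model, not robustness to those real-data artifacts.

## Pipeline

`run_pipeline` executes simulate/load → signal → scores → bivalency,
persists every per-unit table (gene scores, gene sets, gene-set Z,
per-mark 200 bp calls as BED4, co-localization summary and count table,
φ scatter, per-mark replicate-correlation matrices, sliding-window
bedGraphs) and writes a `report.json` whose every number is
recomputable from those tables (asserted in tests). Replicates are
combined by averaging per-replicate SI, mirroring the use of
triplicate means for downstream analysis. Runs are deterministic:
identical config and seed give byte-identical text outputs. Condition
contrasts (e.g. wild-type vs variant-forced) are modeled as two
pipeline runs plus `compare_conditions`, which applies a standard
two-sample location test (Welch t by default, Mann-Whitney optionally)
to a gene set's promoter SI values; no multiple-testing correction is
applied by default since contrasts are reported per set.

## Numerical choices

- Population (ddof 0) SD for all Z denominators; sample SD only inside
  the optional `set_sem` mode and in test SEMs.
- Window counting is a sorted-array bisection per window boundary;
  exact integer counts, no approximation.
- φ of vectors is computed with NaN marking exclusion; scalar and
  vector paths are asserted equal.
- TSV exports use `%.10g` float formatting for stable, diff-able
  output.
- Degenerate inputs rejected loudly: empty libraries (RPKM), constant
  tracks (correlation), zero global SD (Z), gapped grids
  (step > width), non-finite SIs (angle).
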