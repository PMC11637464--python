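# Methods

This note documents the models, parameters, and numerical choices behind
`plexscreen`, and what the synthetic-data tests do and do not establish
about real data.

## 1. Synthetic hashed-screen generator (`synthdata`)

**What it emulates.** A plate-based reprogramming screen profiled by
combinatorial-indexing snRNA-seq: 30–265 wells carrying
treatment × dose (0.1 / 1 / 10 µM) × collection-day labels plus
induction-only control wells; 4–9 discrete cell types along the
MG → progenitor → transition → neuronal-precursor → bipolar axis; a few
thousand UMIs per nucleus; per-well hash oligos with a uniform background
fraction.

**Count model.** Each cell draws a type from its well's composition
vector; its counts are gamma-Poisson (negative binomial) around
`mean_umis_per_cell × program(gene, type)`:
`λ ~ Gamma(shape = dispersion, mean = μ)`, `count ~ Poisson(λ)`. A single
shared dispersion (default 2.0, a typical mid-range UMI overdispersion) is
the minimal overdispersion model; `dispersion = ∞` degenerates to Poisson
and is used by the moment-recovery tests. Gene programs are lognormal
baseline abundances with disjoint marker blocks elevated `marker_fold`-fold
(default 8) in their own type only; a trailing `mito_gene_fraction`
(default 5%) of genes is flagged mitochondrial and carries a fixed
`mito_umi_fraction` (default 5%) share of every program, giving every cell
an injected mitochondrial read fraction.

**Hash model.** Per cell, `hash_reads_per_cell` (default 100) reads are
multinomial with `1 − ε` on the true well's hash and `ε` uniform over all
hashes. ε (`hash_background_eps`, default 0.05) is a single symmetric
background knob — deliberately not a cell-specific ambient model — chosen
to stress the ratio filter; no published background rate exists for this
assay, so 0.05 is a package default, exposed in config. Doublets are out
of scope: the assay removes them cytometrically, not computationally.

**Planted effects.** A well's `neuron_multiplier` scales the neuron-fated
(NeuPre, BP) composition entries before renormalization; the default
screen design plants multiplier 3 at 10 µM and 1.5 at 1 µM for hit
treatments. Because of renormalization a 3× proportion multiplier yields
roughly a 2× realized fold change at the default baseline composition —
the recovery tests rank conditions rather than assume FC equals the
multiplier.

**Randomness.** One `SeedSequence` per dataset spawns fixed-order child
streams (gene program, hash streams, well streams); each well's cells are
drawn vectorized from that well's stream in cell order, so appending wells
never perturbs existing wells' draws, and identical config + seed is
byte-identical on disk. `draw_cell_types` replays only the type draws of a
full simulation (identical values) for composition-only Monte-Carlo runs.

**What passing tests do not show.** The generator has discrete types (no
continuum between states), no batch effects, no ambient RNA, no
doublets, and a single shared dispersion. Tests passing here demonstrate
algorithmic correctness and calibration under the stated model, not
robustness to those real-data complications.

## 2. Demultiplexing and QC (`demux`)

`r = c(1)/c(2)` over each cell's sorted hash counts. Conventions the data
do not force, fixed as package decisions: a zero second-best with positive
best gives `r = +∞` (maximally unambiguous, assigned); a tie for best
gives `r = 1` (ambiguous, unassigned under any threshold > 1); an all-zero
row leaves `r` undefined and the cell unassigned. Both threshold dialects
are expressible: strict *retain if r > θ* (timecourse θ=4, pulse θ=5) and
lenient *discard if r < θ* (screen θ=5, so a cell exactly at 5 is kept).

UMI bounds are strict on both sides (discard `< 500` or `> 20,000`; cells
exactly at a bound are kept). The mitochondrial fraction is computed on
the full gene set before any gene filtering and compared as
*discard if > 0.15* (screen preset only). Droplet presets use UMI floors
of 2,500 or 3,000 and skip the hash step. Removal counts attribute each
cell to its first failing rule in the fixed order hash → low UMI → high
UMI → mito so that counts are additive and conservation
(`n_in = n_retained + Σ removed`) is assertable per run.

## 3. Embedding, clustering, annotation, specificity (`cluster_annotate`)

Pipeline: per-cell size factors (UMI total over geometric mean of totals)
→ log1p → PCA (full SVD; deterministic) → least-squares residualization of
each PC on log10(UMIs) plus batch indicators (batch terms dropped when a
single batch) → symmetric kNN graph with Euclidean weights → Leiden
(RBConfiguration) at the preset resolution → UMAP layout. Presets:
20 PCs / 50 neighbors / resolution 6·10⁻⁴ (timecourse & pulse),
30 / 100 / 1·10⁻⁴ (screen), 30 / 12 / 5·10⁻⁴ (subcluster); min_dist 0.1
everywhere. The contract for Leiden and UMAP is determinism under a fixed
seed, not a particular implementation.

**Cluster annotation.** Per cluster and candidate type, the score is the
mean over the type's markers of (fraction of cluster cells with ≥ 1 UMI of
the marker) × (the marker's mean normalized expression in the cluster,
normalized to sum to one across clusters). Argmax wins; exact ties break
lexicographically and are flagged; below a 0.05 score floor the cluster is
"Unknown". The marker-to-type aggregation is a documented package choice —
the marker-gene literature does not fix one.

**Specificity.** `S = 1 − JSD₂(p_g, e_k)` as in the README. Distance (not
divergence) and log base 2 are chosen so `S ∈ [0, 1]`, which is the scale
on which the 0.3 cutoff is meaningful. "Detected" means ≥ 1 UMI;
"mean expression" is size-factor-normalized uniformly throughout the
package. Genes with zero total expression are excluded rather than given
an arbitrary S. The closed-form implementation (one-hot mixture) is
cross-checked in tests against an independent numeric JSD.

**Enrichment** is a one-sided hypergeometric tail `P(X ≥ overlap)` per
user-supplied gene set with Benjamini–Hochberg adjustment across sets and
significance at `p ≤ 0.01` and `q ≤ 0.05`. No ontology database ships with
the package; any annotation source can be supplied as gene lists.

## 4. Trajectory (`trajectory`)

**Pseudotime.** τ is the Dijkstra distance from the root (the cell nearest
the source-cluster PC centroid) over the kNN graph with Euclidean edge
weights in residualized PC space; unreachable cells get `+∞`. This
geodesic-over-kNN construction replaces principal-graph learning: the
downstream computations need only a per-cell ordering and a density over
scores, and the geodesic is simple, testable (invariant to rigid rotations
of PC space; Spearman ≥ 0.9 against latent time on simulated linear
trajectories), and free of graph-fitting hyperparameters.

**Commitment point.** Gaussian KDE with Silverman bandwidth on the τ
values inside the window (default (10, 20)), evaluated on a 512-point
grid; τ\* is the interior argmin. If the minimum sits on a window boundary
the density is monotone there and `None` is returned with a warning. The
shipped default partition threshold of 16 applies to reproducing the
original culture data, whose pseudotime scale fixes that number; synthetic
runs recompute τ\* from their own density.

**Windowed DEG.** Cells with `lo < τ < hi` (≥ 50 required) enter a
per-gene log-link count regression of UMIs on τ with log size factor as
offset, fit by vectorized IRLS across all genes simultaneously. The family
is NB2 with method-of-moments dispersion estimated from the Poisson fit
(`α̂ = Σ[(y−μ̂)² − μ̂]/Σμ̂²`), falling back to Poisson when `α̂ ≤ 0`. β is per
unit pseudotime on the natural-log scale and the `|β| < 0.08` filter is
applied to that coefficient; q-values are BH over converged genes and the
250 lowest-q survivors are retained (ties broken by p then gene name for
determinism). Non-converged or all-zero genes are flagged and excluded,
never silently kept. Coefficients and standard errors are verified against
statsmodels GLMs in the test suite; FDR calibration is checked by
simulation (realized FDR ≈ 0.06 at q < 0.05 on 1000 null + 50 signal
genes).

**Trend modules.** Finite-τ cells are ordered by τ; normalized expression
is smoothed by a centered 51-cell rolling mean (a heatmap convention;
results are insensitive to the exact width at these sizes), z-scored per
gene, and clustered by k-means (k = 3, fixed seed, 10 restarts). Labels
are canonicalized by each module centroid's peak position: latest peak →
module 1 (increasing), middle → 2 (transient), earliest → 3 (decreasing).

## 5. Hit calling (`screen`)

Condition granularity is treatment × dose × collection day; the ≥ 20-cell
floor applies at this granularity, and dropped conditions are excluded
*before* size factors so they cannot distort the geometric mean. Neuronal
precursor and bipolar types merge to *Neuron* (and early/late
progenitor-like to *ProL*) ahead of tabulation; unmapped type names are
kept as-is with a warning. `s_t = total_t / geomean(retained totals)` so
the retained size factors have geometric mean 1, and
`FC = adjusted(t)/adjusted(control)` with the control matched by
collection day (pooled induction-only wells of that day). A zero control
count leaves FC undefined and flagged rather than infinite. FC is
scale-invariant: multiplying a condition's counts by any constant is
absorbed by its size factor. No p-value is attached to FC — the screen
design ranks conditions — but treatment clustering (average-linkage,
Euclidean, on row-normalized compositions, input-order invariant) is
provided for structure discovery. A bootstrap CI over cells could be added
by resampling `cells` rows; it is deliberately not part of the hit table.

## 6. Pipeline and determinism (`pipeline`)

Stage order: read → demux → QC → embed (normalize, PCA, residualize,
graph, layout) → cluster → annotate → trajectory or hits. Every printed
parameter lives on `RunConfig`; presets only fill defaults. All outputs
are TSV with fixed column order; two runs with the same seed are
byte-identical (asserted in tests including the UMAP layout). A stage
failure persists partial outputs plus an `INCOMPLETE` flag naming the
stage. The trajectory window accepts `"auto"` (the interquartile range of
finite τ) for synthetic data whose pseudotime scale differs from the
(10, 20) culture-data window.

## 7. Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which the measured properties are stable:
demultiplexing accuracy at 5,000 cells / 24 wells; planted-hit recovery at
20 treatments × 3 doses × 200 cells/well over 50–100 seeds; DEG
calibration at 300 cells × 1,050 genes over 25–50 seeds; pseudotime
fidelity at 1,000 cells; module recovery at 60 genes × 400–500 cells; the
end-to-end determinism run at 21 wells × 100 cells. The full-suite
defaults (`SimConfig`: 2,000 genes, 2,500 mean UMIs) match the data scale
the generator emulates.

## Known limitations

- Pseudotime is single-lineage; no branch detection or velocity.
- Linear residualization only; no MNN-style integration.
- The NB Wald test is slightly anticonservative at small counts (realized
  FDR ~0.06 at nominal 0.05 in simulation); BH across genes absorbs most
  of this.
- The annotation score assumes marker panels with positive markers only.
- The generator's discrete types cannot test trajectory continuity; the
  trajectory tests use a separate linear-latent fixture instead.
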