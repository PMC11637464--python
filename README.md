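# plexscreen

Analysis toolkit for **multiplexed (hashed) single-nucleus RNA-seq screens**
of cell-fate reprogramming, of the kind used to ask: *which compounds
increase the number of neurons produced when Müller glia (MG) are driven
toward a neuronal fate by Ascl1 overexpression?*

In such a screen, nuclei from each treatment well are labelled with a
well-specific polyadenylated oligo ("hash") before pooling, so that a single
sequencing run covers tens-to-hundreds of treatment × dose × collection-day
conditions. The computational problem is to

1. assign each nucleus back to its well from the hash counts
   (demultiplexing) and apply cell-level QC,
2. embed, cluster and annotate the cells into discrete states
   (MG → progenitor-like → transition → neuronal precursor → bipolar),
3. order cells along the reprogramming trajectory (pseudotime), locate the
   commitment point after which cells no longer need the inducing factor,
   and find genes changing across that window, and
4. call screen hits as shifts in cell-type composition relative to the
   induction-only control.

## The statistics at the core

**Demultiplexing.** For each cell, with hash counts `c(1) ≥ c(2) ≥ …`, the
confidence statistic is the *top-to-second-best ratio* `r = c(1)/c(2)`
(`+∞` when `c(2) = 0`). A cell is assigned to the well of its top hash when
`r` clears a preset threshold (`r > 4` timecourse, `r > 5` pulse, discard
`r < 5` screen). UMI bounds (500–20,000), and in the screen preset a 15%
mitochondrial-fraction ceiling, complete QC.

**Gene specificity.** Let `p_g` be gene *g*'s mean size-factor-normalized
expression per cell type, normalized to sum to one across types, and `e_k`
the one-hot profile of type *k*. The specificity is

```
S(g, k) = 1 − JSD₂(p_g, e_k)
```

with `JSD₂` the base-2 Jensen–Shannon *distance* (square root of the
divergence), so `S ∈ [0, 1]`. A gene is *highly specific* for `k` when its
detection fraction in `k` exceeds 0.05 and `S > 0.3`.

**Pseudotime.** τ is the geodesic (shortest-path) distance from a root cell
— the cell nearest the MG cluster's centroid — over the k-nearest-neighbor
graph with Euclidean edge weights in residualized PC space. The
*commitment point* τ\* is the interior minimum of a Gaussian-KDE of τ on
the window (10, 20). Windowed differential expression fits, per gene,

```
UMIs ~ NB(μ),  log μ = β₀ + β·τ + log(size factor)
```

with method-of-moments dispersion (Poisson fallback), drops `|β| < 0.08`,
keeps the 250 lowest-q survivors, and groups them into three k-means trend
modules (increasing / transient / decreasing).

**Hit calling.** Cells are tabulated into a cell-type × condition matrix
(neuronal precursor + bipolar merged to *Neuron*), conditions with < 20
cells are dropped, each column is adjusted by a size factor
`s_t = total_t / geomean(totals)`, and

```
FC(t, type) = adjusted(t, type) / adjusted(control on t's collection day, type)
```

ranks treatments by their *Neuron* fold change versus the Ascl1-only
control.

## Worked example

```python
import numpy as np
from plexscreen import synthdata as sd, demux as dx, screen as sc

# 20 treatments x 3 doses + per-day controls; one planted hit
wells = sd.screen_design(
    n_treatments=20, cells_per_well=200,
    planted_hits={"drug_003": {10.0: 3.0, 1.0: 1.5}},
)
cfg = sd.SimConfig(wells=wells, seed=1, n_genes=200)
ds = sd.simulate_screen(cfg)

calls = dx.call_hashes(ds.hashes, ratio_min=5.0)
print(f"hash recovery rate: {calls.hash_recovery_rate:.3f}")

cells, report = dx.filter_cells(ds.expr, calls, dx.QC_PRESETS["screen"], ds.manifest)
print(f"retained {report['n_retained']} of {report['n_in']} cells")

cells["cell_type"] = ds.truth.cells["cell_type"].reindex(cells.index)
comp = sc.build_composition(cells)
sc.size_factors(comp)
hits = sc.fold_changes(comp, control_label="Only Ascl1")
neuron = hits[(hits.cell_type == "Neuron") & hits.retained & (hits.dose_um == 10.0)]
print(neuron.sort_values("fc", ascending=False)[["treatment", "count", "fc"]]
      .head(3).to_string(index=False))
```

prints

```
hash recovery rate: 1.000
retained 13197 of 13200 cells
treatment  count       fc
 drug_003    100 2.000000
 drug_008     57 1.230216
 drug_006     56 1.208633
```

With 5% uniform hash background every cell still demultiplexes cleanly;
three cells fall outside the UMI bounds. The planted compound `drug_003`
tops the Neuron fold-change ranking at the 10 µM dose with FC = 2.0 — the
3× proportion multiplier becomes a ~2× fold change after the composition
renormalizes — while unplanted treatments sit near FC = 1.

The same stages run from the shell:

```sh
plexscreen simulate --design screen --out data/
plexscreen run --preset screen --input-dir data/ --out results/ --seed 7
```

## Layout

- `plexscreen.synthdata` — gamma-Poisson screen generator with ground truth
- `plexscreen.demux` — hash calling, ratio statistic, QC presets
- `plexscreen.cluster_annotate` — embedding, Leiden clustering, marker
  annotation, JS specificity, hypergeometric gene-set enrichment
- `plexscreen.trajectory` — geodesic pseudotime, commitment point, windowed
  DEG, trend modules
- `plexscreen.screen` — composition matrix, size factors, fold-change hit
  table, treatment clustering
- `plexscreen.pipeline` / `plexscreen.cli` — presets, I/O and the
  `plexscreen` command

See `docs/methods.md` for the full model description and design notes.
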