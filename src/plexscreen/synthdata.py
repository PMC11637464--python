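"""Synthetic hashed single-nucleus screen datasets with known ground truth.

The generator emulates the structure of a multi-well reprogramming screen:
a handful of discrete cell types (a glial source population, progenitor-like
and transitional states, and neuron-fated precursor/bipolar states), wells
carrying treatment x dose x collection-day labels, per-well cell-type
compositions that planted "hit" compounds shift toward the neuron-fated
types, gamma-Poisson (negative binomial) UMI counts with type-specific
marker programs, and per-cell hash-oligo reads with a symmetric background
noise fraction. Every draw is reproducible from ``SimConfig.seed``, and the
random stream is split per well so adding wells never perturbs the draws of
existing wells.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml
from anndata import AnnData

from .demux import HashCountTable

#: Canonical cell-type names, in trajectory order. The first five emulate
#: the culture system (glia -> progenitor-like -> transition -> neuronal
#: precursor -> bipolar); further types model unrelated contaminants.
CELL_TYPE_POOL = (
    "MG",
    "ProL",
    "Transition",
    "NeuPre",
    "BP",
    "Microglia",
    "Astrocyte",
    "FibroL",
    "Unknown",
)

#: Types counted as neuron-fated; planted compound effects multiply their
#: well composition.
NEURON_TYPES = ("NeuPre", "BP")

_BASE_COMPOSITION = {
    "MG": 0.35,
    "ProL": 0.20,
    "Transition": 0.13,
    "NeuPre": 0.15,
    "BP": 0.07,
    "Microglia": 0.03,
    "Astrocyte": 0.03,
    "FibroL": 0.02,
    "Unknown": 0.02,
}


@dataclass
class WellSpec:
    """One treatment well of the screen."""

    well_id: str
    treatment: str
    dose_um: Optional[float]
    collection_day: int
    n_cells: int
    composition: Optional[np.ndarray] = None  # defaults to the config baseline
    neuron_multiplier: float = 1.0

    def validate(self, n_cell_types: int) -> None:
        if self.n_cells < 0:
            raise ValueError(f"n_cells must be >= 0 in well {self.well_id}")
        if self.neuron_multiplier <= 0:
            raise ValueError(f"neuron_multiplier must be > 0 in well {self.well_id}")
        if self.composition is not None:
            comp = np.asarray(self.composition, dtype=float)
            if comp.shape != (n_cell_types,):
                raise ValueError(
                    f"composition of well {self.well_id} has length {comp.shape[0]},"
                    f" expected {n_cell_types}"
                )
            if abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
                raise ValueError(
                    f"composition of well {self.well_id} must be non-negative and sum to 1"
                )


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults emulate a mid-sized screen: median a few thousand UMIs per
    nucleus, five cell types with ten markers each, gamma-Poisson counts
    with shared shape ``dispersion`` (Poisson in the ``dispersion = inf``
    limit), and hash reads of which a fraction ``hash_background_eps`` is
    uniform background over all hashes.
    """

    wells: list[WellSpec] = field(default_factory=list)
    n_genes: int = 2_000
    n_cell_types: int = 5
    markers_per_type: int = 10
    mean_umis_per_cell: float = 2_500.0
    dispersion: float = 2.0
    hash_background_eps: float = 0.05
    hash_reads_per_cell: int = 100
    mito_gene_fraction: float = 0.05
    mito_umi_fraction: float = 0.05
    marker_fold: float = 8.0
    control_label: str = "Only Ascl1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")
        if not 1 <= self.n_cell_types <= len(CELL_TYPE_POOL):
            raise ValueError(
                f"n_cell_types must be in [1, {len(CELL_TYPE_POOL)}]"
            )
        if self.markers_per_type < 0:
            raise ValueError("markers_per_type must be >= 0")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError("markers_per_type * n_cell_types exceeds n_genes")
        if self.mean_umis_per_cell <= 0:
            raise ValueError("mean_umis_per_cell must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 (use numpy.inf for Poisson)")
        if not 0.0 <= self.hash_background_eps <= 1.0:
            raise ValueError("hash_background_eps must be in [0, 1]")
        if self.hash_reads_per_cell < 0:
            raise ValueError("hash_reads_per_cell must be >= 0")
        if not 0.0 <= self.mito_gene_fraction <= 1.0:
            raise ValueError("mito_gene_fraction must be in [0, 1]")
        if not 0.0 <= self.mito_umi_fraction < 1.0:
            raise ValueError("mito_umi_fraction must be in [0, 1)")
        if self.marker_fold <= 0:
            raise ValueError("marker_fold must be > 0")
        for w in self.wells:
            w.validate(self.n_cell_types)
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well_id values must be unique")

    @property
    def cell_types(self) -> list[str]:
        return list(CELL_TYPE_POOL[: self.n_cell_types])

    def baseline_composition(self) -> np.ndarray:
        comp = np.array([_BASE_COMPOSITION[t] for t in self.cell_types], dtype=float)
        return comp / comp.sum()


@dataclass
class GroundTruth:
    """What the generator actually drew, for parameter-recovery tests."""

    cells: pd.DataFrame  # index cell_id; columns well_id, cell_type
    gene_means: pd.DataFrame  # genes x cell types: per-UMI program probabilities
    planted_hits: pd.DataFrame  # treatment, dose_um, neuron_multiplier (!= 1 only)


@dataclass
class SimulatedDataset:
    expr: AnnData
    hashes: HashCountTable
    manifest: pd.DataFrame
    truth: GroundTruth
    markers: dict[str, list[str]]
    config: SimConfig

    def write(self, outdir: str) -> None:
        write_dataset(self, outdir)


def _root_streams(config: SimConfig) -> tuple[np.random.SeedSequence, ...]:
    # fixed spawn order: [gene program, hash streams, well streams...]
    root = np.random.SeedSequence(config.seed)
    return tuple(root.spawn(3))


def _gene_programs(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-type expression programs (columns sum to 1).

    The first ``markers_per_type`` * type block of genes are markers,
    elevated ``marker_fold``-fold in their own type only. The trailing
    ``mito_gene_fraction`` of genes are flagged mitochondrial and receive a
    fixed ``mito_umi_fraction`` share of every type's program.
    """
    prog_ss, _, _ = _root_streams(config)
    rng = np.random.default_rng(prog_ss)
    n_genes, n_types = config.n_genes, config.n_cell_types
    n_mito = int(round(config.mito_gene_fraction * n_genes))
    n_mito = min(n_mito, n_genes - n_types * config.markers_per_type)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    means = np.tile(base[:, None], (1, n_types))
    markers: dict[str, list[str]] = {}
    gene_names = np.array(
        [f"mt-Gene{i:05d}" if i >= n_genes - n_mito else f"Gene{i:05d}" for i in range(n_genes)]
    )
    for k, t in enumerate(config.cell_types):
        lo, hi = k * config.markers_per_type, (k + 1) * config.markers_per_type
        means[lo:hi, k] *= config.marker_fold
        markers[t] = list(gene_names[lo:hi])

    is_mito = np.zeros(n_genes, dtype=bool)
    if n_mito:
        is_mito[-n_mito:] = True
    prog = np.empty_like(means)
    for k in range(n_types):
        col = means[:, k].copy()
        nuclear = col[~is_mito]
        prog[~is_mito, k] = nuclear / nuclear.sum() * (1.0 - config.mito_umi_fraction)
        if n_mito:
            mito = col[is_mito]
            prog[is_mito, k] = mito / mito.sum() * config.mito_umi_fraction

    genes = pd.DataFrame(
        {"gene_id": gene_names, "gene_name": gene_names, "is_mito": is_mito}
    ).set_index("gene_id", drop=False)
    prog_df = pd.DataFrame(prog, index=genes.index, columns=config.cell_types)
    return genes, prog_df, markers


def effective_composition(config: SimConfig, well: WellSpec) -> np.ndarray:
    """Well composition after the planted neuron-multiplier, renormalized."""
    comp = (
        np.asarray(well.composition, dtype=float)
        if well.composition is not None
        else config.baseline_composition()
    )
    comp = comp.copy()
    for i, t in enumerate(config.cell_types):
        if t in NEURON_TYPES:
            comp[i] *= well.neuron_multiplier
    return comp / comp.sum()


def draw_cell_types(config: SimConfig) -> pd.DataFrame:
    """Draw only the per-cell wells and true types (no expression).

    Uses the same per-well streams and draw order as
    :func:`simulate_expression`, so the types agree exactly with a full
    simulation under the same config; composition-only analyses (e.g.
    Monte-Carlo hit-recovery runs) can skip the count sampling.
    """
    config.validate()
    if not config.wells:
        raise ValueError("wells must be non-empty")
    _, _, well_root = _root_streams(config)
    well_streams = well_root.spawn(len(config.wells))
    types = config.cell_types
    cell_ids, well_of, type_of = [], [], []
    for well, ss in zip(config.wells, well_streams):
        rng = np.random.default_rng(ss)
        comp = effective_composition(config, well)
        t_idx = rng.choice(len(types), size=well.n_cells, p=comp)
        cell_ids.extend(f"{well.well_id}_{i:05d}" for i in range(well.n_cells))
        well_of.extend([well.well_id] * well.n_cells)
        type_of.extend(types[i] for i in t_idx)
    return pd.DataFrame(
        {"well_id": well_of, "cell_type": type_of},
        index=pd.Index(cell_ids, name="cell_id"),
    )


def simulate_expression(config: SimConfig) -> tuple[AnnData, GroundTruth]:
    """Draw the gene x cell UMI count matrix and its ground truth.

    Per cell, counts are gamma-Poisson around ``mean_umis_per_cell`` times
    the cell's type program: lambda ~ Gamma(shape=dispersion,
    mean=mu), count ~ Poisson(lambda). ``dispersion = inf`` gives pure
    Poisson sampling.
    """
    config.validate()
    if not config.wells:
        raise ValueError("wells must be non-empty")
    genes, prog_df, _ = _gene_programs(config)
    prog = prog_df.to_numpy()
    _, _, well_root = _root_streams(config)
    well_streams = well_root.spawn(len(config.wells))

    blocks, cell_ids, well_of, type_of = [], [], [], []
    types = config.cell_types
    for well, ss in zip(config.wells, well_streams):
        rng = np.random.default_rng(ss)
        comp = effective_composition(config, well)
        t_idx = rng.choice(len(types), size=well.n_cells, p=comp)
        mu = config.mean_umis_per_cell * prog[:, t_idx].T  # cells x genes
        if np.isinf(config.dispersion):
            counts = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=config.dispersion, scale=mu / config.dispersion)
            counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
        cell_ids.extend(f"{well.well_id}_{i:05d}" for i in range(well.n_cells))
        well_of.extend([well.well_id] * well.n_cells)
        type_of.extend(types[i] for i in t_idx)

    X = sp.vstack(blocks, format="csr") if blocks else sp.csr_matrix((0, config.n_genes))
    obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    adata = AnnData(X=X, obs=obs, var=genes.drop(columns="gene_id").assign(gene_id=genes["gene_id"]))
    adata.var_names = genes.index

    truth_cells = pd.DataFrame(
        {"well_id": well_of, "cell_type": type_of}, index=adata.obs_names
    )
    hits = pd.DataFrame(
        [
            {
                "treatment": w.treatment,
                "dose_um": w.dose_um,
                "neuron_multiplier": w.neuron_multiplier,
            }
            for w in config.wells
            if w.neuron_multiplier != 1.0
        ],
        columns=["treatment", "dose_um", "neuron_multiplier"],
    )
    return adata, GroundTruth(truth_cells, prog_df, hits)


def simulate_hashes(config: SimConfig, truth: GroundTruth) -> HashCountTable:
    """Draw hash-oligo counts per cell.

    Each cell's ``hash_reads_per_cell`` reads are multinomial with
    probability (1 - eps) concentrated on the true well's hash and eps
    spread uniformly over all hashes (the true one included).
    """
    config.validate()
    if len(truth.cells) == 0:
        raise ValueError("ground truth contains no cells")
    _, hash_root, _ = _root_streams(config)
    hash_ids = [f"hash_{w.well_id}" for w in config.wells]
    hash_to_well = {h: w.well_id for h, w in zip(hash_ids, config.wells)}
    well_index = {w.well_id: j for j, w in enumerate(config.wells)}
    H = len(hash_ids)
    eps = config.hash_background_eps

    streams = hash_root.spawn(len(config.wells))
    counts = np.zeros((len(truth.cells), H), dtype=np.int64)
    well_arr = truth.cells["well_id"].to_numpy()
    for w, ss in zip(config.wells, streams):
        rows = np.flatnonzero(well_arr == w.well_id)
        if rows.size == 0:
            continue
        p = np.full(H, eps / H)
        p[well_index[w.well_id]] += 1.0 - eps
        rng = np.random.default_rng(ss)
        counts[rows] = rng.multinomial(config.hash_reads_per_cell, p, size=rows.size)
    df = pd.DataFrame(counts, index=truth.cells.index, columns=hash_ids)
    return HashCountTable(df, hash_to_well)


def simulate_screen(config: SimConfig) -> SimulatedDataset:
    """Full synthetic screen: expression + hashes + well manifest + truth."""
    config.validate()
    if not any(w.treatment == config.control_label for w in config.wells):
        raise ValueError(
            f"no control well: expected at least one well with treatment"
            f" {config.control_label!r}"
        )
    expr, truth = simulate_expression(config)
    hashes = simulate_hashes(config, truth)
    _, _, markers = _gene_programs(config)
    manifest = pd.DataFrame(
        [
            {
                "well_id": w.well_id,
                "hash_id": f"hash_{w.well_id}",
                "treatment": w.treatment,
                "dose_um": w.dose_um,
                "collection_day": w.collection_day,
            }
            for w in config.wells
        ]
    )
    return SimulatedDataset(expr, hashes, manifest, truth, markers, config)


def screen_design(
    n_treatments: int = 92,
    doses: Sequence[float] = (0.1, 1.0, 10.0),
    cells_per_well: int = 100,
    control_wells_per_day: int = 3,
    collection_days: Sequence[int] = (1, 2),
    planted_hits: Optional[dict[str, dict[float, float]]] = None,
    control_label: str = "Only Ascl1",
) -> list[WellSpec]:
    """Well layout for a chemical screen.

    Treatments are split across collection days; each day also carries
    ``control_wells_per_day`` control wells. ``planted_hits`` maps a
    treatment name to its per-dose neuron multiplier, e.g.
    ``{"drug_003": {10.0: 3.0, 1.0: 1.5}}``; unspecified doses default to 1.
    """
    planted_hits = planted_hits or {}
    wells: list[WellSpec] = []
    for t in range(n_treatments):
        name = f"drug_{t:03d}"
        day = collection_days[t % len(collection_days)]
        for d in doses:
            mult = planted_hits.get(name, {}).get(d, 1.0)
            wells.append(
                WellSpec(
                    well_id=f"W{len(wells):03d}",
                    treatment=name,
                    dose_um=d,
                    collection_day=day,
                    n_cells=cells_per_well,
                    neuron_multiplier=mult,
                )
            )
    for day in collection_days:
        for r in range(control_wells_per_day):
            wells.append(
                WellSpec(
                    well_id=f"W{len(wells):03d}",
                    treatment=control_label,
                    dose_um=None,
                    collection_day=day,
                    n_cells=cells_per_well,
                )
            )
    return wells


def timecourse_design(
    days: Sequence[int] = (0, 1, 2, 3, 4, 5),
    wells_per_condition: int = 2,
    cells_per_well: int = 200,
) -> list[WellSpec]:
    """Induction-timecourse layout: one condition per induction duration.

    Longer induction shifts the composition along the trajectory (fewer
    glia, more neuron-fated cells), emulating progressive reprogramming.
    """
    wells = []
    for day in days:
        # neuron multiplier grows with induction length; day 0 is uninduced
        mult = 1.0 if day == 0 else 1.0 + day
        for r in range(wells_per_condition):
            wells.append(
                WellSpec(
                    well_id=f"T{day}d_{r}",
                    treatment=f"dox_{day}d",
                    dose_um=None,
                    collection_day=day,
                    n_cells=cells_per_well,
                    neuron_multiplier=mult,
                )
            )
    return wells


def _config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["dispersion"] = float(config.dispersion) if np.isfinite(config.dispersion) else "inf"
    for w in d["wells"]:
        if w["composition"] is not None:
            w["composition"] = [float(x) for x in w["composition"]]
    return d


def write_dataset(ds: SimulatedDataset, outdir: str) -> None:
    """Write the dataset in the pipeline's input formats.

    Expression and hash tables go out gene x cell / hash x cell as
    matrix-market MTX with TSV sidecars; the well manifest, ground truth,
    marker panel and the echoed config are plain text.
    """
    os.makedirs(outdir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(outdir, "expr.mtx"), ds.expr.X.T.astype(np.int64).tocoo()
    )
    ds.expr.var[["gene_id", "gene_name", "is_mito"]].to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"cell_id": ds.expr.obs_names}).to_csv(
        os.path.join(outdir, "cells.tsv"), sep="\t", index=False
    )
    scipy.io.mmwrite(
        os.path.join(outdir, "hash.mtx"),
        sp.coo_matrix(ds.hashes.counts.to_numpy().T),
    )
    pd.DataFrame({"hash_id": ds.hashes.hash_ids}).to_csv(
        os.path.join(outdir, "hashes.tsv"), sep="\t", index=False
    )
    ds.manifest.to_csv(os.path.join(outdir, "wells.tsv"), sep="\t", index=False)
    ds.truth.cells.rename_axis("cell_id").to_csv(
        os.path.join(outdir, "ground_truth.tsv"), sep="\t"
    )
    with open(os.path.join(outdir, "markers.yaml"), "w") as fh:
        yaml.safe_dump({k: [str(g) for g in v] for k, v in ds.markers.items()}, fh)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(_config_to_dict(ds.config), fh)
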