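"""End-to-end orchestration: I/O, presets, and staged runs.

A run executes demultiplex -> QC -> embed -> cluster -> annotate and then
either the trajectory stage (timecourse/pulse presets) or the hit-calling
stage (screen preset). Every paper-facing parameter is surfaced on
:class:`RunConfig`; presets fill in the printed defaults. All outputs are
TSV with fixed column order so reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml
from anndata import AnnData

from . import cluster_annotate as ca
from . import demux as dx
from . import screen as sc
from . import trajectory as tj

logger = logging.getLogger("plexscreen")


@dataclass
class InputPaths:
    expr_mtx: str
    genes_tsv: str
    cells_tsv: str
    hash_mtx: Optional[str] = None
    hashes_tsv: Optional[str] = None
    wells_tsv: Optional[str] = None
    markers_yaml: Optional[str] = None

    @classmethod
    def from_dir(cls, d: str) -> "InputPaths":
        def opt(name):
            p = os.path.join(d, name)
            return p if os.path.exists(p) else None

        return cls(
            expr_mtx=os.path.join(d, "expr.mtx"),
            genes_tsv=os.path.join(d, "genes.tsv"),
            cells_tsv=os.path.join(d, "cells.tsv"),
            hash_mtx=opt("hash.mtx"),
            hashes_tsv=opt("hashes.tsv"),
            wells_tsv=opt("wells.tsv"),
            markers_yaml=opt("markers.yaml"),
        )


def read_inputs(
    paths: InputPaths,
) -> tuple[AnnData, Optional[dx.HashCountTable], Optional[pd.DataFrame], Optional[dict]]:
    """Parse the matrix-market inputs and their TSV sidecars.

    Expression is stored gene x cell on disk and returned cells x genes;
    the hash table is hash x cell on disk. Dimension mismatches between a
    matrix and its sidecars are rejected with the offending counts; a well
    manifest referencing an unknown hash id is rejected naming the id.
    """
    X = sp.csr_matrix(scipy.io.mmread(paths.expr_mtx)).T
    genes = pd.read_csv(paths.genes_tsv, sep="\t")
    cells = pd.read_csv(paths.cells_tsv, sep="\t")
    if X.shape[1] != len(genes):
        raise ValueError(
            f"expression matrix has {X.shape[1]} genes but genes.tsv lists {len(genes)}"
        )
    if X.shape[0] != len(cells):
        raise ValueError(
            f"expression matrix has {X.shape[0]} cells but cells.tsv lists {len(cells)}"
        )
    if "is_mito" not in genes:
        genes["is_mito"] = False
    var = genes.set_index(pd.Index(genes["gene_id"].astype(str)))
    adata = AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(cells["cell_id"].astype(str), name="cell_id")),
        var=var,
    )

    hashes = manifest = markers = None
    if paths.hash_mtx and paths.hashes_tsv:
        H = np.asarray(sp.csr_matrix(scipy.io.mmread(paths.hash_mtx)).T.todense())
        hash_ids = pd.read_csv(paths.hashes_tsv, sep="\t")["hash_id"].astype(str)
        if H.shape[1] != len(hash_ids):
            raise ValueError(
                f"hash matrix has {H.shape[1]} hashes but hashes.tsv lists {len(hash_ids)}"
            )
        if H.shape[0] != len(cells):
            raise ValueError(
                f"hash matrix has {H.shape[0]} cells but cells.tsv lists {len(cells)}"
            )
        if paths.wells_tsv is None:
            raise ValueError("hash matrix given without a wells.tsv manifest")
        manifest = pd.read_csv(paths.wells_tsv, sep="\t")
        unknown = sorted(set(manifest["hash_id"].astype(str)) - set(hash_ids))
        if unknown:
            raise ValueError(f"manifest references unknown hash id(s): {unknown}")
        hash_to_well = dict(
            zip(manifest["hash_id"].astype(str), manifest["well_id"].astype(str))
        )
        counts = pd.DataFrame(H, index=adata.obs_names, columns=list(hash_ids))
        hashes = dx.HashCountTable(counts, hash_to_well)
    if paths.markers_yaml:
        with open(paths.markers_yaml) as fh:
            markers = yaml.safe_load(fh)
    return adata, hashes, manifest, markers


@dataclass
class RunConfig:
    """One pipeline run: preset defaults plus explicit overrides."""

    preset: str
    input_dir: str
    outdir: str
    seed: int = 0
    qc: dx.QCConfig = field(default_factory=dx.QCConfig)
    embed: ca.EmbedConfig = field(default_factory=ca.EmbedConfig)
    window: tuple[float, float] | str = (10.0, 20.0)  # or "auto" (quantile window)
    threshold: Optional[float] = 16.0
    control_label: str = "Only Ascl1"
    mg_label: str = "MG"
    min_cells: int = 20
    merge_map: Mapping[str, str] = field(
        default_factory=lambda: dict(sc.DEFAULT_MERGE_MAP)
    )
    deg_min_cells: int = 50
    compute_layout: bool = True
    score_floor: float = 0.05


#: Which analysis branch each preset runs after annotation.
PRESET_KIND = {
    "timecourse": "trajectory",
    "pulse": "trajectory",
    "screen": "screen",
    "subcluster": "annotate",
    "invivo": "annotate",
}


def make_run_config(preset: str, input_dir: str, outdir: str, seed: int = 0, **overrides) -> RunConfig:
    """Build a RunConfig with the preset's printed QC/embedding defaults."""
    if preset not in PRESET_KIND:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESET_KIND)}")
    qc_key = preset if preset in dx.QC_PRESETS else "invivo_d5"
    cfg = RunConfig(
        preset=preset,
        input_dir=input_dir,
        outdir=outdir,
        seed=seed,
        qc=dataclasses.replace(dx.QC_PRESETS[qc_key]),
        embed=dataclasses.replace(ca.EMBED_PRESETS.get(preset, ca.EmbedConfig())),
    )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown RunConfig field {key!r}")
        setattr(cfg, key, val)
    return cfg


def _echo_config(cfg: RunConfig, path: str) -> None:
    d = dataclasses.asdict(cfg)
    d["merge_map"] = dict(cfg.merge_map)
    d["window"] = cfg.window if isinstance(cfg.window, str) else list(cfg.window)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def run_preset(cfg: RunConfig) -> dict:
    """Execute the preset's full stage sequence and write all outputs.

    Returns a summary dict (per-stage cell counts plus branch results).
    On a stage failure the partial outputs stay on disk together with an
    ``INCOMPLETE`` flag naming the failed stage.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    log_path = os.path.join(cfg.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    summary: dict = {"preset": cfg.preset, "seed": cfg.seed}
    try:
        stage = "read_inputs"
        adata, hashes, manifest, markers = read_inputs(
            InputPaths.from_dir(cfg.input_dir)
        )
        summary["n_cells_in"] = adata.n_obs
        logger.info("read %d cells x %d genes", adata.n_obs, adata.n_vars)

        stage = "demux"
        demux = None
        if hashes is not None and cfg.qc.ratio_min is not None:
            demux = dx.call_hashes(
                hashes, ratio_min=cfg.qc.ratio_min, ratio_strict=cfg.qc.ratio_strict
            )
            summary["hash_recovery_rate"] = demux.hash_recovery_rate
            logger.info("hash recovery rate %.3f", demux.hash_recovery_rate)

        stage = "qc"
        cells, report = dx.filter_cells(adata, demux, cfg.qc, manifest)
        removed = sum(v for k, v in report.items() if k.startswith("removed_"))
        assert report["n_in"] == report["n_retained"] + removed, "cell-count conservation"
        summary["qc"] = report
        logger.info("QC retained %d of %d cells", report["n_retained"], report["n_in"])
        pd.DataFrame([report]).to_csv(
            os.path.join(cfg.outdir, "qc_report.tsv"), sep="\t", index=False
        )

        stage = "embed"
        emb = ca.embed(
            adata, cells, cfg.embed, seed=cfg.seed, compute_layout=cfg.compute_layout
        )
        if emb.layout is not None:
            cells["umap_1"] = emb.layout[:, 0]
            cells["umap_2"] = emb.layout[:, 1]

        stage = "cluster"
        labels = ca.cluster(emb.graph, cfg.embed.cluster_resolution, seed=cfg.seed)
        cells["cluster"] = labels
        summary["n_clusters"] = int(len(np.unique(labels)))
        logger.info("found %d clusters", summary["n_clusters"])

        stage = "annotate"
        if markers:
            cluster_table, per_cell = ca.annotate_clusters(
                adata, cells, labels, markers, score_floor=cfg.score_floor
            )
            cells["cell_type"] = per_cell
            cluster_table.to_csv(os.path.join(cfg.outdir, "clusters.tsv"), sep="\t")
        else:
            cells["cell_type"] = pd.Series(
                [f"cluster_{c}" for c in labels], index=cells.index
            )

        kind = PRESET_KIND[cfg.preset]
        if kind == "screen":
            stage = "hits"
            comp = sc.build_composition(cells, cfg.merge_map, min_cells=cfg.min_cells)
            sc.size_factors(comp)
            hits = sc.fold_changes(comp, control_label=cfg.control_label)
            totals = sc.total_cell_counts(cells)
            comp.counts.to_csv(os.path.join(cfg.outdir, "composition.tsv"), sep="\t")
            hits.to_csv(os.path.join(cfg.outdir, "hits.tsv"), sep="\t", index=False)
            totals.to_csv(os.path.join(cfg.outdir, "totals.tsv"), sep="\t", index=False)
            if len(comp.retained) >= 2:
                tc = sc.cluster_treatments(comp)
                pd.DataFrame({"condition": tc.leaf_order}).to_csv(
                    os.path.join(cfg.outdir, "treatment_order.tsv"), sep="\t", index=False
                )
            summary["n_conditions_retained"] = int(len(comp.retained))
            neuron = hits[(hits["cell_type"] == "Neuron") & hits["retained"]]
            if len(neuron):
                top = neuron.sort_values(
                    ["fc", "condition"], ascending=[False, True], kind="mergesort"
                ).iloc[0]
                summary["top_neuron_condition"] = str(top["condition"])
                summary["top_neuron_fc"] = float(top["fc"])
        elif kind == "trajectory":
            stage = "trajectory"
            mg_mask = (cells["cell_type"] == cfg.mg_label).to_numpy()
            pt = tj.pseudotime(emb.pcs, cells.index, mg_mask, graph=emb.graph)
            cells["pseudotime"] = pt.tau
            if cfg.window == "auto":
                # synthetic runs: window spanning the bulk of the trajectory
                finite = pt.tau.to_numpy()[np.isfinite(pt.tau.to_numpy())]
                lo, hi = (float(q) for q in np.quantile(finite, [0.25, 0.75]))
            else:
                lo, hi = cfg.window
            try:
                tau_star = tj.commitment_point(pt.tau.to_numpy(), lo, hi)
            except ValueError:
                tau_star = None
            summary["commitment_point"] = tau_star
            summary["partition_threshold"] = (
                tau_star if tau_star is not None else cfg.threshold
            )
            totals_umi = cells["n_umi"].to_numpy(dtype=float)
            sf = ca.cell_size_factors(totals_umi)
            sub = adata[cells.index.to_numpy()]
            deg = tj.pseudotime_deg(
                sp.csr_matrix(sub.X),
                list(sub.var_names),
                pt.tau.to_numpy(),
                size_factors=sf,
                lo=lo,
                hi=hi,
                min_cells=cfg.deg_min_cells,
            )
            deg.to_csv(os.path.join(cfg.outdir, "deg.tsv"), sep="\t", index=False)
            kept = deg.loc[deg["retained"], "gene"]
            if len(kept) >= 3:
                gidx = pd.Index(sub.var_names).get_indexer(kept)
                modules, heat = tj.gene_modules(
                    sp.csr_matrix(sub.X)[:, gidx],
                    list(kept),
                    pt.tau.to_numpy(),
                    size_factors=sf,
                    seed=cfg.seed,
                )
                modules.rename_axis("gene").to_csv(
                    os.path.join(cfg.outdir, "modules.tsv"), sep="\t"
                )
                heat.to_csv(os.path.join(cfg.outdir, "heatmap.tsv"), sep="\t")
            summary["n_deg_retained"] = int(deg["retained"].sum())

        stage = "write"
        cells.rename_axis("cell_id").to_csv(
            os.path.join(cfg.outdir, "cells.tsv"), sep="\t"
        )
        _echo_config(cfg, os.path.join(cfg.outdir, "config.yaml"))
        flag = os.path.join(cfg.outdir, "INCOMPLETE")
        if os.path.exists(flag):
            os.remove(flag)
        return summary
    except Exception as exc:
        with open(os.path.join(cfg.outdir, "INCOMPLETE"), "w") as fh:
            fh.write(f"failed at stage: {stage}\n{exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
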