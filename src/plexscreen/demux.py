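"""Hash demultiplexing and cell-level quality control.

Each nucleus carries counts of well-specific polyadenylated hash oligos.
The confidence statistic for assigning a nucleus to a well is the
``top_to_second_best_ratio``: the count of the most abundant hash divided
by the count of the second most abundant hash. Cells are retained when the
ratio clears a preset-specific threshold and their UMI total / mitochondrial
fraction fall inside the preset's bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from anndata import AnnData


@dataclass
class HashCountTable:
    """Per-cell counts of each well hash oligo.

    Parameters
    ----------
    counts
        cells x hashes non-negative integer counts.
    hash_to_well
        Maps each hash id (column of ``counts``) to the well it labels.
    """

    counts: pd.DataFrame
    hash_to_well: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()]
            raise ValueError(f"duplicate hash ids: {sorted(set(dupes))}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("hash counts must be non-negative")

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def hash_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class DemuxResult:
    """Per-cell hash call with the top-to-second-best ratio.

    ``assignments`` has one row per cell with columns ``best_hash``,
    ``second_hash``, ``ratio`` and ``assigned_well`` (NaN when the cell does
    not clear the ratio threshold or has no hash reads).
    """

    assignments: pd.DataFrame
    ratio_min: Optional[float]
    ratio_strict: bool

    @property
    def hash_recovery_rate(self) -> float:
        return hash_recovery_rate(self)


@dataclass
class QCConfig:
    """Cell-retention thresholds.

    UMI bounds are strict on both sides (a cell is discarded when its UMI
    total is *below* ``umi_min`` or *above* ``umi_max``; a cell exactly at a
    bound is kept). ``ratio_strict`` selects between the two threshold
    dialects: retain ratio > ``ratio_min`` (strict) versus discard
    ratio < ``ratio_min`` (non-strict, i.e. a cell exactly at the threshold
    is retained). ``mito_max`` discards cells whose mitochondrial UMI
    fraction exceeds it; ``None`` disables the filter. ``ratio_min=None``
    disables hash-based filtering (droplet data with no hashing step).
    """

    umi_min: int = 500
    umi_max: int = 20_000
    ratio_min: Optional[float] = 5.0
    ratio_strict: bool = False
    mito_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.umi_min >= self.umi_max:
            raise ValueError("umi_min must be < umi_max")
        if self.mito_max is not None and not 0 <= self.mito_max <= 1:
            raise ValueError("mito_max must be in [0, 1]")


#: Per-experiment QC presets. The timecourse retains ratio > 4, the pulse
#: ratio > 5, and the screen discards ratio < 5 together with cells above
#: 15% mitochondrial reads. The droplet (in-vivo) presets use higher UMI
#: floors and no hash step.
QC_PRESETS: Mapping[str, QCConfig] = {
    "timecourse": QCConfig(500, 20_000, ratio_min=4.0, ratio_strict=True),
    "pulse": QCConfig(500, 20_000, ratio_min=5.0, ratio_strict=True),
    "screen": QCConfig(500, 20_000, ratio_min=5.0, ratio_strict=False, mito_max=0.15),
    "invivo_d5": QCConfig(2_500, 10**9, ratio_min=None),
    "invivo_d9": QCConfig(3_000, 10**9, ratio_min=None),
    "invivo_d21": QCConfig(2_500, 10**9, ratio_min=None),
}


def call_hashes(
    hashes: HashCountTable,
    ratio_min: Optional[float] = 5.0,
    ratio_strict: bool = False,
) -> DemuxResult:
    """Assign each cell to a well from its hash counts.

    For each cell the ratio r = count(best hash) / count(second hash) is
    computed. Conventions: a second-best count of 0 with a positive best
    gives r = +inf (maximally unambiguous, assigned); a tie for the best
    hash gives r = 1 (ambiguous, unassigned under any threshold > 1); a
    cell with no hash reads has an undefined ratio and stays unassigned.
    """
    if hashes.counts.shape[0] == 0:
        raise ValueError("hash count table has no cells")
    missing = [h for h in hashes.hash_ids if h not in hashes.hash_to_well]
    if missing:
        raise KeyError(f"hash ids missing from the well map: {missing}")

    arr = hashes.counts.to_numpy(dtype=np.int64)
    n_cells, n_hashes = arr.shape
    best_idx = np.argmax(arr, axis=1)
    best = arr[np.arange(n_cells), best_idx]
    if n_hashes > 1:
        masked = arr.copy()
        masked[np.arange(n_cells), best_idx] = -1
        second_idx = np.argmax(masked, axis=1)
        second = masked[np.arange(n_cells), second_idx]
    else:
        second_idx = best_idx
        second = np.zeros(n_cells, dtype=np.int64)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(second > 0, best / np.maximum(second, 1), np.inf)
    ratio = np.where(best > 0, ratio, np.nan)  # no reads: undefined

    passes = best > 0
    if ratio_min is not None:
        with np.errstate(invalid="ignore"):
            passes &= (ratio > ratio_min) if ratio_strict else (ratio >= ratio_min)

    hash_names = hashes.hash_ids.to_numpy()
    wells = np.array([hashes.hash_to_well[h] for h in hash_names], dtype=object)
    df = pd.DataFrame(
        {
            "best_hash": np.where(best > 0, hash_names[best_idx], None),
            "second_hash": np.where(second > 0, hash_names[second_idx], None),
            "ratio": ratio,
            "assigned_well": np.where(passes, wells[best_idx], None),
        },
        index=hashes.cell_ids,
    )
    return DemuxResult(df, ratio_min=ratio_min, ratio_strict=ratio_strict)


def hash_recovery_rate(demux: DemuxResult) -> float:
    """Fraction of cells with a well assignment."""
    n = len(demux.assignments)
    if n == 0:
        raise ValueError("no cells in demux result")
    return float(demux.assignments["assigned_well"].notna().sum() / n)


def mito_fraction(expr: AnnData) -> pd.Series:
    """Per-cell fraction of UMIs in genes flagged ``is_mito``.

    Computed on the full gene set, before any gene filtering.
    """
    totals = np.asarray(expr.X.sum(axis=1)).ravel()
    if "is_mito" in expr.var:
        mito = np.asarray(
            expr[:, expr.var["is_mito"].astype(bool).to_numpy()].X.sum(axis=1)
        ).ravel()
    else:
        mito = np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return pd.Series(frac, index=expr.obs_names, name="mito_frac")


def filter_cells(
    expr: AnnData,
    demux: Optional[DemuxResult],
    qc: QCConfig,
    manifest: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the QC filters and build the per-cell metadata table.

    Returns ``(cells, report)`` where ``cells`` is indexed by cell id with
    columns ``n_umi``, ``mito_frac``, ``ratio``, ``well`` and — when a well
    manifest is given — ``treatment``, ``dose_um``, ``collection_day``.
    ``report`` counts the cells removed by each rule (a cell failing several
    rules is attributed to the first in the fixed order: hash, umi_low,
    umi_high, mito) and satisfies
    ``n_in == n_retained + sum(removed.values())``.
    """
    n_umi = pd.Series(
        np.asarray(expr.X.sum(axis=1)).ravel(), index=expr.obs_names, name="n_umi"
    )
    cells = pd.DataFrame({"n_umi": n_umi, "mito_frac": mito_fraction(expr)})
    if demux is not None:
        sub = demux.assignments.reindex(cells.index)
        cells["ratio"] = sub["ratio"]
        cells["well"] = sub["assigned_well"]
        ok_hash = sub["assigned_well"].notna().to_numpy()
    else:
        cells["ratio"] = np.nan
        cells["well"] = None
        ok_hash = np.ones(len(cells), dtype=bool)

    ok_lo = cells["n_umi"].to_numpy() >= qc.umi_min
    ok_hi = cells["n_umi"].to_numpy() <= qc.umi_max
    if qc.mito_max is not None:
        ok_mito = cells["mito_frac"].to_numpy() <= qc.mito_max
    else:
        ok_mito = np.ones(len(cells), dtype=bool)

    # first-failing-rule attribution keeps the counts additive
    fail_hash = ~ok_hash
    fail_lo = ok_hash & ~ok_lo
    fail_hi = ok_hash & ok_lo & ~ok_hi
    fail_mito = ok_hash & ok_lo & ok_hi & ~ok_mito
    keep = ok_hash & ok_lo & ok_hi & ok_mito

    report = {
        "n_in": int(len(cells)),
        "removed_hash": int(fail_hash.sum()),
        "removed_umi_low": int(fail_lo.sum()),
        "removed_umi_high": int(fail_hi.sum()),
        "removed_mito": int(fail_mito.sum()),
        "n_retained": int(keep.sum()),
    }
    retained = cells.loc[keep].copy()
    if manifest is not None and demux is not None:
        meta = manifest.drop_duplicates("well_id").set_index("well_id")
        for col in ("treatment", "dose_um", "collection_day"):
            if col in meta:
                retained[col] = retained["well"].map(meta[col])
    if len(retained) == 0:
        warnings.warn("all cells removed by QC filtering", stacklevel=2)
    return retained, report
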