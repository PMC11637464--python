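"""Cell-type-composition hit calling for the chemical screen.

Annotated cells are tabulated into a cell-type x condition matrix
(condition = treatment x dose x collection day), neuron-fated subtypes are
merged, conditions with fewer than 20 recovered cells are dropped, the
columns are size-factor adjusted (column total over the geometric mean of
retained column totals), and each condition's adjusted counts are compared
to the control condition collected on the same day as a fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

#: Default cell-type merge used for hit calling: neuron-fated precursor and
#: bipolar states pool into "Neuron"; early/late progenitor-like pool into
#: "ProL".
DEFAULT_MERGE_MAP: Mapping[str, str] = {
    "BP": "Neuron",
    "NeuPre": "Neuron",
    "ProL (early)": "ProL",
    "ProL (late)": "ProL",
    # canonical types that stay under their own name
    "MG": "MG",
    "ProL": "ProL",
    "Transition": "Transition",
    "Microglia": "Microglia",
    "Astrocyte": "Astrocyte",
    "FibroL": "FibroL",
    "Unknown": "Unknown",
}

CONDITION_SEP = "|"


def condition_id(treatment, dose_um, collection_day) -> str:
    dose = "NA" if dose_um is None or (isinstance(dose_um, float) and np.isnan(dose_um)) else f"{dose_um:g}"
    return f"{treatment}{CONDITION_SEP}{dose}{CONDITION_SEP}{collection_day}"


@dataclass
class CompositionMatrix:
    """Cell-type x condition counts with per-condition size factors.

    ``counts`` holds all conditions; ``meta`` (indexed like the columns)
    carries treatment/dose/collection, the column total, and the
    ``retained`` flag (total >= the minimum cell count). ``size_factors``
    are defined for retained conditions only and have geometric mean 1.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    size_factors: Optional[pd.Series] = None
    merge_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_MERGE_MAP))

    @property
    def retained(self) -> pd.Index:
        return self.meta.index[self.meta["retained"]]

    def adjusted(self) -> pd.DataFrame:
        """Size-factor-adjusted counts over retained conditions."""
        if self.size_factors is None:
            raise ValueError("size factors have not been computed")
        cols = self.retained
        return self.counts[cols] / self.size_factors[cols]


def build_composition(
    cells: pd.DataFrame,
    merge_map: Mapping[str, str] = DEFAULT_MERGE_MAP,
    min_cells: int = 20,
) -> CompositionMatrix:
    """Tabulate annotated cells into the composition matrix.

    ``cells`` needs ``cell_type``, ``treatment``, ``dose_um`` and
    ``collection_day`` columns. Cell types absent from ``merge_map`` keep
    their own name. Conditions recovering fewer than ``min_cells`` cells
    are flagged not retained (dropped before size factors and fold
    changes).
    """
    required = {"cell_type", "treatment", "dose_um", "collection_day"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table lacks columns: {sorted(missing)}")
    df = cells.copy()
    unknown = sorted(set(df["cell_type"]) - set(merge_map))
    if merge_map and unknown:
        warnings.warn(
            f"cell types not in the merge map kept as-is: {unknown}", stacklevel=2
        )
    df["merged_type"] = df["cell_type"].map(lambda t: merge_map.get(t, t))
    df["condition"] = [
        condition_id(t, d, c)
        for t, d, c in zip(df["treatment"], df["dose_um"], df["collection_day"])
    ]
    counts = (
        df.groupby(["merged_type", "condition"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    meta = (
        df.drop_duplicates("condition")
        .set_index("condition")[["treatment", "dose_um", "collection_day"]]
        .loc[counts.columns]
    )
    meta["total"] = counts.sum(axis=0)
    meta["retained"] = meta["total"] >= min_cells
    return CompositionMatrix(counts, meta, merge_map=dict(merge_map))


def size_factors(comp: CompositionMatrix) -> pd.Series:
    """Per-condition size factors over retained conditions.

    s_t = (column total of t) / geometric mean of retained column totals;
    by construction the geometric mean of s over retained conditions is 1.
    """
    cols = comp.retained
    if len(cols) == 0:
        raise ValueError("no retained conditions")
    totals = comp.meta.loc[cols, "total"].astype(float)
    assert (totals > 0).all(), "retained condition with zero total"
    s = totals / np.exp(np.log(totals).mean())
    comp.size_factors = s
    return s


def fold_changes(
    comp: CompositionMatrix,
    control_label: str = "Only Ascl1",
    by_collection: bool = True,
) -> pd.DataFrame:
    """Per condition x cell type fold change versus the control condition.

    FC(t, type) = adjusted count(t, type) / adjusted count(control, type),
    where the control is the ``control_label`` condition collected on t's
    collection day (``by_collection=True``) or the single pooled control.
    A control adjusted count of 0 leaves FC undefined (NaN) with
    ``control_zero`` flagged. Conditions below the cell floor appear with
    ``retained=False`` and no FC.
    """
    if comp.size_factors is None:
        size_factors(comp)
    adj = comp.adjusted()
    meta = comp.meta
    is_ctrl = meta["treatment"] == control_label

    ctrl_for_day: dict = {}
    if by_collection:
        days = sorted(meta.loc[meta["retained"], "collection_day"].unique())
        missing_days = []
        for day in days:
            cands = meta.index[
                is_ctrl & (meta["collection_day"] == day) & meta["retained"]
            ]
            if len(cands) == 0:
                missing_days.append(int(day))
            else:
                ctrl_for_day[day] = cands[0]
        if missing_days:
            raise ValueError(
                f"no retained {control_label!r} control for collection day(s)"
                f" {missing_days}"
            )
    else:
        cands = meta.index[is_ctrl & meta["retained"]]
        if len(cands) == 0:
            raise ValueError(f"no retained {control_label!r} control condition")
        ctrl_for_day = {day: cands[0] for day in meta["collection_day"].unique()}

    rows = []
    for cond in comp.counts.columns:
        m = meta.loc[cond]
        retained = bool(m["retained"])
        ctrl = ctrl_for_day.get(m["collection_day"]) if retained else None
        for cell_type in comp.counts.index:
            count = int(comp.counts.loc[cell_type, cond])
            fc = np.nan
            control_zero = False
            if retained and ctrl is not None:
                denom = adj.loc[cell_type, ctrl]
                if denom == 0:
                    control_zero = True
                else:
                    fc = float(adj.loc[cell_type, cond] / denom)
            rows.append(
                {
                    "condition": cond,
                    "treatment": m["treatment"],
                    "dose_um": m["dose_um"],
                    "collection_day": m["collection_day"],
                    "cell_type": cell_type,
                    "count": count,
                    "total_cells": int(m["total"]),
                    "size_factor": float(comp.size_factors[cond]) if retained else np.nan,
                    "fc": fc,
                    "control_zero": control_zero,
                    "control_condition": ctrl,
                    "retained": retained,
                }
            )
    return pd.DataFrame(rows)


def total_cell_counts(cells: pd.DataFrame) -> pd.DataFrame:
    """Total recovered cells per condition (all cell types), descending."""
    df = cells.copy()
    df["condition"] = [
        condition_id(t, d, c)
        for t, d, c in zip(df["treatment"], df["dose_um"], df["collection_day"])
    ]
    out = (
        df.groupby("condition", sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
        .sort_values(["n_cells", "condition"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


@dataclass
class TreatmentClustering:
    proportions: pd.DataFrame  # condition x cell type, rows sum to 1
    linkage: np.ndarray
    leaf_order: list[str]


def cluster_treatments(comp: CompositionMatrix) -> TreatmentClustering:
    """Average-linkage hierarchical clustering of condition compositions.

    Rows are retained conditions' cell-type proportions (summing to 1);
    distances are Euclidean. Conditions are sorted lexicographically
    before linkage so the tree does not depend on input order.
    """
    cols = sorted(comp.retained)
    if len(cols) < 2:
        raise ValueError("treatment clustering needs >= 2 retained conditions")
    props = comp.counts[cols].T
    props = props.div(props.sum(axis=1), axis=0)
    Z = linkage(props.to_numpy(), method="average", metric="euclidean")
    order = [props.index[i] for i in leaves_list(Z)]
    return TreatmentClustering(props, Z, order)
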