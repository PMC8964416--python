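"""Core- and patient-level immune quantification.

Scores per TMA core:

* ``immune_score`` — count of segmented cells positive for any of
  CD45/CD3/CD4/CD8 and negative for the epithelial marker AE1.
* ``stroma_score`` — percent of non-epithelial-mask cells that are negative
  for AE1 and all immune markers (i.e. unclassified stromal cells), of all
  cells in the non-epithelial region.
* percent-of-total for the five single markers and six T-cell subtypes.

Per patient: the unweighted mean percent over assessable cores (patients
need at least two assessable cores), and the immune "hot-spot" core — the
core with the highest CD3 count (single-marker mode) or highest total
T-cell count (multi-marker mode).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import IMMUNE_SCORE_MARKERS, SINGLE_MARKERS, T_CELL_CLASSES

__all__ = [
    "immune_score",
    "stroma_score",
    "percent_of_total",
    "compartment_split",
    "core_score_table",
    "patient_average",
    "hotspot_select",
]

#: Quantities reported as percent-of-total per core.
PCT_QUANTITIES: tuple[str, ...] = tuple(SINGLE_MARKERS) + tuple(T_CELL_CLASSES)


def _require_markers(positivity: pd.DataFrame, markers) -> None:
    missing = set(markers) - set(positivity.columns)
    if missing:
        raise ValueError(f"positivity table missing markers: {sorted(missing)}")


def immune_score(positivity: pd.DataFrame) -> int:
    """Count immune cells: positive for any of CD45/CD3/CD4/CD8, AE1-negative."""
    _require_markers(positivity, IMMUNE_SCORE_MARKERS + ("AE1",))
    any_immune = positivity[list(IMMUNE_SCORE_MARKERS)].any(axis=1)
    return int((any_immune & ~positivity["AE1"].astype(bool)).sum())


def stroma_score(cells: pd.DataFrame, positivity: pd.DataFrame) -> float:
    """Percent of non-epithelial-region cells that are unclassified stroma.

    Stromal cells are outside the epithelial mask and negative for AE1 and
    every immune marker.  Returns NaN (undefined) when the core has no
    cells outside the epithelial mask.
    """
    _require_markers(positivity, IMMUNE_SCORE_MARKERS + ("AE1",))
    outside = ~cells["in_epithelial_mask"].astype(bool)
    n_outside = int(outside.sum())
    if n_outside == 0:
        return float("nan")
    any_immune = positivity[list(IMMUNE_SCORE_MARKERS)].any(axis=1)
    stromal = outside & ~positivity["AE1"].astype(bool) & ~any_immune
    return 100.0 * int(stromal.sum()) / n_outside


def percent_of_total(count: int, total: int) -> float:
    """Percent of total segmented cells; errors on an empty core."""
    if total <= 0:
        raise ValueError("percent_of_total undefined for an empty core")
    return 100.0 * count / total


def compartment_split(cells: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Per-subtype counts split by epithelial-mask membership.

    Returns one row per T-cell subtype with ``epithelial`` and ``stromal``
    counts; the two columns sum to the subtype total.
    """
    in_mask = cells["in_epithelial_mask"].astype(bool).to_numpy()
    rows = []
    cls = classes.to_numpy()
    for subtype in T_CELL_CLASSES:
        member = cls == subtype
        rows.append(
            {
                "subtype": subtype,
                "epithelial": int((member & in_mask).sum()),
                "stromal": int((member & ~in_mask).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("subtype")


def core_score_table(
    cells: pd.DataFrame,
    positivity: pd.DataFrame,
    classes: pd.Series,
    cores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per core: immune/stroma scores, counts and percents.

    ``positivity`` and ``classes`` must be aligned with ``cells`` (same
    index).  When ``cores`` is given, its ``patient_id`` and ``assessable``
    columns are joined in and non-assessable cores are retained but flagged.
    """
    if not cells.index.equals(positivity.index):
        raise ValueError("cells and positivity must share an index")
    if not cells.index.equals(classes.index):
        raise ValueError("cells and classes must share an index")

    rows = []
    for core_id, idx in cells.groupby("core_id").groups.items():
        sub_cells = cells.loc[idx]
        sub_pos = positivity.loc[idx]
        sub_cls = classes.loc[idx]
        n = len(sub_cells)
        row: dict = {
            "core_id": core_id,
            "patient_id": sub_cells["patient_id"].iloc[0],
            "n_cells": n,
            "immune_score": immune_score(sub_pos),
            "stroma_score": stroma_score(sub_cells, sub_pos),
        }
        row["stroma_score_defined"] = not np.isnan(row["stroma_score"])
        for marker in SINGLE_MARKERS:
            c = int(sub_pos[marker].sum())
            row[f"n_{marker}"] = c
            row[f"pct_{marker}"] = percent_of_total(c, n)
        class_counts = sub_cls.value_counts()
        for subtype in T_CELL_CLASSES:
            c = int(class_counts.get(subtype, 0))
            row[f"n_{subtype}"] = c
            row[f"pct_{subtype}"] = percent_of_total(c, n)
        row["n_tcell"] = int(sum(class_counts.get(s, 0) for s in T_CELL_CLASSES))
        split = compartment_split(sub_cells, sub_cls)
        for subtype in T_CELL_CLASSES:
            row[f"n_{subtype}_epithelial"] = int(split.loc[subtype, "epithelial"])
            row[f"n_{subtype}_stromal"] = int(split.loc[subtype, "stromal"])
        rows.append(row)
    table = pd.DataFrame(rows)
    if cores is not None:
        meta_cols = ["core_id"] + [
            c for c in ("assessable",) if c in cores.columns
        ]
        table = table.drop(columns=["assessable"], errors="ignore").merge(
            cores[meta_cols], on="core_id", how="left"
        )
        if "assessable" in table.columns:
            table["assessable"] = table["assessable"].fillna(True).astype(bool)
    else:
        table["assessable"] = True
    return table.sort_values("core_id").reset_index(drop=True)


def patient_average(
    core_scores: pd.DataFrame, weighted: bool = False, min_cores: int = 2
) -> pd.DataFrame:
    """Per-patient mean percent over assessable cores.

    Patients with fewer than ``min_cores`` assessable cores are excluded
    (one core cannot reflect intra-tumor heterogeneity).  The default mean
    is unweighted across cores; ``weighted=True`` weights by core cell
    count instead.
    """
    ok = core_scores[core_scores["assessable"]].copy()
    n_cores = ok.groupby("patient_id").size()
    eligible = n_cores.index[n_cores >= min_cores]
    ok = ok[ok["patient_id"].isin(eligible)]
    pct_cols = [f"pct_{q}" for q in PCT_QUANTITIES]

    if weighted:
        def agg(g: pd.DataFrame) -> pd.Series:
            w = g["n_cells"].to_numpy(dtype=float)
            return pd.Series(
                {c: float(np.average(g[c], weights=w)) for c in pct_cols}
            )
        out = ok.groupby("patient_id").apply(agg, include_groups=False)
    else:
        out = ok.groupby("patient_id")[pct_cols].mean()
    out["n_assessable_cores"] = n_cores.loc[out.index]
    return out.reset_index()


def hotspot_select(core_scores: pd.DataFrame, mode: str = "multi") -> pd.DataFrame:
    """Select each patient's immune hot-spot core.

    ``single`` mode maximizes the CD3-positive count; ``multi`` mode
    maximizes the summed count of the six T-cell subtypes.  Ties break to
    the lexicographically smallest core_id.  Only assessable cores compete;
    a patient with none raises an error.
    """
    if mode == "single":
        key = "n_CD3"
    elif mode == "multi":
        key = "n_tcell"
    else:
        raise ValueError("mode must be 'single' or 'multi'")
    ok = core_scores[core_scores["assessable"]]
    if ok.empty:
        raise ValueError("no assessable cores to select a hot-spot from")
    missing = set(core_scores["patient_id"]) - set(ok["patient_id"])
    if missing:
        raise ValueError(
            f"patients with no assessable core: {sorted(missing)[:3]}"
        )
    ok = ok.sort_values(["patient_id", "core_id"], kind="stable")
    idx = ok.groupby("patient_id")[key].idxmax()  # first max -> smallest core_id
    out = ok.loc[idx].reset_index(drop=True)
    return out.rename(columns={key: "hotspot_count"}).assign(hotspot_mode=mode)
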