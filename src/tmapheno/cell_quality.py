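"""Post-segmentation cell filtering and core assessability.

Six filtering criteria are applied to segmented cells, in order:

1. epithelial cells (inside the epithelial mask) must have 1–2 nuclei;
2. each subcellular compartment area (nucleus, membrane, cytoplasm) must be
   strictly between 10 and 1500 pixels;
3. the cell must be well aligned with the first staining round;
4. the cell must sit more than 25 pixels from every image margin;
5. the nuclear segmentation mask area must be strictly between 100 and 3000
   pixels (read as a conjunction — the disjunctive reading excludes nothing);
6. duplicates — cells sharing a core and rounded centroid — are collapsed to
   the lexicographically first cell id.

The kept set does not depend on the order the criteria are applied; the
order matters only for attributing multi-reason exclusions in the report,
where each dropped cell is counted once under its first failing criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QCThresholds", "QCReport", "apply_cell_filters", "flag_assessable_cores"]

_REQUIRED_FIELDS = (
    "cell_id",
    "core_id",
    "x",
    "y",
    "nucleus_count",
    "area_nucleus",
    "area_membrane",
    "area_cytoplasm",
    "in_epithelial_mask",
    "aligned_round0",
)

CRITERION_NAMES = {
    1: "epithelial_nuclei",
    2: "compartment_area",
    3: "round0_alignment",
    4: "edge_margin",
    5: "nuclear_area",
    6: "duplicate",
}


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds for the six filtering criteria."""

    nuclei_range_epithelial: tuple[int, int] = (1, 2)  # inclusive
    compartment_area_px: tuple[float, float] = (10.0, 1500.0)  # open interval
    margin_min_px: float = 25.0  # strict >
    nuclear_area_px: tuple[float, float] = (100.0, 3000.0)  # open interval
    require_round0_alignment: bool = True
    drop_duplicates: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (
            self.nuclei_range_epithelial,
            self.compartment_area_px,
            self.nuclear_area_px,
        ):
            if not lo < hi:
                raise ValueError(f"interval lower bound {lo} must be < upper bound {hi}")
        if self.margin_min_px < 0:
            raise ValueError("margin must be nonnegative")


@dataclass
class QCReport:
    """Accounting of exclusions: cells_in = cells_out + sum of exclusions."""

    cells_in: int = 0
    cells_out: int = 0
    exclusions: dict[int, int] = field(default_factory=dict)

    def reconciles(self) -> bool:
        return self.cells_in == self.cells_out + sum(self.exclusions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"criterion": k, "name": CRITERION_NAMES[k], "excluded": v}
            for k, v in sorted(self.exclusions.items())
        ]
        return pd.DataFrame(rows)


def _core_dims_lookup(core_dims) -> pd.DataFrame:
    if isinstance(core_dims, pd.DataFrame):
        missing = {"core_id", "width_px", "height_px"} - set(core_dims.columns)
        if missing:
            raise ValueError(f"core_dims missing columns: {sorted(missing)}")
        return core_dims[["core_id", "width_px", "height_px"]]
    rows = [
        {"core_id": k, "width_px": w, "height_px": h} for k, (w, h) in core_dims.items()
    ]
    return pd.DataFrame(rows)


def apply_cell_filters(
    cells: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    core_dims: pd.DataFrame | dict | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the six filtering criteria; return kept cells and a QC report.

    ``core_dims`` maps core_id to image dimensions (a DataFrame with
    ``core_id``/``width_px``/``height_px`` columns, or a dict of
    ``core_id -> (width, height)``); required for the margin criterion.
    """
    thresholds = thresholds or QCThresholds()
    for col in _REQUIRED_FIELDS:
        if col not in cells.columns:
            raise ValueError(f"cells table missing required field '{col}'")
        bad = cells[col].isna()
        if bad.any():
            cid = cells.loc[bad, "cell_id"].iloc[0] if col != "cell_id" else "<missing>"
            raise ValueError(f"missing value in required field '{col}' (first cell: {cid})")
    if core_dims is None:
        raise ValueError("core_dims is required for the edge-margin criterion")

    df = cells.copy()
    n_in = len(df)

    lo_n, hi_n = thresholds.nuclei_range_epithelial
    fail1 = df["in_epithelial_mask"].astype(bool) & ~df["nucleus_count"].between(lo_n, hi_n)

    lo_a, hi_a = thresholds.compartment_area_px
    fail2 = ~(
        df["area_nucleus"].gt(lo_a) & df["area_nucleus"].lt(hi_a)
        & df["area_membrane"].gt(lo_a) & df["area_membrane"].lt(hi_a)
        & df["area_cytoplasm"].gt(lo_a) & df["area_cytoplasm"].lt(hi_a)
    )

    if thresholds.require_round0_alignment:
        fail3 = ~df["aligned_round0"].astype(bool)
    else:
        fail3 = pd.Series(False, index=df.index)

    dims = _core_dims_lookup(core_dims)
    merged = df.merge(dims, on="core_id", how="left", suffixes=("", "_dims"))
    merged.index = df.index
    wcol = "width_px_dims" if "width_px_dims" in merged.columns else "width_px"
    hcol = "height_px_dims" if "height_px_dims" in merged.columns else "height_px"
    if merged[wcol].isna().any():
        missing_core = merged.loc[merged[wcol].isna(), "core_id"].iloc[0]
        raise ValueError(f"no image dimensions for core '{missing_core}'")
    # Chebyshev distance to the nearest image border (pixel grid).
    edge_dist = np.minimum.reduce(
        [
            df["x"].to_numpy(dtype=float),
            df["y"].to_numpy(dtype=float),
            merged[wcol].to_numpy(dtype=float) - 1 - df["x"].to_numpy(dtype=float),
            merged[hcol].to_numpy(dtype=float) - 1 - df["y"].to_numpy(dtype=float),
        ]
    )
    fail4 = pd.Series(~(edge_dist > thresholds.margin_min_px), index=df.index)

    lo_nuc, hi_nuc = thresholds.nuclear_area_px
    fail5 = ~(df["area_nucleus"].gt(lo_nuc) & df["area_nucleus"].lt(hi_nuc))

    if thresholds.drop_duplicates:
        key = pd.DataFrame(
            {
                "core_id": df["core_id"],
                "rx": df["x"].astype(float).round().astype(int),
                "ry": df["y"].astype(float).round().astype(int),
            }
        )
        # Keep the lexicographically smallest cell_id in each duplicate group
        # so the kept set is independent of input row order.
        order = df["cell_id"].astype(str).argsort(kind="stable")
        dup_sorted = key.iloc[order].duplicated(keep="first")
        fail6 = pd.Series(False, index=df.index)
        fail6.iloc[order[dup_sorted.to_numpy()]] = True
    else:
        fail6 = pd.Series(False, index=df.index)

    fails = [fail1, fail2, fail3, fail4, fail5, fail6]
    any_fail = pd.Series(False, index=df.index)
    exclusions: dict[int, int] = {}
    for i, f in enumerate(fails, start=1):
        first_here = f & ~any_fail
        exclusions[i] = int(first_here.sum())
        any_fail |= f

    kept = df.loc[~any_fail].copy()
    report = QCReport(cells_in=n_in, cells_out=len(kept), exclusions=exclusions)
    assert report.reconciles()
    return kept, report


def flag_assessable_cores(
    cores: pd.DataFrame, kept_cells: pd.DataFrame, min_cells: int = 100
) -> pd.DataFrame:
    """Update core assessability from post-QC cell counts.

    A core is assessable when it retains at least ``min_cells`` cells.
    Patients with fewer than two assessable cores are flagged
    (``patient_excluded``) for exclusion from per-patient averaging, since a
    single core cannot capture intra-tumor heterogeneity.
    """
    counts = kept_cells.groupby("core_id").size()
    out = cores.copy()
    out["kept_cell_count"] = out["core_id"].map(counts).fillna(0).astype(int)
    out["assessable"] = out["kept_cell_count"] >= min_cells
    per_patient = out.groupby("patient_id")["assessable"].sum()
    out["patient_excluded"] = out["patient_id"].map(per_patient < 2)
    return out
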