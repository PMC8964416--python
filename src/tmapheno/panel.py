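"""Marker panel definitions and the multi-marker gating rule table.

The panel mirrors a ten-marker multiplexed immunofluorescence design for
T-cell phenotyping in colorectal tumor tissue: an epithelial marker (AE1),
six lineage markers (CD45, CD3, CD4, CD8, FOXP3, PD1) and structural
markers used for segmentation and subcellular analysis (DAPI, pan-cytokeratin,
NaKATPase, S6).  Classification into the eight cell classes uses the six
markers AE1, CD3, CD4, CD8, FOXP3 and PD1; CD45 participates only in the
core-level immune score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Markers used by the multi-marker rule table, in canonical order.
CLASSIFICATION_MARKERS: tuple[str, ...] = ("AE1", "CD3", "CD4", "CD8", "FOXP3", "PD1")

#: Markers whose positivity defines an "immune cell" for core-level scoring.
IMMUNE_SCORE_MARKERS: tuple[str, ...] = ("CD45", "CD3", "CD4", "CD8")

#: Individually analyzed immune markers (single-marker workflow).
SINGLE_MARKERS: tuple[str, ...] = ("CD3", "CD4", "CD8", "FOXP3", "PD1")

#: Structural / segmentation markers carried in the cell table but not gated on.
STRUCTURAL_MARKERS: tuple[str, ...] = ("DAPI", "panCK", "NaKATPase", "S6")

#: Full panel order used for synthetic cell tables.
ALL_MARKERS: tuple[str, ...] = (
    "DAPI", "AE1", "panCK", "NaKATPase", "S6",
    "CD45", "CD3", "CD4", "CD8", "FOXP3", "PD1",
)

#: The eight multi-marker cell classes.
CLASS_LABELS: tuple[str, ...] = (
    "Th", "ThPD1", "Tc", "TcPD1", "Treg", "TregPD1", "Epithelial", "Other",
)

#: The six T-cell subtype classes (everything except Epithelial/Other).
T_CELL_CLASSES: tuple[str, ...] = ("Th", "ThPD1", "Tc", "TcPD1", "Treg", "TregPD1")

# For each class, which of the six classification markers must be positive.
# All other classification markers are negative.  "Other" is the catch-all
# for patterns not matching any lymphocyte or epithelial definition; its
# canonical pattern (used by the synthetic generator) is all-negative.
CLASS_POSITIVE_MARKERS: dict[str, frozenset[str]] = {
    "Tc": frozenset({"CD3", "CD8"}),
    "TcPD1": frozenset({"CD3", "CD8", "PD1"}),
    "Th": frozenset({"CD3", "CD4"}),
    "ThPD1": frozenset({"CD3", "CD4", "PD1"}),
    "Treg": frozenset({"CD3", "CD4", "FOXP3"}),
    "TregPD1": frozenset({"CD3", "CD4", "FOXP3", "PD1"}),
    "Epithelial": frozenset({"AE1"}),
    "Other": frozenset(),
}

# Positivity over the FULL panel implied by each ground-truth class, used by
# the synthetic generator to pick the intensity component per marker.  DAPI
# stains every nucleated cell; CD45 marks all leukocytes; the epithelial
# structural markers co-stain epithelial cells.
CLASS_PANEL_POSITIVE: dict[str, frozenset[str]] = {
    label: (
        CLASS_POSITIVE_MARKERS[label]
        | frozenset({"DAPI"})
        | (frozenset({"CD45"}) if label in T_CELL_CLASSES else frozenset())
        | (
            frozenset({"panCK", "NaKATPase", "S6"})
            if label == "Epithelial"
            else frozenset()
        )
    )
    for label in CLASS_LABELS
}


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered marker panel with per-marker roles.

    Roles: ``epithelial`` (AE1), ``lineage`` (CD45/CD3/CD4/CD8/FOXP3/PD1),
    ``structural`` (DAPI/panCK/NaKATPase/S6).
    """

    markers: tuple[str, ...] = ALL_MARKERS
    roles: dict[str, str] = field(default_factory=lambda: {
        **{m: "structural" for m in STRUCTURAL_MARKERS},
        "AE1": "epithelial",
        **{m: "lineage" for m in ("CD45", "CD3", "CD4", "CD8", "FOXP3", "PD1")},
    })

    def __post_init__(self) -> None:
        missing = set(CLASSIFICATION_MARKERS) - set(self.markers)
        if missing:
            raise ValueError(f"classification markers missing from panel: {sorted(missing)}")
        unknown = set(self.roles) - set(self.markers)
        if unknown:
            raise ValueError(f"roles given for markers not in panel: {sorted(unknown)}")


def classify_pattern(
    ae1: bool, cd3: bool, cd4: bool, cd8: bool, foxp3: bool, pd1: bool
) -> str:
    """Map one positivity pattern to its cell class.

    Decision order: epithelial marker first, then cytotoxic, helper and
    regulatory T-cell definitions; anything else (including CD4+CD8+
    double positives, which the gating table does not cover) is ``Other``.
    Total on all 64 patterns.
    """
    if ae1:
        return "Epithelial"
    if cd3 and cd8 and not cd4:
        return "TcPD1" if pd1 else "Tc"
    if cd3 and cd4 and not cd8:
        if foxp3:
            return "TregPD1" if pd1 else "Treg"
        return "ThPD1" if pd1 else "Th"
    return "Other"
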