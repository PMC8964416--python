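"""Seeded synthetic multiplexed-TMA cohorts with known ground truth.

Emulates the structure of a stage III colorectal cancer tissue-microarray
study: patients contribute up to three 1-mm cores, each core yields a table
of segmented cells with per-marker mean/SD intensities, and patients carry
clinical covariates plus disease-free and overall survival outcomes.  Every
cell has a known ground-truth class drawn from the eight-class gating table,
so downstream QC, classification, scoring and survival stages can all be
tested against truth.

Model choices
-------------
* Per-marker intensities are two-component lognormal: a negative and a
  positive component on the log scale, the positive component displaced by
  ``separation`` negative-component SDs.  Fluorescence intensities are
  strictly positive and heavy tailed, which the lognormal captures.
* Core-to-core heterogeneity within a patient is a logit-normal perturbation
  of the patient's class mixture, renormalized, so fractions stay in (0,1).
* Survival is proportional hazards: exponential event times whose hazard is
  ``baseline_hazard * exp(beta_treg * I[patient Treg fraction > cohort
  median])``, with independent exponential censoring.  Overall survival is
  the relapse time plus an exponential post-relapse gap, so OS stochastically
  dominates DFS by construction.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import ALL_MARKERS, CLASS_LABELS, CLASS_PANEL_POSITIVE, T_CELL_CLASSES

__all__ = [
    "MarkerIntensity",
    "SimConfig",
    "generate_cohort",
    "generate_survival",
    "generate_pathologist_scores",
    "write_cohort",
    "write_core_masks",
    "load_config",
]

# Default expected class fractions (order of CLASS_LABELS):
# Th, ThPD1, Tc, TcPD1, Treg, TregPD1, Epithelial, Other.
# T-cell fractions sit near the cohort-level per-subtype means reported for
# FOLFOX-treated stage III colorectal TMAs (tenths of a percent each, ~2.7%
# of cells being T cells overall); the remainder splits between epithelial
# tumor cells and unclassified stromal cells.
DEFAULT_CLASS_MIXTURE: tuple[float, ...] = (
    0.0013, 0.0056, 0.0069, 0.0048, 0.0057, 0.0026, 0.52, 0.4531,
)

#: Mixing weights for 1/2/3 assessable cores per patient; shaped like the
#: 7/99/62 split of a 168-patient TMA design.
DEFAULT_CORE_COUNT_WEIGHTS: tuple[float, ...] = (7.0, 99.0, 62.0)


@dataclass(frozen=True)
class MarkerIntensity:
    """Two-component lognormal intensity model for one marker.

    ``neg_loc``/``neg_scale`` parameterize the negative population on the
    natural-log scale.  The positive component sits at
    ``neg_loc + separation * neg_scale`` (unless ``pos_loc`` is given
    explicitly) with scale ``pos_scale``.  ``separation`` is therefore the
    distance between components in units of the negative SD — the knob that
    controls how easy classification is.
    """

    neg_loc: float = np.log(100.0)
    neg_scale: float = 0.5
    pos_scale: float = 0.5
    separation: float = 5.0
    pos_loc: float | None = None

    def __post_init__(self) -> None:
        if self.neg_scale <= 0 or self.pos_scale <= 0:
            raise ValueError("intensity scales must be > 0")

    @property
    def positive_loc(self) -> float:
        if self.pos_loc is not None:
            return self.pos_loc
        return self.neg_loc + self.separation * self.neg_scale


@dataclass
class SimConfig:
    """Configuration for one synthetic cohort."""

    n_patients: int = 117
    #: Fixed cores per patient in {1,2,3}, or None to mix per
    #: DEFAULT_CORE_COUNT_WEIGHTS.
    cores_per_patient: int | None = None
    #: Expected cells per core; realized counts are lognormal around this.
    cells_per_core: int = 2000
    #: Expected class fractions in the order of CLASS_LABELS; must sum to 1.
    class_mixture: tuple[float, ...] = DEFAULT_CLASS_MIXTURE
    intensity_params: dict[str, MarkerIntensity] = field(default_factory=dict)
    #: Overall separation factor applied to markers without explicit params.
    separation: float = 5.0
    #: SD of the logit-normal per-core perturbation of class fractions.
    heterogeneity_sd: float = 0.3
    #: SD of the logit-normal per-patient perturbation of the base mixture.
    patient_sd: float = 0.4
    #: Log hazard ratio for Treg-high (above cohort median) vs Treg-low.
    beta_treg: float = np.log(0.5)
    #: Relapse events per month in the Treg-low group.
    baseline_hazard: float = 0.010
    #: Hazard of independent (administrative) censoring, per month.
    censor_rate: float = 0.012
    #: Hazard of death after relapse, per month (couples OS to DFS).
    post_relapse_hazard: float = 0.03
    #: Probability that a pathologist category is flipped to a neighbor.
    pathologist_noise: float = 0.1
    width_px: int = 1800
    height_px: int = 1800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.cores_per_patient is not None and self.cores_per_patient not in (1, 2, 3):
            raise ValueError("cores_per_patient must be in {1, 2, 3} (up to three 1-mm cores)")
        if self.cells_per_core < 50:
            raise ValueError(
                "cells_per_core < 50: core-level scores become degenerate at "
                "such low cell counts; use at least 50"
            )
        mix = np.asarray(self.class_mixture, dtype=float)
        if mix.shape != (len(CLASS_LABELS),):
            raise ValueError(f"class_mixture must have {len(CLASS_LABELS)} entries")
        if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("class_mixture must be nonnegative and sum to 1")
        if self.baseline_hazard <= 0 or self.post_relapse_hazard <= 0:
            raise ValueError("hazards must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be nonnegative")
        if self.heterogeneity_sd < 0 or self.patient_sd < 0:
            raise ValueError("dispersion SDs must be nonnegative")

    def marker_intensity(self, marker: str) -> MarkerIntensity:
        if marker in self.intensity_params:
            return self.intensity_params[marker]
        return MarkerIntensity(separation=self.separation)


def _perturb_logit(fractions: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Logit-normal perturbation of a composition, renormalized.

    Zero entries stay zero (the perturbation acts multiplicatively on odds).
    """
    if sd == 0:
        return fractions.copy()
    out = fractions.copy()
    pos = out > 0
    logits = np.log(out[pos]) - np.log1p(-np.clip(out[pos], None, 1 - 1e-12))
    logits = logits + rng.normal(0.0, sd, size=logits.shape)
    odds = np.exp(logits)
    out[pos] = odds / (1.0 + odds)
    return out / out.sum()


def _sample_clinical(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates with marginals shaped like a stage III CRC cohort."""
    t_stage = rng.choice([2, 3, 4], size=n, p=np.array([10, 70, 37]) / 117)
    n_stage = rng.choice([1, 2], size=n, p=np.array([83, 34]) / 117)
    sex = rng.choice(["F", "M"], size=n, p=np.array([46, 71]) / 117)
    age = np.clip(np.round(rng.normal(59.2, 11.2, size=n)), 26, 79).astype(int)
    lnc = np.clip(np.round(rng.lognormal(np.log(19.0), 0.42, size=n)), 5, 73).astype(int)
    pln = np.minimum(1 + rng.poisson(2.0, size=n), np.minimum(lnc, 13))
    lvi = rng.random(n) < 68 / 117
    differentiation = rng.choice(
        ["moderate-to-well", "poor", "missing"], size=n, p=np.array([99, 16, 2]) / 117
    )
    return pd.DataFrame(
        {
            "t_stage": t_stage,
            "n_stage": n_stage,
            "age": age,
            "sex": sex,
            "lnc": lnc,
            "pln": pln,
            "lvi": lvi,
            "differentiation": differentiation,
        }
    )


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns ``(patients, cores, cells)`` DataFrames.  Deterministic given
    ``config.seed``.  Patient Treg fractions (realized, over all their cells)
    drive the survival model; pathologist-style categorical scores are filled
    from the ground-truth composition with configurable label noise.
    """
    rng = np.random.default_rng(config.seed)
    mix = np.asarray(config.class_mixture, dtype=float)
    n_classes = len(CLASS_LABELS)

    patient_ids = [f"P{i + 1:04d}" for i in range(config.n_patients)]
    patients = _sample_clinical(config.n_patients, rng)
    patients.insert(0, "patient_id", patient_ids)

    if config.cores_per_patient is None:
        w = np.asarray(DEFAULT_CORE_COUNT_WEIGHTS, dtype=float)
        n_cores_per_patient = rng.choice([1, 2, 3], size=config.n_patients, p=w / w.sum())
    else:
        n_cores_per_patient = np.full(config.n_patients, config.cores_per_patient)

    core_rows: list[dict] = []
    cell_frames: list[pd.DataFrame] = []
    treg_idx = [CLASS_LABELS.index(c) for c in ("Treg", "TregPD1")]
    tcell_idx = [CLASS_LABELS.index(c) for c in T_CELL_CLASSES]
    treg_cells = np.zeros(config.n_patients)
    total_cells = np.zeros(config.n_patients)

    for p_i, pid in enumerate(patient_ids):
        patient_mix = _perturb_logit(mix, config.patient_sd, rng)
        for c_i in range(n_cores_per_patient[p_i]):
            core_id = f"{pid}_core{c_i + 1}"
            core_mix = _perturb_logit(patient_mix, config.heterogeneity_sd, rng)
            n_cells = max(50, int(np.round(rng.lognormal(np.log(config.cells_per_core), 0.25))))
            counts = rng.multinomial(n_cells, core_mix)
            cells = _sample_cells(core_id, pid, counts, config, rng)
            cell_frames.append(cells)
            treg_cells[p_i] += counts[treg_idx].sum()
            total_cells[p_i] += n_cells
            core_rows.append(
                {
                    "core_id": core_id,
                    "patient_id": pid,
                    "tma_id": f"TMA{(p_i % 5) + 1}",
                    "width_px": config.width_px,
                    "height_px": config.height_px,
                    "assessable": True,
                    "n_cells_true": n_cells,
                    **{f"n_{CLASS_LABELS[k]}": int(counts[k]) for k in range(n_classes)},
                    "true_tcell_count": int(counts[tcell_idx].sum()),
                }
            )

    cores = pd.DataFrame(core_rows)
    cells = pd.concat(cell_frames, ignore_index=True)

    patients["true_treg_fraction"] = treg_cells / total_cells
    patients = generate_survival(patients, patients["true_treg_fraction"].to_numpy(), config, rng)
    cores = generate_pathologist_scores(
        cores, cells, noise=config.pathologist_noise, rng=rng
    )
    # Drop generator-internal composition columns from the public core table,
    # keeping the ground-truth T-cell count used by tests.
    keep = [
        "core_id", "patient_id", "tma_id", "width_px", "height_px",
        "assessable", "path_immune", "path_stroma", "true_tcell_count",
    ]
    return patients, cores[keep].copy(), cells


def _sample_cells(
    core_id: str,
    patient_id: str,
    class_counts: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Vectorized draw of one core's cell table given its class counts."""
    n = int(class_counts.sum())
    labels = np.repeat(np.arange(len(CLASS_LABELS)), class_counts)
    rng.shuffle(labels)
    class_names = np.asarray(CLASS_LABELS, dtype=object)[labels]

    # Positions: uniform in the core disc (radius = min dimension / 2,
    # centered), matching a circular 1-mm punch inscribed in the image.
    radius = min(config.width_px, config.height_px) / 2.0
    cx, cy = config.width_px / 2.0, config.height_px / 2.0
    r = radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0, 2 * np.pi, n)
    x = np.clip(cx + r * np.cos(theta), 0, config.width_px - 1)
    y = np.clip(cy + r * np.sin(theta), 0, config.height_px - 1)

    is_epi = class_names == "Epithelial"
    # Nucleus counts: epithelial cells occasionally bi-/tri-nucleated;
    # small fractions of segmentation failures (0 nuclei) everywhere.
    nucleus_count = np.where(
        is_epi,
        rng.choice([0, 1, 2, 3], size=n, p=[0.01, 0.75, 0.22, 0.02]),
        rng.choice([0, 1, 2], size=n, p=[0.02, 0.97, 0.01]),
    )
    area_nucleus = np.round(rng.lognormal(np.log(320.0), 0.45, n)).astype(int)
    area_membrane = np.round(rng.lognormal(np.log(220.0), 0.45, n)).astype(int)
    area_cytoplasm = np.round(rng.lognormal(np.log(380.0), 0.45, n)).astype(int)
    aligned = rng.random(n) < 0.99
    in_mask = np.where(is_epi, rng.random(n) < 0.95, rng.random(n) < 0.10)

    data: dict[str, np.ndarray] = {
        "cell_id": np.array([f"{core_id}_c{i + 1}" for i in range(n)], dtype=object),
        "core_id": np.full(n, core_id, dtype=object),
        "patient_id": np.full(n, patient_id, dtype=object),
        "x": np.round(x, 1),
        "y": np.round(y, 1),
        "nucleus_count": nucleus_count.astype(int),
        "area_nucleus": area_nucleus,
        "area_membrane": area_membrane,
        "area_cytoplasm": area_cytoplasm,
        "in_epithelial_mask": in_mask,
        "aligned_round0": aligned,
    }

    for marker in ALL_MARKERS:
        mi = config.marker_intensity(marker)
        positive = np.array(
            [marker in CLASS_PANEL_POSITIVE[c] for c in CLASS_LABELS], dtype=bool
        )[labels]
        loc = np.where(positive, mi.positive_loc, mi.neg_loc)
        scale = np.where(positive, mi.pos_scale, mi.neg_scale)
        mean = np.exp(rng.normal(loc, scale))
        # Within-cell SD scales with the mean (shot-noise-like texture).
        cv = rng.lognormal(np.log(0.25), 0.15, n)
        data[f"mean_{marker}"] = np.round(mean, 3)
        data[f"sd_{marker}"] = np.round(mean * cv, 3)

    data["true_class"] = class_names
    return pd.DataFrame(data)


def generate_survival(
    patients: pd.DataFrame,
    treg_fraction: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill DFS/OS fields from a proportional-hazards model on Treg status.

    Relapse hazard is ``baseline_hazard * exp(beta_treg)`` for patients whose
    Treg fraction exceeds the cohort median and ``baseline_hazard`` otherwise.
    Death follows relapse after an exponential gap, and an independent
    exponential censoring time is shared by both endpoints, so observed
    OS times are always >= DFS times.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    treg_fraction = np.asarray(treg_fraction, dtype=float)
    if len(treg_fraction) != len(patients):
        raise ValueError("need one Treg fraction per patient")
    if config.baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")

    high = treg_fraction > np.median(treg_fraction)
    hazard = config.baseline_hazard * np.exp(config.beta_treg * high)
    n = len(patients)
    relapse = rng.exponential(1.0 / hazard)
    death = relapse + rng.exponential(1.0 / config.post_relapse_hazard, n)
    if config.censor_rate > 0:
        censor = rng.exponential(1.0 / config.censor_rate, n)
    else:
        censor = np.full(n, np.inf)
    # Guarantee strictly positive observed times even at extreme hazards.
    censor = np.maximum(censor, 1e-3)

    out = patients.copy()
    out["treg_high_true"] = high
    out["dfs_months"] = np.maximum(np.round(np.minimum(relapse, censor), 2), 0.01)
    out["dfs_event"] = (relapse <= censor).astype(int)
    out["os_months"] = np.maximum(np.round(np.minimum(death, censor), 2), 0.01)
    out["os_event"] = (death <= censor).astype(int)
    return out


_CATEGORIES = np.array(["low", "moderate", "high"], dtype=object)


def _flip_adjacent(idx: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each 3-level category to an adjacent one with probability noise."""
    if noise <= 0:
        return idx
    flip = rng.random(len(idx)) < noise
    direction = np.where(rng.random(len(idx)) < 0.5, -1, 1)
    out = idx.copy()
    out[flip] = np.clip(idx[flip] + direction[flip], 0, 2)
    # At the extremes the only adjacent category is inward.
    same = flip & (out == idx)
    out[same] = np.clip(idx[same] + np.where(idx[same] == 0, 1, -1), 0, 2)
    return out


def generate_pathologist_scores(
    cores: pd.DataFrame,
    cells: pd.DataFrame,
    noise: float = 0.1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill categorical immune/stroma scores from ground-truth composition.

    Stroma: ``high`` when the stromal (unclassified, non-epithelial) cell
    count exceeds the epithelial count by more than 10%, ``low`` when it
    falls short by more than 10%, ``moderate`` in the equivalence band.
    Immune: cohort-wide tertiles of the true immune-cell fraction.
    With probability ``noise`` a label is flipped to an adjacent category,
    emulating inter-observer variability.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    comp = (
        cells.groupby("core_id")["true_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(cores["core_id"])
        .fillna(0)
    )
    for label in CLASS_LABELS:
        if label not in comp.columns:
            comp[label] = 0
    stromal = comp["Other"].to_numpy(dtype=float)
    epithelial = comp["Epithelial"].to_numpy(dtype=float)
    immune = comp[list(T_CELL_CLASSES)].sum(axis=1).to_numpy(dtype=float)
    total = comp[list(CLASS_LABELS)].sum(axis=1).to_numpy(dtype=float)

    stroma_idx = np.where(
        stromal > 1.1 * epithelial, 2, np.where(stromal < 0.9 * epithelial, 0, 1)
    )
    frac = np.divide(immune, total, out=np.zeros_like(immune), where=total > 0)
    t1, t2 = np.quantile(frac, [1 / 3, 2 / 3])
    immune_idx = np.where(frac > t2, 2, np.where(frac > t1, 1, 0))

    out = cores.copy()
    out["path_immune"] = _CATEGORIES[_flip_adjacent(immune_idx, noise, rng)]
    out["path_stroma"] = _CATEGORIES[_flip_adjacent(stroma_idx, noise, rng)]
    return out


def sample_annotations(
    cells: pd.DataFrame, per_class: int = 50, seed: int = 0
):
    """Emulate manual annotation by sampling ground-truth labels.

    Draws up to ``per_class`` cells per true class and returns an
    AnnotationSet carrying both class labels and the per-marker positivity
    each class implies — the synthetic stand-in for a human annotator
    clicking cells on the images.
    """
    from .cell_classify import AnnotationSet
    from .panel import CLASSIFICATION_MARKERS, CLASS_POSITIVE_MARKERS

    rng = np.random.default_rng(seed)
    class_rows = []
    marker_rows = []
    for cls, grp in cells.groupby("true_class"):
        take = grp.sample(min(per_class, len(grp)), random_state=rng.integers(2**31))
        for cid in take["cell_id"]:
            class_rows.append({"cell_id": cid, "label": cls})
            for marker in CLASSIFICATION_MARKERS:
                marker_rows.append(
                    {
                        "cell_id": cid,
                        "marker": marker,
                        "positive": marker in CLASS_POSITIVE_MARKERS[cls],
                    }
                )
    return AnnotationSet(
        class_labels=pd.DataFrame(class_rows),
        marker_labels=pd.DataFrame(marker_rows),
        annotator="manual",
    )


def write_cohort(
    patients: pd.DataFrame, cores: pd.DataFrame, cells: pd.DataFrame, out_dir: str | Path
) -> None:
    """Write patients.csv, cores.csv and cells.csv to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients.to_csv(out / "patients.csv", index=False)
    cores.to_csv(out / "cores.csv", index=False)
    cells.to_csv(out / "cells.csv", index=False)


def write_core_masks(
    cores: pd.DataFrame, cells: pd.DataFrame, out_dir: str | Path, spot_radius: int = 4
) -> list[Path]:
    """Write a 16-bit label-mask TIFF per core (cell index as pixel label).

    Cells are rendered as small discs at their centroids — a stand-in for
    true segmentation masks, sufficient for integration tests with
    image-reading code.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for _, core in cores.iterrows():
        mask = np.zeros((int(core.height_px), int(core.width_px)), dtype=np.uint16)
        sub = cells[cells["core_id"] == core.core_id]
        yy, xx = np.mgrid[-spot_radius:spot_radius + 1, -spot_radius:spot_radius + 1]
        disc = (yy**2 + xx**2) <= spot_radius**2
        for label, (x, y) in enumerate(zip(sub["x"], sub["y"]), start=1):
            if label > np.iinfo(np.uint16).max:
                warnings.warn("more cells than uint16 labels; truncating mask")
                break
            r0, c0 = int(round(y)) - spot_radius, int(round(x)) - spot_radius
            r1, c1 = r0 + disc.shape[0], c0 + disc.shape[1]
            rs, cs = max(r0, 0), max(c0, 0)
            re, ce = min(r1, mask.shape[0]), min(c1, mask.shape[1])
            if re <= rs or ce <= cs:
                continue
            window = disc[rs - r0 : re - r0, cs - c0 : ce - c0]
            mask[rs:re, cs:ce][window] = label
        path = out / f"{core.core_id}_mask.tif"
        tifffile.imwrite(path, mask)
        paths.append(path)
    return paths


def load_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML file (keys mirror the dataclass fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "intensity_params" in raw:
        raw["intensity_params"] = {
            m: MarkerIntensity(**v) for m, v in raw["intensity_params"].items()
        }
    if "class_mixture" in raw:
        raw["class_mixture"] = tuple(float(v) for v in raw["class_mixture"])
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimConfig(**raw)
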