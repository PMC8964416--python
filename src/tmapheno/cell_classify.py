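"""Per-marker positivity and eight-class T-cell classification.

Three classification routes are provided, all emitting one of the eight
classes (Th, ThPD1, Tc, TcPD1, Treg, TregPD1, Epithelial, Other) per cell:

``rule``
    Explicit gating: markers are binarized (two-component Gaussian mixture
    on log intensities by default) and the positivity pattern is mapped
    through the gating table.
``svm``
    Linear-kernel support vector machines trained from annotated cells,
    either one binary model per marker or a single multi-class model on the
    mean/SD intensity features of all six classification markers.
``probabilistic``
    An automated-annotation workflow: candidate positives are harvested per
    marker by intensity and morphology, a class-conditional Gaussian
    probability model is fit per marker, and per-cell marker posteriors are
    combined through the gating table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .panel import CLASSIFICATION_MARKERS, classify_pattern

__all__ = [
    "AnnotationSet",
    "binarize_marker",
    "binarize_panel",
    "classify_rule_table",
    "train_marker_svm",
    "train_multimarker_svm",
    "auto_annotate",
    "fit_probabilistic_model",
    "predict_probabilistic",
    "crossval_accuracy",
    "MarkerSVM",
    "MultiMarkerSVM",
    "ProbabilisticModel",
]

#: Minimum bimodality (Ashman's D) for a mixture fit to be trusted; below
#: this the intensity distribution is treated as single-component negative.
_MIN_ASHMAN_D = 2.0


# ---------------------------------------------------------------------------
# Marker binarization


def _gmm2_components(
    log_int: np.ndarray, seed: int = 0
) -> tuple[float, float, float] | None:
    """Fit a 2-component GMM to log intensities.

    Returns ``(threshold, lower_mean, upper_mean)`` where the threshold is
    the log intensity at which the posterior of the upper component crosses
    0.5, or None when the fit is not meaningfully bimodal (Ashman's D < 2,
    or one component does not beat two on BIC), in which case all cells are
    treated as negative.
    """
    from sklearn.mixture import GaussianMixture

    # Positive populations can be rare (T-cell markers mark only a few
    # percent of cells); k-means initialization routinely misses such a
    # component, so seed the components at the bulk median and the extreme
    # upper quantile instead.
    x = log_int.reshape(-1, 1)
    spread = max(np.var(log_int) / 4.0, 1e-4)
    gm = GaussianMixture(
        n_components=2,
        random_state=seed,
        means_init=[[np.median(log_int)], [np.quantile(log_int, 0.995)]],
        weights_init=[0.95, 0.05],
        precisions_init=[[[1.0 / spread]], [[1.0 / spread]]],
    )
    gm.fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    lo, hi = np.argsort(means)
    d = abs(means[hi] - means[lo]) / np.sqrt((sds[lo] ** 2 + sds[hi] ** 2) / 2)
    # Guard against calling positives on a unimodal marker: require both a
    # separated second mode (Ashman's D) and that two components beat one
    # on BIC.
    gm1 = GaussianMixture(n_components=1).fit(x)
    if d < _MIN_ASHMAN_D or gm.bic(x) >= gm1.bic(x):
        return None

    def upper_post_minus_half(x: float) -> float:
        post = gm.predict_proba(np.array([[x]]))[0]
        return post[hi] - 0.5

    a, b = means[lo], means[hi]
    if upper_post_minus_half(a) >= 0 or upper_post_minus_half(b) <= 0:
        t = float((a + b) / 2)
    else:
        t = float(optimize.brentq(upper_post_minus_half, a, b))
    return t, float(a), float(b)


def _gmm2_threshold(log_int: np.ndarray, seed: int = 0) -> float | None:
    res = _gmm2_components(log_int, seed=seed)
    return None if res is None else res[0]


def binarize_marker(
    cells: pd.DataFrame,
    marker: str,
    method: str = "gmm2",
    threshold: float | None = None,
    slide_col: str | None = "tma_id",
    seed: int = 0,
) -> pd.Series:
    """Call each cell positive/negative for one marker.

    ``method`` is one of ``gmm2`` (two-component Gaussian mixture on log
    intensities, fit per slide when ``slide_col`` is available), ``otsu``,
    or ``fixed`` (requires ``threshold`` on the raw intensity scale).  The
    call is a scalar-threshold comparison, so it is monotone in intensity.
    The returned Series stores per-slide thresholds in ``.attrs``.
    """
    col = f"mean_{marker}"
    if col not in cells.columns:
        raise ValueError(f"no intensity column '{col}' for marker {marker}")
    intensity = cells[col].to_numpy(dtype=float)

    if method == "fixed":
        if threshold is None:
            raise ValueError("method 'fixed' requires a threshold")
        out = pd.Series(intensity > threshold, index=cells.index, name=marker)
        out.attrs["thresholds"] = {"all": float(threshold)}
        return out

    if slide_col is not None and slide_col in cells.columns:
        groups = cells[slide_col].astype(str)
    else:
        groups = pd.Series("all", index=cells.index)

    positive = np.zeros(len(cells), dtype=bool)
    thresholds: dict[str, float | None] = {}
    for slide, idx in groups.groupby(groups).groups.items():
        vals = cells.loc[idx, col].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            warnings.warn(f"marker {marker} constant on slide {slide}; all negative")
            thresholds[str(slide)] = None
            continue
        logv = np.log(np.maximum(vals, 1e-12))
        if method == "gmm2":
            t = _gmm2_threshold(logv, seed=seed)
            if t is None:
                warnings.warn(
                    f"marker {marker} not bimodal on slide {slide}; all negative"
                )
                thresholds[str(slide)] = None
                continue
        elif method == "otsu":
            from skimage.filters import threshold_otsu

            t = float(threshold_otsu(logv))
        else:
            raise ValueError(f"unknown binarization method '{method}'")
        pos_here = logv > t
        positions = cells.index.get_indexer(idx)
        positive[positions] = pos_here
        thresholds[str(slide)] = float(np.exp(t))

    out = pd.Series(positive, index=cells.index, name=marker)
    out.attrs["thresholds"] = thresholds
    return out


def binarize_panel(
    cells: pd.DataFrame,
    markers: tuple[str, ...] = CLASSIFICATION_MARKERS,
    method: str = "gmm2",
    slide_col: str | None = "tma_id",
    seed: int = 0,
) -> pd.DataFrame:
    """Positivity matrix (cells x markers) for a set of markers."""
    cols = {
        m: binarize_marker(cells, m, method=method, slide_col=slide_col, seed=seed)
        for m in markers
    }
    out = pd.DataFrame(cols, index=cells.index)
    out.attrs["thresholds"] = {m: s.attrs.get("thresholds") for m, s in cols.items()}
    return out


# ---------------------------------------------------------------------------
# Rule-table classification


def classify_rule_table(positivity: pd.DataFrame) -> pd.Series:
    """Map per-cell positivity patterns to the eight classes.

    ``positivity`` must contain boolean columns for all six classification
    markers.  Total on all 64 patterns; every cell receives exactly one
    class.
    """
    missing = set(CLASSIFICATION_MARKERS) - set(positivity.columns)
    if missing:
        raise ValueError(f"positivity missing markers: {sorted(missing)}")
    ae1 = positivity["AE1"].to_numpy(dtype=bool)
    cd3 = positivity["CD3"].to_numpy(dtype=bool)
    cd4 = positivity["CD4"].to_numpy(dtype=bool)
    cd8 = positivity["CD8"].to_numpy(dtype=bool)
    foxp3 = positivity["FOXP3"].to_numpy(dtype=bool)
    pd1 = positivity["PD1"].to_numpy(dtype=bool)

    tc = ~ae1 & cd3 & cd8 & ~cd4
    th = ~ae1 & cd3 & cd4 & ~cd8 & ~foxp3
    treg = ~ae1 & cd3 & cd4 & ~cd8 & foxp3
    labels = np.select(
        [
            ae1,
            tc & ~pd1,
            tc & pd1,
            th & ~pd1,
            th & pd1,
            treg & ~pd1,
            treg & pd1,
        ],
        ["Epithelial", "Tc", "TcPD1", "Th", "ThPD1", "Treg", "TregPD1"],
        default="Other",
    )
    out = pd.Series(labels, index=positivity.index, name="class_call")
    out.attrs["source"] = "rule"
    return out


def _check_rule_table_consistency() -> None:
    """Internal sanity check: vectorized table equals the scalar gate."""
    from itertools import product

    patterns = pd.DataFrame(
        list(product([False, True], repeat=6)), columns=list(CLASSIFICATION_MARKERS)
    )
    vec = classify_rule_table(patterns)
    for i, row in patterns.iterrows():
        assert vec.iloc[i] == classify_pattern(*row), row


# ---------------------------------------------------------------------------
# Annotations


@dataclass
class AnnotationSet:
    """Annotated cells for classifier training.

    ``marker_labels`` holds per-marker positivity assertions (columns
    ``cell_id``, ``marker``, ``positive``); ``class_labels`` holds
    multi-class assertions (columns ``cell_id``, ``label``).  Either may be
    empty.  ``annotator`` records provenance (manual or automatic).
    """

    marker_labels: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cell_id", "marker", "positive"])
    )
    class_labels: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cell_id", "label"])
    )
    annotator: str = "manual"

    def __post_init__(self) -> None:
        dup = self.class_labels.groupby("cell_id")["label"].nunique()
        if (dup > 1).any():
            bad = dup.index[dup > 1][0]
            raise ValueError(f"conflicting class labels for cell '{bad}'")
        dup_m = self.marker_labels.groupby(["cell_id", "marker"])["positive"].nunique()
        if (dup_m > 1).any():
            raise ValueError("conflicting marker positivity annotations")

    def validate_against(self, cells: pd.DataFrame) -> None:
        known = set(cells["cell_id"])
        for df in (self.marker_labels, self.class_labels):
            unknown = set(df["cell_id"]) - known
            if unknown:
                raise ValueError(
                    f"annotations reference unknown cells, e.g. {sorted(unknown)[:3]}"
                )


# ---------------------------------------------------------------------------
# SVM models


@dataclass
class MarkerSVM:
    """Binary linear SVM for one marker on (mean, SD) intensity features."""

    marker: str
    pipeline: Pipeline
    training_accuracy: float

    def predict(self, cells: pd.DataFrame) -> pd.Series:
        X = np.log(
            np.maximum(
                cells[[f"mean_{self.marker}", f"sd_{self.marker}"]].to_numpy(float),
                1e-12,
            )
        )
        return pd.Series(
            self.pipeline.predict(X).astype(bool), index=cells.index, name=self.marker
        )


@dataclass
class MultiMarkerSVM:
    """Eight-class one-vs-rest linear SVM on 12 intensity features."""

    pipeline: Pipeline
    training_accuracy: float
    cv_accuracy_mean: float
    cv_accuracy_sd: float
    classes: tuple[str, ...]

    def predict(self, cells: pd.DataFrame) -> pd.Series:
        X = _multimarker_features(cells)
        out = pd.Series(self.pipeline.predict(X), index=cells.index, name="class_call")
        out.attrs["source"] = "svm"
        return out


def _multimarker_features(cells: pd.DataFrame) -> np.ndarray:
    cols = [f"{stat}_{m}" for m in CLASSIFICATION_MARKERS for stat in ("mean", "sd")]
    missing = [c for c in cols if c not in cells.columns]
    if missing:
        raise ValueError(f"cells table missing feature columns: {missing}")
    # Log features: lognormal intensities become roughly Gaussian.
    return np.log(np.maximum(cells[cols].to_numpy(dtype=float), 1e-12))


def train_marker_svm(
    cells: pd.DataFrame,
    annotations: AnnotationSet,
    marker: str,
    C: float = 1.0,
    seed: int = 0,
) -> MarkerSVM:
    """Train a binary positive/negative SVM for one marker.

    Features are the annotated cells' mean and SD intensity for that marker,
    standardized.  At least five distinct annotated images (cores) are
    recommended; fewer triggers a warning, not an error.
    """
    ann = annotations.marker_labels
    ann = ann[ann["marker"] == marker]
    if ann.empty or ann["positive"].nunique() < 2:
        raise ValueError(
            f"annotations for {marker} contain a single class; annotate both "
            "positive and negative cells before training"
        )
    sub = cells.set_index("cell_id").loc[ann["cell_id"]]
    if "core_id" in sub.columns and sub["core_id"].nunique() < 5:
        warnings.warn(
            f"only {sub['core_id'].nunique()} annotated images for {marker}; "
            "five or more are recommended"
        )
    X = np.log(np.maximum(sub[[f"mean_{marker}", f"sd_{marker}"]].to_numpy(float), 1e-12))
    y = ann["positive"].to_numpy(dtype=bool)
    pipe = make_pipeline(
        StandardScaler(), SVC(kernel="linear", C=C, random_state=seed)
    )
    pipe.fit(X, y)
    acc = float((pipe.predict(X) == y).mean())
    return MarkerSVM(marker=marker, pipeline=pipe, training_accuracy=acc)


def train_multimarker_svm(
    cells: pd.DataFrame,
    annotations: AnnotationSet,
    C: float = 1.0,
    seed: int = 0,
    cv_folds: int = 3,
) -> MultiMarkerSVM:
    """Train the eight-class linear SVM on all six classification markers.

    Classes with fewer than three annotations are dropped with a warning.
    Training accuracy comes from the model refit on all annotations (used
    for prediction); generalization is estimated by stratified k-fold
    cross-validation.
    """
    ann = annotations.class_labels
    if ann.empty:
        raise ValueError("empty class annotation set")
    counts = ann["label"].value_counts()
    small = counts[counts < 3]
    if not small.empty:
        warnings.warn(f"dropping classes with <3 annotations: {list(small.index)}")
        ann = ann[~ann["label"].isin(small.index)]
    if ann["label"].nunique() < 2:
        raise ValueError("need annotations for at least two classes")
    sub = cells.set_index("cell_id").loc[ann["cell_id"]].reset_index()
    X = _multimarker_features(sub)
    y = ann["label"].to_numpy()
    pipe = make_pipeline(
        StandardScaler(),
        SVC(kernel="linear", C=C, decision_function_shape="ovr", random_state=seed),
    )
    cv_mean, cv_sd = _cv_accuracy(pipe, X, y, k=cv_folds, seed=seed)
    pipe.fit(X, y)
    acc = float((pipe.predict(X) == y).mean())
    return MultiMarkerSVM(
        pipeline=pipe,
        training_accuracy=acc,
        cv_accuracy_mean=cv_mean,
        cv_accuracy_sd=cv_sd,
        classes=tuple(sorted(set(y))),
    )


def _cv_accuracy(pipe, X, y, k: int, seed: int) -> tuple[float, float]:
    min_class = pd.Series(y).value_counts().min()
    folds = int(min(k, min_class))
    if folds < k:
        warnings.warn(f"reducing CV folds from {k} to {folds} (smallest class size)")
    if folds < 2:
        return float("nan"), float("nan")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(pipe, X, y, cv=cv)
    return float(scores.mean()), float(scores.std())


def crossval_accuracy(
    cells: pd.DataFrame,
    annotations: AnnotationSet,
    marker: str | None = None,
    k: int = 3,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validated accuracy for an SVM specification.

    ``marker=None`` evaluates the multi-marker eight-class model; otherwise
    the binary model for that marker.  Deterministic given ``seed``; folds
    are reduced with a warning when the smallest class has fewer members
    than ``k``.  Returns overall mean/SD plus per-class recall.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if marker is None:
        ann = annotations.class_labels
        sub = cells.set_index("cell_id").loc[ann["cell_id"]].reset_index()
        X = _multimarker_features(sub)
        y = ann["label"].to_numpy()
    else:
        ann = annotations.marker_labels
        ann = ann[ann["marker"] == marker]
        sub = cells.set_index("cell_id").loc[ann["cell_id"]].reset_index()
        X = np.log(
            np.maximum(sub[[f"mean_{marker}", f"sd_{marker}"]].to_numpy(float), 1e-12)
        )
        y = ann["positive"].to_numpy()

    min_class = pd.Series(y).value_counts().min()
    folds = int(min(k, min_class))
    if folds < k:
        warnings.warn(f"reducing CV folds from {k} to {folds} (smallest class size)")
    if folds < 2:
        raise ValueError("not enough annotations per class for cross-validation")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = []
    per_class_correct: dict = {}
    per_class_total: dict = {}
    for train_idx, test_idx in cv.split(X, y):
        pipe = make_pipeline(
            StandardScaler(), SVC(kernel="linear", C=1.0, random_state=seed)
        )
        pipe.fit(X[train_idx], y[train_idx])
        pred = pipe.predict(X[test_idx])
        fold_acc.append(float((pred == y[test_idx]).mean()))
        for cls in np.unique(y[test_idx]):
            m = y[test_idx] == cls
            per_class_correct[cls] = per_class_correct.get(cls, 0) + int((pred[m] == cls).sum())
            per_class_total[cls] = per_class_total.get(cls, 0) + int(m.sum())
    return {
        "folds": folds,
        "accuracy_mean": float(np.mean(fold_acc)),
        "accuracy_sd": float(np.std(fold_acc)),
        "per_class_recall": {
            str(c): per_class_correct[c] / per_class_total[c] for c in per_class_total
        },
    }


# ---------------------------------------------------------------------------
# Automated annotation + probabilistic model


def auto_annotate(
    cells: pd.DataFrame,
    markers: tuple[str, ...] = CLASSIFICATION_MARKERS,
    nuclear_area_bounds: tuple[float, float] = (100.0, 3000.0),
    min_candidates: int = 20,
    negatives_per_positive: float = 1.0,
    seed: int = 0,
) -> AnnotationSet:
    """Harvest a training set automatically from intensity and morphology.

    Candidate positives per marker are the brightest cells of the marker's
    upper intensity mode — above the upper component mean of a
    two-component mixture fit on log intensities (a flat percentile alone
    floods the candidate set with bright negatives whenever true positives
    are rarer than the percentile) — with nuclear area inside QC bounds;
    candidates without a segmented nucleus are discarded.  Markers whose
    intensity distribution is not bimodal (no positive population) are
    skipped with a warning.  Matched negatives are sampled from below the
    lower component mean.  Cells asserted positive for mutually exclusive
    markers (epithelial AE1 vs the T lineage) keep only the marker with the
    highest intensity z-score.
    """
    rng = np.random.default_rng(seed)
    lo, hi = nuclear_area_bounds
    has_nucleus = cells["nucleus_count"] >= 1
    nuc_ok = has_nucleus & cells["area_nucleus"].gt(lo) & cells["area_nucleus"].lt(hi)

    zscores = {}
    candidates = {}
    neg_pools = {}
    for marker in markers:
        vals = cells[f"mean_{marker}"].to_numpy(dtype=float)
        logv = np.log(np.maximum(vals, 1e-12))
        mu, sd = logv.mean(), logv.std()
        zscores[marker] = (logv - mu) / sd if sd > 0 else np.zeros_like(logv)
        comps = _gmm2_components(logv, seed=seed) if np.ptp(logv) > 0 else None
        if comps is None:
            candidates[marker] = pd.Series(False, index=cells.index)
            neg_pools[marker] = pd.Series(False, index=cells.index)
            continue
        _, mean_lo, mean_hi = comps
        candidates[marker] = pd.Series(logv > mean_hi, index=cells.index) & nuc_ok
        neg_pools[marker] = pd.Series(logv < mean_lo, index=cells.index) & nuc_ok

    # Resolve epithelial-vs-lineage conflicts by the larger z-score.
    cand_df = pd.DataFrame(candidates)
    z_df = pd.DataFrame(zscores, index=cells.index)
    lineage = [m for m in markers if m != "AE1"]
    if "AE1" in cand_df.columns and lineage:
        conflict = cand_df["AE1"] & cand_df[lineage].any(axis=1)
        if conflict.any():
            best_lineage_z = z_df.loc[conflict, lineage].max(axis=1)
            keep_ae1 = z_df.loc[conflict, "AE1"] >= best_lineage_z
            cand_df.loc[conflict[conflict].index[~keep_ae1], "AE1"] = False
            drop_lineage = conflict[conflict].index[keep_ae1]
            cand_df.loc[drop_lineage, lineage] = False

    rows = []
    for marker in markers:
        pos_idx = cand_df.index[cand_df[marker]]
        if len(pos_idx) < min_candidates:
            warnings.warn(
                f"marker {marker}: only {len(pos_idx)} auto-annotation candidates; skipped"
            )
            continue
        neg_pool = cells.index[neg_pools[marker]]
        n_neg = min(len(neg_pool), int(np.ceil(negatives_per_positive * len(pos_idx))))
        neg_idx = rng.choice(neg_pool, size=n_neg, replace=False)
        for i in pos_idx:
            rows.append({"cell_id": cells.at[i, "cell_id"], "marker": marker, "positive": True})
        for i in neg_idx:
            rows.append({"cell_id": cells.at[i, "cell_id"], "marker": marker, "positive": False})
    return AnnotationSet(
        marker_labels=pd.DataFrame(rows, columns=["cell_id", "marker", "positive"]),
        annotator="automatic",
    )


@dataclass
class _GaussianPair:
    """Class-conditional Gaussians with pooled covariance for one marker."""

    mean_pos: np.ndarray
    mean_neg: np.ndarray
    cov: np.ndarray
    prior_pos: float = 0.5

    def posterior_positive(self, X: np.ndarray) -> np.ndarray:
        lp = stats.multivariate_normal.logpdf(X, self.mean_pos, self.cov, allow_singular=True)
        ln = stats.multivariate_normal.logpdf(X, self.mean_neg, self.cov, allow_singular=True)
        logit = (lp + np.log(self.prior_pos)) - (ln + np.log(1 - self.prior_pos))
        return 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))


@dataclass
class ProbabilisticModel:
    """Per-marker Gaussian probability models on (log mean, log SD)."""

    markers: dict[str, _GaussianPair]


def fit_probabilistic_model(
    cells: pd.DataFrame, annotations: AnnotationSet
) -> ProbabilisticModel:
    """Fit one probability model per marker from an annotation set.

    Features are (log mean, log SD) intensity; each marker gets positive and
    negative class-conditional Gaussians with a pooled covariance.  A
    singular pooled covariance falls back to its diagonal with a warning.
    """
    ann = annotations.marker_labels
    if ann.empty:
        raise ValueError("empty annotation set; annotate or auto-annotate first")
    indexed = cells.set_index("cell_id")
    models: dict[str, _GaussianPair] = {}
    for marker, grp in ann.groupby("marker"):
        if grp["positive"].nunique() < 2:
            warnings.warn(f"marker {marker}: single-class annotations; skipped")
            continue
        sub = indexed.loc[grp["cell_id"]]
        X = np.log(
            np.maximum(sub[[f"mean_{marker}", f"sd_{marker}"]].to_numpy(float), 1e-12)
        )
        y = grp["positive"].to_numpy(dtype=bool)
        mp, mn = X[y].mean(axis=0), X[~y].mean(axis=0)
        centered = np.vstack([X[y] - mp, X[~y] - mn])
        cov = centered.T @ centered / max(len(X) - 2, 1)
        if np.linalg.cond(cov) > 1e12:
            warnings.warn(f"marker {marker}: singular pooled covariance; using diagonal")
            cov = np.diag(np.maximum(np.diag(cov), 1e-12))
        models[marker] = _GaussianPair(mean_pos=mp, mean_neg=mn, cov=cov)
    if not models:
        raise ValueError("no marker could be modelled from the annotations")
    return ProbabilisticModel(markers=models)


def predict_probabilistic(
    model: ProbabilisticModel, cells: pd.DataFrame
) -> pd.DataFrame:
    """Classify cells from per-marker posteriors combined via the gate table.

    A marker is called positive when its posterior exceeds 0.5.  Markers
    absent from the model (skipped during fitting) are treated as negative.
    Confidence is the product over classification markers of the posterior
    of the called state, clipped to [0, 1].
    """
    post = {}
    for marker in CLASSIFICATION_MARKERS:
        if marker in model.markers:
            X = np.log(
                np.maximum(
                    cells[[f"mean_{marker}", f"sd_{marker}"]].to_numpy(float), 1e-12
                )
            )
            post[marker] = model.markers[marker].posterior_positive(X)
        else:
            post[marker] = np.zeros(len(cells))
    post_df = pd.DataFrame(post, index=cells.index)
    positivity = post_df > 0.5
    calls = classify_rule_table(positivity)
    conf = np.where(positivity, post_df, 1.0 - post_df).prod(axis=1)
    out = pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy(),
            "class_call": calls.to_numpy(),
            "confidence": np.clip(conf, 0.0, 1.0),
        },
        index=cells.index,
    )
    out.attrs["source"] = "probabilistic"
    return out
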