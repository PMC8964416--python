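"""Cohort-level statistics: concordance, heterogeneity, clustering, survival.

Covers the analysis layer of the TMA workflow:

* pathologist-concordance tests (Welch's ANOVA with pairwise Welch t-tests,
  unadjusted),
* intra-tumor heterogeneity accounting across a patient's cores,
* Spearman correlation of subtype percents and Ward clustering of patients,
* Kaplan–Meier curves with log-rank tests on median-dichotomized scores,
* univariate Cox proportional-hazards models (likelihood-ratio p values) and
  multivariate models with AIC-greedy backward elimination, a VIF > 2
  collinearity screen, and Harrell's C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import T_CELL_CLASSES
from .tissue_scores import PCT_QUANTITIES

__all__ = [
    "HeterogeneityReport",
    "heterogeneity_summary",
    "demographics_summary",
    "welch_anova_pairwise",
    "spearman_matrix",
    "cluster_patients",
    "dichotomize_median",
    "km_logrank",
    "cox_univariate",
    "cox_multivariate_backward",
    "run_full_analysis",
]


def _pct(k: int, n: int) -> int:
    """Percent rounded to the nearest integer (half away from zero)."""
    return int(np.floor(100.0 * k / n + 0.5))


# ---------------------------------------------------------------------------
# Heterogeneity and demographics accounting


@dataclass
class HeterogeneityReport:
    """Counts of score concordance across each patient's cores.

    ``by_score[score]`` holds, per core-count stratum (2 or 3 cores) and
    overall: the number of patients, how many had identical categories on
    all cores (``all_same``), how many three-core patients had three
    distinct categories (``all_different``), and integer percentages
    recomputed from the counts.
    """

    by_score: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for score, strata in self.by_score.items():
            for stratum, d in strata.items():
                rows.append({"score": score, "stratum": stratum, **d})
        return pd.DataFrame(rows)


def heterogeneity_summary(cores: pd.DataFrame) -> HeterogeneityReport:
    """Summarize immune/stroma category concordance across cores per patient.

    Only patients with more than one assessable core are included.  A
    patient is heterogeneous for a score when their cores do not all carry
    the same category.
    """
    df = cores
    if "assessable" in df.columns:
        df = df[df["assessable"]]
    by_score: dict = {}
    for score, col in (("immune", "path_immune"), ("stroma", "path_stroma")):
        grouped = df.groupby("patient_id")[col].agg(["size", "nunique"])
        multi = grouped[grouped["size"] >= 2]
        strata: dict = {}
        for n_cores in (2, 3):
            sub = multi[multi["size"] == n_cores]
            n = len(sub)
            if n == 0:
                continue
            all_same = int((sub["nunique"] == 1).sum())
            entry = {
                "n_patients": n,
                "all_same": all_same,
                "heterogeneous": n - all_same,
                "pct_all_same": _pct(all_same, n),
                "pct_heterogeneous": _pct(n - all_same, n),
            }
            if n_cores == 3:
                all_diff = int((sub["nunique"] == 3).sum())
                entry["all_different"] = all_diff
                entry["pct_all_different"] = _pct(all_diff, n)
            strata[n_cores] = entry
        n_all = len(multi)
        het = int((multi["nunique"] > 1).sum())
        strata["overall"] = {
            "n_patients": n_all,
            "all_same": n_all - het,
            "heterogeneous": het,
            "pct_all_same": _pct(n_all - het, n_all) if n_all else 0,
            "pct_heterogeneous": _pct(het, n_all) if n_all else 0,
        }
        by_score[score] = strata
    return HeterogeneityReport(by_score=by_score)


def demographics_summary(
    patients: pd.DataFrame,
    categorical: tuple[str, ...] = ("sex", "t_stage", "n_stage", "lvi", "differentiation"),
    numeric: tuple[str, ...] = ("age", "lnc", "pln", "dfs_months", "os_months"),
) -> pd.DataFrame:
    """Demographic table: counts with one-decimal percentages per level,
    mean/SD and median/range for numeric covariates."""
    n = len(patients)
    rows = []
    for col in categorical:
        if col not in patients.columns:
            continue
        for level, count in patients[col].value_counts().sort_index().items():
            rows.append(
                {
                    "variable": col,
                    "level": str(level),
                    "count": int(count),
                    "pct": round(100.0 * count / n, 1),
                }
            )
    for col in numeric:
        if col not in patients.columns:
            continue
        v = patients[col].astype(float)
        rows.append(
            {
                "variable": col,
                "level": "mean_sd",
                "mean": round(v.mean(), 1),
                "sd": round(v.std(), 1),
                "median": round(v.median(), 1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Concordance, correlation, clustering


def welch_anova_pairwise(values: pd.Series, groups: pd.Series) -> dict:
    """Welch's (unequal-variance) one-way ANOVA plus pairwise Welch t-tests.

    Pairwise p values are unadjusted (no multiplicity correction).  A group
    with zero variance or fewer than two observations is an error.
    """
    import pingouin as pg

    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(groups)})
    levels = sorted(df["group"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for g in levels:
        sub = df.loc[df["group"] == g, "value"]
        if len(sub) < 2:
            raise ValueError(f"group '{g}' has fewer than two observations")
        if sub.var(ddof=1) == 0:
            raise ValueError(f"group '{g}' has zero variance")
    aov = pg.welch_anova(data=df, dv="value", between="group")
    pcol = next(c for c in aov.columns if c in ("p-unc", "p_unc"))
    p_overall = float(aov[pcol].iloc[0])
    pairwise = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            t = sps.ttest_ind(
                df.loc[df["group"] == a, "value"],
                df.loc[df["group"] == b, "value"],
                equal_var=False,
            )
            pairwise[(a, b)] = float(t.pvalue)
    return {"p_overall": p_overall, "pairwise": pairwise}


def spearman_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation matrix across columns; constant columns are NaN
    off-diagonal and flagged in ``.attrs['constant_columns']``."""
    if len(data) < 3:
        raise ValueError("need at least three observations")
    out = data.corr(method="spearman")
    constant = [c for c in data.columns if data[c].nunique() <= 1]
    for c in constant:
        out.loc[c, :] = np.nan
        out.loc[:, c] = np.nan
        out.loc[c, c] = 1.0
    np.fill_diagonal(out.values, 1.0)
    out.attrs["constant_columns"] = constant
    return out


def cluster_patients(
    data: pd.DataFrame, k: int = 2, standardize: bool = True, metric: str = "euclidean"
) -> pd.Series:
    """Ward agglomerative clustering of patients on subtype percents.

    Cut at ``k`` clusters; cluster labels are renumbered so cluster 1 has
    the highest mean total T-cell percent ("immune hot").  ``metric`` may be
    ``euclidean`` (Ward's natural metric) or ``correlation`` (distances fed
    to linkage directly).
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    if k > len(data):
        raise ValueError(f"k={k} exceeds the number of patients ({len(data)})")
    X = data.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if metric == "euclidean":
        Z = hierarchy.ward(X)
    elif metric == "correlation":
        Z = hierarchy.linkage(pdist(X, metric="correlation"), method="ward")
    else:
        raise ValueError("metric must be 'euclidean' or 'correlation'")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    total = data.sum(axis=1).to_numpy()
    order = sorted(
        np.unique(raw), key=lambda c: -float(np.mean(total[raw == c]))
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([remap[c] for c in raw], index=data.index, name="cluster")


# ---------------------------------------------------------------------------
# Survival


def dichotomize_median(values: pd.Series) -> pd.Series:
    """Split values at the sample median into ``low``/``high`` labels.

    ``low`` includes values equal to the median.  If median ties empty the
    high group, the split falls back to a strict one (``low`` = strictly
    below the median) with a warning.  All-identical values are an error.
    """
    v = pd.Series(values).astype(float)
    if len(v) < 2:
        raise ValueError("need at least two values")
    if v.nunique() == 1:
        raise ValueError("all values identical; no median split possible")
    med = v.median()
    low = v <= med
    if low.all():
        warnings.warn("median ties empty the high group; using strict split")
        low = v < med
    labels = pd.Series(np.where(low, "low", "high"), index=v.index, name="group")
    labels.attrs["median"] = float(med)
    return labels


def km_logrank(
    time: pd.Series, event: pd.Series, group: pd.Series
) -> dict:
    """Kaplan–Meier curves per group and a log-rank comparison.

    Returns ``{"curves": DataFrame(group, time, survival, at_risk),
    "p": float, "statistic": float}``.  Times must be positive and every
    group must contain at least one subject.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    t = np.asarray(time, float)
    e = np.asarray(event, int)
    g = np.asarray(group)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least two groups for a log-rank test")
    frames = []
    for lv in levels:
        m = g == lv
        if m.sum() == 0:
            raise ValueError(f"group '{lv}' has zero subjects")
        km = KaplanMeierFitter()
        km.fit(t[m], e[m], label=str(lv))
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        at_risk = [int((t[m] >= tt).sum()) for tt in sf["time"]]
        frames.append(sf.assign(group=str(lv), at_risk=at_risk))
    res = multivariate_logrank_test(t, g, e)
    return {
        "curves": pd.concat(frames, ignore_index=True),
        "p": float(res.p_value),
        "statistic": float(res.test_statistic),
    }


def _fit_cox(df: pd.DataFrame, time_col: str, event_col: str):
    from lifelines import CoxPHFitter

    cph = CoxPHFitter()
    cph.fit(df, duration_col=time_col, event_col=event_col)
    return cph


def cox_univariate(
    data: pd.DataFrame, covariate: str, time_col: str, event_col: str
) -> dict:
    """Univariate Cox PH fit for one covariate (Efron tie handling).

    Returns HR, 95% Wald CI bounds and the likelihood-ratio p value.
    """
    sub = data[[covariate, time_col, event_col]].dropna()
    if sub[event_col].sum() == 0:
        raise ValueError("no events; Cox model undefined")
    try:
        cph = _fit_cox(sub, time_col, event_col)
    except Exception as exc:  # lifelines ConvergenceError and kin
        warnings.warn(f"Cox fit failed for {covariate}: {exc}")
        return {"covariate": covariate, "converged": False}
    coef = float(cph.params_.iloc[0])
    se = float(cph.standard_errors_.iloc[0])
    lr = cph.log_likelihood_ratio_test()
    return {
        "covariate": covariate,
        "converged": True,
        "coef": coef,
        "hr": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
        "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
        "p_lr": float(lr.p_value),
        "n": int(len(sub)),
        "n_events": int(sub[event_col].sum()),
    }


def _design_matrix(
    data: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-code categoricals; return the design and variable->columns map."""
    cols: dict[str, list[str]] = {}
    parts = []
    for var in variables:
        s = data[var]
        if s.dtype == bool:
            parts.append(s.astype(float).rename(var))
            cols[var] = [var]
        elif pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
            cols[var] = [var]
        else:
            d = pd.get_dummies(s, prefix=var, drop_first=True, dtype=float)
            parts.append(d)
            cols[var] = list(d.columns)
    return pd.concat(parts, axis=1), cols


def _gvif(design: pd.DataFrame, groups: dict[str, list[str]]) -> dict[str, float]:
    """Generalized variance inflation factors per variable group.

    For a one-column variable this is the ordinary VIF; for a g-column
    factor the GVIF is scaled as GVIF^(1/g) so the >2 threshold applies
    per dimension.
    """
    X = design.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    names = list(design.columns)
    out = {}
    det_R = np.linalg.det(R)
    for var, cols in groups.items():
        idx = [names.index(c) for c in cols]
        rest = [i for i in range(len(names)) if i not in idx]
        if not rest:
            out[var] = 1.0
            continue
        det_11 = np.linalg.det(R[np.ix_(idx, idx)])
        det_22 = np.linalg.det(R[np.ix_(rest, rest)])
        if det_R <= 0:
            out[var] = np.inf
            continue
        gvif = det_11 * det_22 / det_R
        out[var] = float(gvif ** (1.0 / len(cols)))
    return out


def _backward_eliminate(
    df: pd.DataFrame,
    groups: dict[str, list[str]],
    time_col: str,
    event_col: str,
    protected: set[str],
):
    """Greedy AIC backward elimination over variable groups."""
    current = dict(groups)
    cph = _fit_cox(df[sum(current.values(), []) + [time_col, event_col]], time_col, event_col)
    best_aic = float(cph.AIC_partial_)
    improved = True
    while improved and len(current) > 1:
        improved = False
        best_drop, best_drop_aic = None, best_aic
        for var in list(current):
            if var in protected:
                continue
            trial = [c for v, cs in current.items() if v != var for c in cs]
            m = _fit_cox(df[trial + [time_col, event_col]], time_col, event_col)
            if float(m.AIC_partial_) < best_drop_aic:
                best_drop, best_drop_aic = var, float(m.AIC_partial_)
        if best_drop is not None:
            del current[best_drop]
            best_aic = best_drop_aic
            improved = True
    final = _fit_cox(df[sum(current.values(), []) + [time_col, event_col]], time_col, event_col)
    return current, final, best_aic


def cox_multivariate_backward(
    data: pd.DataFrame,
    covariates: list[str],
    time_col: str,
    event_col: str,
    biomarker: str | None = None,
    vif_threshold: float = 2.0,
    min_events: int = 10,
) -> dict:
    """Multivariate Cox model with backward elimination and a VIF screen.

    Procedure: (1) fit the full model on complete cases; (2) greedily drop
    the variable whose removal most decreases the AIC, until no removal
    helps; (3) compute (generalized) VIFs on the retained design and remove
    variables with VIF > ``vif_threshold`` one at a time, largest first,
    re-running step 2 after each removal; (4) report per-variable HRs, Wald
    CIs and likelihood-ratio p values, the model AIC and Harrell's C.  The
    biomarker competes for elimination like any other variable.
    """
    variables = list(covariates) + ([biomarker] if biomarker else [])
    sub = data[variables + [time_col, event_col]].dropna().copy()
    if int(sub[event_col].sum()) < min_events:
        raise ValueError(
            f"only {int(sub[event_col].sum())} events; need at least {min_events}"
        )
    design, groups = _design_matrix(sub, variables)
    # Drop constant columns (a level absent after complete-case filtering).
    for var, cols in list(groups.items()):
        keep = [c for c in cols if design[c].nunique() > 1]
        if not keep:
            del groups[var]
        else:
            groups[var] = keep
    df = pd.concat(
        [design[sum(groups.values(), [])], sub[[time_col, event_col]]], axis=1
    )

    # Exactly collinear variables (e.g. a duplicated covariate) make the
    # partial likelihood singular before any model can be fit; screen
    # infinite VIFs up front, dropping the later-listed duplicate.
    removed_vif: list[str] = []
    while len(groups) > 1:
        vifs = _gvif(df[sum(groups.values(), [])], groups)
        exploded = [v for v in groups if not np.isfinite(vifs[v]) or vifs[v] > 1e6]
        if not exploded:
            break
        drop = exploded[-1]
        removed_vif.append(drop)
        warnings.warn(f"removing perfectly collinear variable '{drop}'")
        del groups[drop]

    full = _fit_cox(df[sum(groups.values(), []) + [time_col, event_col]], time_col, event_col)
    full_aic = float(full.AIC_partial_)

    current, model, aic = _backward_eliminate(df, groups, time_col, event_col, set())
    while len(current) > 1:
        vifs = _gvif(df[sum(current.values(), [])], current)
        worst = max(vifs, key=vifs.get)
        if vifs[worst] <= vif_threshold:
            break
        removed_vif.append(worst)
        del current[worst]
        current, model, aic = _backward_eliminate(
            df, current, time_col, event_col, set()
        )

    rows = []
    ll_full = float(model.log_likelihood_)
    for var, cols in current.items():
        others = [c for v, cs in current.items() if v != var for c in cs]
        if others:
            reduced = _fit_cox(df[others + [time_col, event_col]], time_col, event_col)
            ll_red = float(reduced.log_likelihood_)
        else:
            ll_red = float(model._ll_null_)
        chi2 = 2.0 * (ll_full - ll_red)
        p = float(sps.chi2.sf(max(chi2, 0.0), df=len(cols)))
        for c in cols:
            coef = float(model.params_[c])
            se = float(model.standard_errors_[c])
            rows.append(
                {
                    "variable": var,
                    "term": c,
                    "hr": float(np.exp(coef)),
                    "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
                    "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
                    "p_lr": p,
                }
            )
    return {
        "final_variables": list(current),
        "removed_by_vif": removed_vif,
        "table": pd.DataFrame(rows),
        "aic": float(aic),
        "full_aic": full_aic,
        "harrell_c": float(model.concordance_index_),
        "biomarker_retained": biomarker in current if biomarker else None,
        "n": int(len(df)),
        "n_events": int(df[event_col].sum()),
    }


# ---------------------------------------------------------------------------
# Orchestration

CLINICAL_COVARIATES = [
    "t_stage", "n_stage", "age", "sex", "lnc", "pln", "differentiation", "lvi",
]


def run_full_analysis(
    cells: pd.DataFrame,
    cores: pd.DataFrame,
    patients: pd.DataFrame,
    seed: int = 0,
    min_cells_per_core: int = 100,
    binarize_method: str = "gmm2",
    quantities: tuple[str, ...] = PCT_QUANTITIES,
    multivariate_biomarker: str = "Treg",
) -> dict:
    """End-to-end analysis: QC, classification, scoring, statistics.

    Runs both the per-patient averaging and the hot-spot workflow and
    returns a bundle of result tables.  Deterministic given ``seed``.
    """
    from . import cell_classify, cell_quality, tissue_scores

    stage = "qc"
    try:
        kept, qc_report = cell_quality.apply_cell_filters(
            cells, core_dims=cores[["core_id", "width_px", "height_px"]]
        )
        cores_flagged = cell_quality.flag_assessable_cores(
            cores, kept, min_cells=min_cells_per_core
        )

        stage = "classification"
        positivity = cell_classify.binarize_panel(
            kept.merge(
                cores[["core_id", "tma_id"]], on="core_id", how="left"
            ).set_index(kept.index),
            markers=("AE1", "CD3", "CD4", "CD8", "FOXP3", "PD1", "CD45"),
            method=binarize_method,
            seed=seed,
        )
        classes = cell_classify.classify_rule_table(positivity)

        stage = "scoring"
        core_scores = tissue_scores.core_score_table(
            kept, positivity, classes, cores=cores_flagged
        )
        patient_scores = tissue_scores.patient_average(core_scores)
        hotspot_single = tissue_scores.hotspot_select(
            core_scores[core_scores["patient_id"].isin(patient_scores["patient_id"])],
            mode="single",
        )
        hotspot_multi = tissue_scores.hotspot_select(
            core_scores[core_scores["patient_id"].isin(patient_scores["patient_id"])],
            mode="multi",
        )

        stage = "concordance"
        merged = core_scores.merge(
            cores_flagged[["core_id", "path_immune", "path_stroma"]], on="core_id"
        )
        ok = merged[merged["assessable"]]
        concordance = {}
        try:
            concordance["immune"] = welch_anova_pairwise(
                ok["immune_score"], ok["path_immune"]
            )
            stroma_ok = ok[ok["stroma_score_defined"]]
            concordance["stroma"] = welch_anova_pairwise(
                stroma_ok["stroma_score"], stroma_ok["path_stroma"]
            )
        except ValueError as exc:
            concordance["error"] = str(exc)
        heterogeneity = heterogeneity_summary(cores_flagged[cores_flagged["assessable"]])

        stage = "clustering"
        pct_cols = [f"pct_{c}" for c in T_CELL_CLASSES]
        pat_idx = patient_scores.set_index("patient_id")
        correlation = spearman_matrix(pat_idx[pct_cols])
        clusters = {
            k: cluster_patients(pat_idx[pct_cols], k=k) for k in (2, 3)
        }

        stage = "survival"
        surv = patients.set_index("patient_id")
        results = {}
        for mode, table in (
            ("average", pat_idx),
            ("hotspot", hotspot_multi.set_index("patient_id")),
        ):
            joined = table.join(surv, how="inner")
            forest_rows = []
            km_out = {}
            for q in quantities:
                col = f"pct_{q}"
                for endpoint, (tcol, ecol) in {
                    "dfs": ("dfs_months", "dfs_event"),
                    "os": ("os_months", "os_event"),
                }.items():
                    try:
                        row = cox_univariate(joined, col, tcol, ecol)
                    except ValueError as exc:
                        row = {"covariate": col, "converged": False, "error": str(exc)}
                    row.update({"quantity": q, "endpoint": endpoint, "mode": mode})
                    forest_rows.append(row)
                try:
                    groups = dichotomize_median(joined[col])
                    km_out[q] = {
                        ep: km_logrank(joined[tc], joined[ec], groups)
                        for ep, (tc, ec) in {
                            "dfs": ("dfs_months", "dfs_event"),
                            "os": ("os_months", "os_event"),
                        }.items()
                    }
                except ValueError as exc:
                    km_out[q] = {"error": str(exc)}
            multiv = {}
            clin = joined.copy()
            clin["differentiation"] = clin["differentiation"].replace("missing", np.nan)
            for endpoint, (tcol, ecol) in {
                "dfs": ("dfs_months", "dfs_event"),
                "os": ("os_months", "os_event"),
            }.items():
                try:
                    multiv[endpoint] = cox_multivariate_backward(
                        clin,
                        CLINICAL_COVARIATES,
                        tcol,
                        ecol,
                        biomarker=f"pct_{multivariate_biomarker}",
                    )
                except ValueError as exc:
                    multiv[endpoint] = {"error": str(exc)}
            results[mode] = {
                "forest": pd.DataFrame(forest_rows),
                "km": km_out,
                "multivariate": multiv,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return {
        "qc_report": qc_report,
        "cores": cores_flagged,
        "core_scores": core_scores,
        "patient_scores": patient_scores,
        "hotspot_single": hotspot_single,
        "hotspot_multi": hotspot_multi,
        "concordance": concordance,
        "heterogeneity": heterogeneity,
        "correlation": correlation,
        "clusters": clusters,
        "survival": results,
    }
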