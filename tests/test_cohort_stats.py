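"""Statistics layer: heterogeneity, ANOVA, clustering, KM/Cox, elimination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmapheno import cohort_stats as cs
from tmapheno import synthetic_cohort as sc


class TestHeterogeneity:
    def _cores(self, patterns):
        rows = []
        for pid, (imm, st) in enumerate(patterns):
            for k, (i, s) in enumerate(zip(imm, st)):
                rows.append(
                    {
                        "core_id": f"P{pid}_c{k}",
                        "patient_id": f"P{pid}",
                        "path_immune": i,
                        "path_stroma": s,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_cores_homogeneous(self):
        cores = self._cores([(["high", "high"], ["low", "low"])])
        rep = cs.heterogeneity_summary(cores)
        assert rep.by_score["immune"]["overall"]["heterogeneous"] == 0
        assert rep.by_score["stroma"]["overall"]["all_same"] == 1

    def test_three_distinct_categories_all_different(self):
        cores = self._cores(
            [((["low", "moderate", "high"]), (["low", "low", "high"]))]
        )
        rep = cs.heterogeneity_summary(cores)
        assert rep.by_score["immune"][3]["all_different"] == 1
        assert rep.by_score["immune"][3]["heterogeneous"] == 1
        assert rep.by_score["stroma"][3]["all_different"] == 0

    def test_printed_count_fixture_reproduces_percentages(self, heterogeneity_cores):
        rep = cs.heterogeneity_summary(heterogeneity_cores)
        imm, st = rep.by_score["immune"], rep.by_score["stroma"]
        assert imm["overall"]["n_patients"] == 161
        assert imm["overall"]["heterogeneous"] == 104
        assert imm["overall"]["pct_heterogeneous"] == 65
        assert st["overall"]["heterogeneous"] == 101
        assert st["overall"]["pct_heterogeneous"] == 63
        assert imm[2]["all_same"] == 44 and imm[2]["pct_all_same"] == 44
        assert st[2]["all_same"] == 42 and st[2]["pct_all_same"] == 42
        assert imm[3]["all_different"] == 5 and imm[3]["pctt_all_different" if False else "pct_all_different"] == 8
        assert st[3]["all_different"] == 6 and st[3]["pct_all_different"] == 10

    def test_percentages_recompute_from_counts(self, heterogeneity_cores):
        rep = cs.heterogeneity_summary(heterogeneity_cores)
        for strata in rep.by_score.values():
            for entry in strata.values():
                n = entry["n_patients"]
                assert entry["all_same"] + entry["heterogeneous"] == n
                assert entry["pct_heterogeneous"] == int(
                    np.floor(100 * entry["heterogeneous"] / n + 0.5)
                )


def test_demographics_recompute_printed_percentages(demographics_patients):
    table = cs.demographics_summary(demographics_patients).set_index(["variable", "level"])
    expected = {
        ("sex", "F"): (46, 39.3),
        ("sex", "M"): (71, 60.7),
        ("t_stage", "2"): (10, 8.5),
        ("t_stage", "3"): (70, 59.8),
        ("t_stage", "4"): (37, 31.6),
        ("n_stage", "1"): (83, 70.9),
        ("n_stage", "2"): (34, 29.1),
        ("lvi", "False"): (49, 41.9),
        ("lvi", "True"): (68, 58.1),
        ("differentiation", "moderate-to-well"): (99, 84.6),
        ("differentiation", "poor"): (16, 13.7),
        ("differentiation", "missing"): (2, 1.7),
    }
    for key, (count, pct) in expected.items():
        row = table.loc[key]
        assert row["count"] == count
        assert row["pct"] == pytest.approx(pct)


class TestWelchAnova:
    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.normal(0, 1, 50), rng.normal(5, 1, 50), rng.normal(10, 1, 50)]
        )
        groups = np.repeat(["a", "b", "c"], 50)
        res = cs.welch_anova_pairwise(pd.Series(values), pd.Series(groups))
        assert res["p_overall"] < 0.001
        assert res["pairwise"][("a", "c")] < 0.001

    def test_null_p_uniform(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(300):
            values = rng.normal(size=60)
            groups = np.repeat(["a", "b", "c"], 20)
            pvals.append(
                cs.welch_anova_pairwise(pd.Series(values), pd.Series(groups))["p_overall"]
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_matches_reference_implementation(self):
        """Cross-check against the general Welch formula via scipy's
        one-way with unequal variances (alexandergovern approximates)."""
        rng = np.random.default_rng(2)
        a, b, c = rng.normal(0, 1, 30), rng.normal(0.5, 2, 40), rng.normal(1, 0.5, 25)
        values = pd.Series(np.concatenate([a, b, c]))
        groups = pd.Series(["a"] * 30 + ["b"] * 40 + ["c"] * 25)
        ours = cs.welch_anova_pairwise(values, groups)["p_overall"]
        # Independent oracle: explicit Welch ANOVA computation.
        gs = [a, b, c]
        w = [len(g) / np.var(g, ddof=1) for g in gs]
        mw = sum(wi * g.mean() for wi, g in zip(w, gs)) / sum(w)
        k = len(gs)
        num = sum(wi * (g.mean() - mw) ** 2 for wi, g in zip(w, gs)) / (k - 1)
        lam = sum(
            (1 - wi / sum(w)) ** 2 / (len(g) - 1) for wi, g in zip(w, gs)
        )
        den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
        f = num / den
        df2 = (k**2 - 1) / (3 * lam)
        p_oracle = stats.f.sf(f, k - 1, df2)
        assert ours == pytest.approx(p_oracle, rel=1e-6)

    def test_zero_variance_group_errors(self):
        values = pd.Series([1.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        groups = pd.Series(["a", "a", "a", "b", "b", "b"])
        with pytest.raises(ValueError, match="zero variance"):
            cs.welch_anova_pairwise(values, groups)


class TestSpearman:
    def test_monotone_transform_perfect_rho(self):
        x = pd.Series(np.arange(20, dtype=float))
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
        m = cs.spearman_matrix(df)
        assert m.loc["x", "y"] == pytest.approx(1.0)
        assert m.loc["x", "z"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(1000, 3)), columns=list("abc"))
        m = cs.spearman_matrix(df)
        off = m.values[~np.eye(3, dtype=bool)]
        assert (np.abs(off) < 0.1).all()

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        m = cs.spearman_matrix(df)
        assert np.isnan(m.loc["a", "b"])
        assert m.attrs["constant_columns"] == ["b"]


class TestClustering:
    def test_two_blobs_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        hot = rng.normal(5, 0.3, size=(20, 4))
        cold = rng.normal(0, 0.3, size=(25, 4))
        df = pd.DataFrame(np.vstack([hot, cold]))
        labels = cs.cluster_patients(df, k=2)
        truth = [1] * 20 + [2] * 25
        assert adjusted_rand_score(truth, labels) == 1.0
        # hot cluster (higher total) is labelled 1
        assert (labels.iloc[:20] == 1).all()

    def test_duplicated_rows_cocluster(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 3))
        df = pd.DataFrame(np.vstack([base, base[0]]))
        for k in (2, 3):
            labels = cs.cluster_patients(df, k=k)
            assert labels.iloc[0] == labels.iloc[-1]

    def test_k_one_single_cluster(self):
        df = pd.DataFrame(np.random.default_rng(2).normal(size=(10, 3)))
        assert (cs.cluster_patients(df, k=1) == 1).all()

    def test_k_exceeding_n_errors(self):
        df = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            cs.cluster_patients(df, k=5)


class TestDichotomize:
    def test_even_split(self):
        labels = cs.dichotomize_median(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(labels) == ["low", "low", "high", "high"]

    def test_median_ties_go_low(self):
        labels = cs.dichotomize_median(pd.Series([1.0, 2.0, 2.0, 3.0]))
        assert list(labels) == ["low", "low", "low", "high"]

    def test_all_identical_errors(self):
        with pytest.raises(ValueError, match="identical"):
            cs.dichotomize_median(pd.Series([2.0, 2.0, 2.0]))

    def test_group_size_gap_bounded_by_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = pd.Series(rng.integers(0, 10, 21).astype(float))
            if v.nunique() == 1:
                continue
            labels = cs.dichotomize_median(v)
            n_low, n_high = (labels == "low").sum(), (labels == "high").sum()
            ties = (v == v.median()).sum()
            # ties all land in the low group, so the imbalance they add is
            # at most twice their count (they also deplete the high side)
            assert abs(n_low - n_high) <= 2 * ties


class TestKMLogrank:
    def test_identical_groups_p_one(self):
        t = np.array([3.0, 5.0, 7.0, 9.0, 11.0])
        e = np.array([1, 0, 1, 1, 0])
        time = np.concatenate([t, t])
        event = np.concatenate([e, e])
        group = ["a"] * 5 + ["b"] * 5
        res = cs.km_logrank(pd.Series(time), pd.Series(event), pd.Series(group))
        assert res["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        t1 = rng.exponential(5, 50)
        t2 = t1.max() + rng.exponential(5, 50)  # strictly greater
        res = cs.km_logrank(
            pd.Series(np.concatenate([t1, t2])),
            pd.Series(np.ones(100, dtype=int)),
            pd.Series(["short"] * 50 + ["long"] * 50),
        )
        assert res["p"] < 0.05

    def test_km_starts_at_one(self):
        res = cs.km_logrank(
            pd.Series([1.0, 2.0, 3.0, 4.0]),
            pd.Series([1, 1, 1, 1]),
            pd.Series(["a", "a", "b", "b"]),
        )
        for _, grp in res["curves"].groupby("group"):
            assert grp.sort_values("time")["survival"].iloc[0] == pytest.approx(1.0)

    def test_positive_times_required(self):
        with pytest.raises(ValueError, match="positive"):
            cs.km_logrank(
                pd.Series([0.0, 1.0]), pd.Series([1, 1]), pd.Series(["a", "b"])
            )


def _simulate_cox(n, hr, seed, censor=0.1):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1.0 / (0.05 * hr**x))
    c = rng.exponential(1.0 / (0.05 * censor)) if censor > 0 else np.full(n, np.inf)
    return pd.DataFrame(
        {
            "x": x,
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
        }
    )


class TestCoxUnivariate:
    def test_reparameterization_invariance(self):
        df = _simulate_cox(300, 0.5, 0)
        a = cs.cox_univariate(df, "x", "time", "event")
        df2 = df.assign(x=df["x"] * 10.0)
        b = cs.cox_univariate(df2, "x", "time", "event")
        assert b["coef"] == pytest.approx(a["coef"] / 10.0, rel=1e-4)
        assert b["p_lr"] == pytest.approx(a["p_lr"], rel=1e-6)

    def test_null_p_uniform(self):
        pvals = [
            cs.cox_univariate(_simulate_cox(150, 1.0, s), "x", "time", "event")["p_lr"]
            for s in range(150)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_hr_recovery(self):
        hits = 0
        for s in range(25):
            r = cs.cox_univariate(_simulate_cox(1000, 0.5, 100 + s, censor=0), "x", "time", "event")
            hits += 0.4 < r["hr"] < 0.6
        assert hits >= 22

    def test_ci_contains_point_estimate(self):
        r = cs.cox_univariate(_simulate_cox(200, 0.7, 5), "x", "time", "event")
        assert r["ci_low"] <= r["hr"] <= r["ci_high"]
        assert 0 < r["p_lr"] <= 1

    def test_no_events_errors(self):
        df = _simulate_cox(50, 1.0, 0)
        df["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            cs.cox_univariate(df, "x", "time", "event")


class TestCoxBackward:
    def _clinical(self, n, seed, beta_x=np.log(0.3)):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)  # true-effect biomarker
        noise = {f"z{i}": rng.normal(0, 1, n) for i in range(4)}
        lp = beta_x * x
        t = rng.exponential(np.exp(-lp) / 0.05)
        c = rng.exponential(1.0 / 0.01, n)
        return pd.DataFrame(
            {
                "x": x,
                **noise,
                "time": np.minimum(t, c),
                "event": (t <= c).astype(int),
            }
        )

    def test_collinear_duplicate_removed_by_vif(self):
        df = self._clinical(300, 0)
        df["x_copy"] = df["x"]
        res = cs.cox_multivariate_backward(
            df, ["x", "x_copy", "z0", "z1"], "time", "event"
        )
        assert not {"x", "x_copy"} <= set(res["final_variables"])

    def test_final_aic_never_exceeds_full(self):
        for seed in range(5):
            df = self._clinical(200, seed)
            res = cs.cox_multivariate_backward(
                df, ["x", "z0", "z1", "z2", "z3"], "time", "event"
            )
            assert res["aic"] <= res["full_aic"] + 1e-9

    def test_true_biomarker_retained(self):
        kept = 0
        reps = 20
        for seed in range(reps):
            df = self._clinical(500, 50 + seed)
            res = cs.cox_multivariate_backward(
                df, ["z0", "z1", "z2", "z3"], "time", "event", biomarker="x"
            )
            kept += res["biomarker_retained"]
        assert kept >= 0.9 * reps

    def test_too_few_events_errors(self):
        df = self._clinical(30, 0)
        df["event"] = 0
        df.loc[:3, "event"] = 1
        with pytest.raises(ValueError, match="events"):
            cs.cox_multivariate_backward(df, ["x", "z0"], "time", "event")


class TestFullPipeline:
    @pytest.fixture(scope="class")
    def bundle(self):
        cfg = sc.SimConfig(n_patients=25, cells_per_core=250, seed=17)
        patients, cores, cells = sc.generate_cohort(cfg)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cs.run_full_analysis(cells, cores, patients, seed=17)

    def test_smoke_schema(self, bundle):
        assert {"core_scores", "patient_scores", "survival", "heterogeneity"} <= set(bundle)
        forest = bundle["survival"]["average"]["forest"]
        conv = forest[forest["converged"]]
        assert (conv["hr"] > 0).all()
        assert ((conv["p_lr"] > 0) & (conv["p_lr"] <= 1)).all()
        assert (conv["ci_low"] <= conv["hr"]).all()
        assert (conv["hr"] <= conv["ci_high"]).all()

    def test_stage_error_naming(self):
        with pytest.raises((RuntimeError, ValueError), match="stage|field"):
            cs.run_full_analysis(
                pd.DataFrame({"cell_id": []}),
                pd.DataFrame({"core_id": [], "width_px": [], "height_px": []}),
                pd.DataFrame({"patient_id": []}),
            )
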