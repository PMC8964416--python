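import numpy as np
import pandas as pd
import pytest

from tmapheno import synthetic_cohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort: ~12 patients, ~300 cells/core."""
    cfg = sc.SimConfig(n_patients=12, cells_per_core=300, seed=7)
    patients, cores, cells = sc.generate_cohort(cfg)
    return cfg, patients, cores, cells


@pytest.fixture(scope="session")
def medium_cohort():
    """A mid-size cohort used by classifier-recovery tests."""
    cfg = sc.SimConfig(n_patients=15, cells_per_core=700, seed=11)
    patients, cores, cells = sc.generate_cohort(cfg)
    return cfg, patients, cores, cells


def make_heterogeneity_fixture() -> pd.DataFrame:
    """Cores for 161 multi-core patients with prescribed concordance counts.

    99 two-core patients: 44 immune-concordant, 42 stroma-concordant.
    62 three-core patients: immune 13 all-same / 5 all-different /
    44 partially discordant; stroma 18 / 6 / 38.
    """
    rows = []

    def two_core(pid, immune_same, stroma_same):
        imm = ["low", "low"] if immune_same else ["low", "high"]
        st = ["moderate", "moderate"] if stroma_same else ["moderate", "low"]
        for k in range(2):
            rows.append(
                {
                    "core_id": f"{pid}_c{k+1}",
                    "patient_id": pid,
                    "path_immune": imm[k],
                    "path_stroma": st[k],
                    "assessable": True,
                }
            )

    def three_core(pid, immune_kind, stroma_kind):
        patt = {
            "same": ["low", "low", "low"],
            "partial": ["low", "low", "high"],
            "alldiff": ["low", "moderate", "high"],
        }
        imm, st = patt[immune_kind], patt[stroma_kind]
        for k in range(3):
            rows.append(
                {
                    "core_id": f"{pid}_c{k+1}",
                    "patient_id": pid,
                    "path_immune": imm[k],
                    "path_stroma": st[k],
                    "assessable": True,
                }
            )

    for i in range(99):
        two_core(f"T2_{i:03d}", immune_same=i < 44, stroma_same=i < 42)

    # Three-core: immune kinds 13 same / 5 alldiff / 44 partial,
    # stroma kinds 18 same / 6 alldiff / 38 partial, paired arbitrarily.
    immune_kinds = ["same"] * 13 + ["alldiff"] * 5 + ["partial"] * 44
    stroma_kinds = ["same"] * 18 + ["alldiff"] * 6 + ["partial"] * 38
    rng = np.random.default_rng(0)
    rng.shuffle(stroma_kinds)
    for i, (ik, sk) in enumerate(zip(immune_kinds, stroma_kinds)):
        three_core(f"T3_{i:03d}", ik, sk)
    return pd.DataFrame(rows)


def make_demographics_fixture() -> pd.DataFrame:
    """117 patients with prescribed clinical covariate counts."""
    n = 117
    df = pd.DataFrame({"patient_id": [f"P{i:03d}" for i in range(n)]})
    df["sex"] = ["F"] * 46 + ["M"] * 71
    df["t_stage"] = [2] * 10 + [3] * 70 + [4] * 37
    df["n_stage"] = [1] * 83 + [2] * 34
    df["lvi"] = [False] * 49 + [True] * 68
    df["differentiation"] = ["moderate-to-well"] * 99 + ["poor"] * 16 + ["missing"] * 2
    return df


@pytest.fixture(scope="session")
def heterogeneity_cores():
    return make_heterogeneity_fixture()


@pytest.fixture(scope="session")
def demographics_patients():
    return make_demographics_fixture()
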