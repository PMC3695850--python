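"""Panel data model: IO round trips, dichotomization, design matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cepanel as cp
from cepanel.panel import group_counts


def test_write_read_round_trip(toy_panel, tmp_path):
    toy = cp.dichotomize_group(toy_panel)
    path = tmp_path / "panel.csv"
    cp.write_panel(toy, path)
    back = cp.read_panel(path, {"categorical": ["sex"]})
    back = cp.dichotomize_group(back)
    assert back.equals(toy)


def test_round_trip_preserves_missing_cells(toy_panel, tmp_path):
    toy = toy_panel.copy()
    toy.effectiveness[0, 2] = np.nan
    toy.interval_costs[1, 3] = np.nan
    path = tmp_path / "panel.csv"
    cp.write_panel(toy, path)
    back = cp.read_panel(path, {"categorical": ["sex"]})
    assert np.isnan(back.effectiveness[0, 2])
    assert np.isnan(back.interval_costs[1, 3])
    assert back.equals(toy)


def test_long_and_wide_dialects_parse_identically(toy_panel, tmp_path):
    long_path = tmp_path / "long.csv"
    cp.write_panel(toy_panel, long_path)
    wide_rows = []
    for i in range(toy_panel.n):
        row = {"patient_id": toy_panel.patient_ids[i],
               "group_score": toy_panel.group_score[i],
               "age": toy_panel.covariates.iloc[i]["age"],
               "sex": toy_panel.covariates.iloc[i]["sex"]}
        for k in range(toy_panel.K):
            row[f"eff_{k + 1}"] = toy_panel.effectiveness[i, k]
        for k in range(toy_panel.K - 1):
            row[f"cost_{k + 2}"] = toy_panel.interval_costs[i, k]
        wide_rows.append(row)
    wide_path = tmp_path / "wide.csv"
    pd.DataFrame(wide_rows).to_csv(wide_path, index=False)

    a = cp.read_panel(long_path, {"categorical": ["sex"]})
    b = cp.read_panel(wide_path, {
        "format": "wide", "times": toy_panel.nominal_times,
        "categorical": ["sex"], "covariates": ["age", "sex"]})
    assert a.equals(b)


def test_negative_cost_names_patient_and_interval(toy_panel, tmp_path):
    bad = toy_panel.copy()
    bad.interval_costs[1, 2] = -5.0
    path = tmp_path / "bad.csv"
    # bypass validation on write by editing the CSV directly
    cp.write_panel(toy_panel, path)
    df = pd.read_csv(path)
    df.loc[(df.patient_id == 2) & (df.mp == 4), "cost"] = -5.0
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match=r"patient.*2.*interval 4"):
        cp.read_panel(path)


def test_unknown_covariate_column_errors(toy_panel, tmp_path):
    path = tmp_path / "panel.csv"
    cp.write_panel(toy_panel, path)
    with pytest.raises(ValueError, match="unknown covariate"):
        cp.read_panel(path, {"covariates": ["nonexistent"]})


# -- dichotomization --------------------------------------------------------

def test_dichotomize_threshold_convention(toy_panel):
    out = cp.dichotomize_group(toy_panel, 4.0)
    # 3.9 -> low, 4.0 -> high (>= threshold), missing stays missing
    assert out.group[0] == 0.0
    assert out.group[1] == 1.0
    assert np.isnan(out.group[2])
    assert out.group[3] == 1.0


@pytest.mark.parametrize("threshold,expected_high", [
    (0.0, 3),      # all observed scores >= 0 -> all high
    (99.0, 0),     # threshold above max -> all low
])
def test_dichotomize_boundaries(toy_panel, threshold, expected_high):
    out = cp.dichotomize_group(toy_panel, threshold)
    counts = group_counts(out)
    assert counts["high"] == expected_high
    assert counts["low"] == 3 - expected_high
    assert counts["missing"] == 1


@given(st.lists(st.one_of(st.none(),
                          st.floats(0, 10, allow_nan=False)),
                min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_dichotomize_partitions_patients(scores):
    n = len(scores)
    ds = cp.PanelDataset(
        patient_ids=np.arange(n),
        nominal_times=np.array([0.0, 1.0]),
        effectiveness=np.ones((n, 2)),
        interval_costs=np.ones((n, 1)),
        group_score=np.array([np.nan if s is None else s for s in scores]),
        group=np.full(n, np.nan),
        covariates=pd.DataFrame(index=range(n)),
    )
    out = cp.dichotomize_group(ds, 4.0)
    c = group_counts(out)
    assert c["low"] + c["high"] + c["missing"] == n


# -- design construction ----------------------------------------------------

def test_design_column_count_one_binary_confounder():
    n = 6
    cov = pd.DataFrame({"b": [0.0, 1.0, 0.0, 1.0, 1.0, 0.0]})
    ds = cp.PanelDataset(
        patient_ids=np.arange(n),
        nominal_times=np.array([0.0, 3.0, 7.0, 9.0, 12.0]),
        effectiveness=np.ones((n, 5)),
        interval_costs=np.ones((n, 4)),
        group_score=np.linspace(3, 5, n),
        group=np.array([0, 1, 0, 1, 0, 1.0]),
        covariates=cov,
    )
    d = cp.build_design(ds, ["b"])
    # intercept + 1 confounder + 3 MP dummies + group = 6
    assert d.z.shape == (n, 4, 6)
    assert d.cols_z == ["intercept", "b", "mp3", "mp4", "mp5", "group"]
    # effectiveness design additionally carries the baseline score
    assert d.cols_e == ["intercept", "b", "baseline_eff",
                        "mp3", "mp4", "mp5", "group"]
    # cumulative rows have no MP terms
    assert d.cols_cum_cost == ["intercept", "b", "group"]


def test_design_empty_confounder_list(complete_ds):
    d = cp.build_design(complete_ds, [])
    assert d.cols_z == ["intercept", "mp3", "mp4", "mp5", "group"]
    assert d.z[:, :, 0].min() == 1.0


def test_design_missing_confounder_retained_as_nan(default_sim):
    ds = default_sim.data
    d = cp.build_design(ds, ["iip", "soc", "sas"])
    n_missing_rows = ds.covariates[["iip", "soc", "sas"]].isna().sum().sum()
    assert n_missing_rows > 0
    assert np.isnan(d.z[:, 0, 1:4]).sum() == n_missing_rows
    assert d.z.shape[0] == ds.n          # nothing dropped


def test_design_reference_level_absent_errors(complete_ds):
    with pytest.raises(ValueError, match="reference level"):
        cp.build_design(complete_ds, ["diagnosis"],
                        categorical=["diagnosis"],
                        reference={"diagnosis": "not-a-level"})


def test_design_full_rank_on_default_scenario(complete_ds):
    d = cp.build_design(complete_ds,
                        ["gender", "diagnosis", "iip", "soc", "sas"],
                        categorical=["gender", "diagnosis"])
    flat = d.e.reshape(-1, d.e.shape[-1])
    assert np.linalg.matrix_rank(flat) == flat.shape[1]
    assert np.linalg.matrix_rank(d.cum_cost) == d.cum_cost.shape[1]


# -- descriptive table ------------------------------------------------------

def test_missingness_table_counts(toy_panel):
    toy = cp.dichotomize_group(toy_panel)
    toy.effectiveness[3, 2] = np.nan
    tab = cp.missingness_table(toy)
    assert (tab.n_missing.sum()) == 1
    # two zero costs in interval 7-9 (patients 2 high, 3 excluded: missing
    # group) -> high group shows 1 zero in 7-9 plus patient 2's 9-12 etc.
    cell = tab[(tab.variable == "cost") & (tab.month == "7-9")
               & (tab.group == "high")]
    assert int(cell.n_zero.iloc[0]) == 1
    assert tab.attrs["n_missing_group"] == 1


def test_missingness_table_default_scenario_zero_share(default_sim):
    ds = cp.dichotomize_group(default_sim.complete)
    tab = cp.missingness_table(ds)
    cost = tab[tab.variable == "cost"].set_index(["month", "group"])
    for month in ("0-3", "3-7"):
        for g in ("low", "high"):
            frac = cost.loc[(month, g), "n_zero"] / cost.loc[(month, g),
                                                             "n_obs"]
            assert frac < 0.05
    for month in ("7-9", "9-12"):
        fracs = [cost.loc[(month, g), "n_zero"] / cost.loc[(month, g),
                                                           "n_obs"]
                 for g in ("low", "high")]
        assert 0.25 < np.mean(fracs) < 0.50
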