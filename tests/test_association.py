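"""Endpoints, summaries, regression models, KM and auxiliary tests."""

import math

import numpy as np
import pandas as pd
import pytest

from immunocontext.association import (chi_square_assoc, cohort_summary,
                                       derive_endpoints, durations_from_dates,
                                       fit_response_model,
                                       fit_survival_model, km_estimate,
                                       kruskal_wallis)
from immunocontext.cohort import CohortConfig, generate_cohort
from immunocontext.errors import DataError


def test_derive_endpoints_responder_and_validation():
    df = pd.DataFrame({
        "response": ["PR", "SD", "NE", "CR"],
        "pfs_time_months": [8.3, 12.0, 5.0, 7.0],
        "pfs_event": [1, 0, 1, 1],
        "os_time_months": [10.0, 14.0, 6.0, 9.0],
        "os_event": [1, 0, 0, 0],
    })
    out = derive_endpoints(df)
    assert out["responder"].tolist()[0] == 1.0
    assert out["responder"].tolist()[1] == 0.0
    assert pd.isna(out["responder"].iloc[2])
    with pytest.raises(DataError):
        derive_endpoints(pd.DataFrame({"pfs_time_months": [-1.0],
                                       "pfs_event": [1]}))


def test_durations_from_dates_censoring_rule():
    months, flag = durations_from_dates("2020-01-01", "2020-09-10", None)
    assert flag == 1 and months == pytest.approx(8.3, abs=0.05)
    months, flag = durations_from_dates("2020-01-01", None, "2021-01-01")
    assert flag == 0 and months == pytest.approx(12.0, abs=0.05)


def test_cohort_summary_printed_percentages():
    resp = ["CR"] * 26 + ["PR"] * 73 + ["SD"] * 25 + ["PD"] * 32
    out = cohort_summary(pd.DataFrame({"response": resp}))
    pct = dict(zip(out["level"], out["pct"]))
    assert pct == {"CR": 16.7, "PR": 46.8, "SD": 16.0, "PD": 20.5}
    single = cohort_summary(pd.DataFrame({"arm": ["A", "A", "A"]}))
    assert single["pct"].tolist() == [100.0]
    with pytest.raises(DataError):
        cohort_summary(pd.DataFrame())


def test_balanced_table_gives_unit_odds_ratio():
    df = pd.DataFrame({
        "cd8_i": ["high"] * 40 + ["low"] * 40,
        "response": (["PR"] * 20 + ["PD"] * 20) * 2,
    })
    res = fit_response_model(derive_endpoints(df), "cd8_i", covariates=())
    assert res.estimate("cd8_i=high") == pytest.approx(1.0, abs=1e-6)
    lo, hi = res.ci("cd8_i=high")
    assert lo <= 1.0 <= hi


def test_perfect_separation_reported_not_raised():
    df = pd.DataFrame({
        "cd8_i": ["high"] * 20 + ["low"] * 20,
        "response": ["PR"] * 20 + ["PD"] * 20,
    })
    res = fit_response_model(derive_endpoints(df), "cd8_i", covariates=())
    assert not res.estimable
    assert res.message


def test_cox_symmetry_unit_hazard_ratio():
    times = list(range(1, 21))
    df = pd.DataFrame({
        "group": [1] * 20 + [3] * 20,
        "os_time_months": times + times,
        "os_event": [1] * 40,
        "subsequent_it": ["no"] * 40,
    })
    res = fit_survival_model(df, "os", "group", covariates=())
    assert res.estimate("group=1") == pytest.approx(1.0, abs=1e-6)


def test_cox_invariances():
    df = derive_endpoints(generate_cohort(CohortConfig(n_patients=400,
                                                       seed=8)))
    covs = ["stage", "ecog_ps", "ldh_elevated", "treatment"]
    a = fit_survival_model(df, "os", "group", covariates=covs)
    b = fit_survival_model(df, "os", "group", covariates=covs[::-1])
    assert a.estimate("group=1") == pytest.approx(b.estimate("group=1"),
                                                 rel=1e-8)
    shifted = df.copy()
    shifted["os_time_months"] = shifted["os_time_months"] + 5.0
    c = fit_survival_model(shifted, "os", "group", covariates=covs)
    assert c.estimate("group=1") == pytest.approx(a.estimate("group=1"),
                                                 rel=1e-6)


def test_logistic_invariant_to_covariate_order():
    df = derive_endpoints(generate_cohort(CohortConfig(n_patients=400,
                                                       seed=9)))
    covs = ["stage", "ecog_ps", "ldh_elevated", "treatment"]
    a = fit_response_model(df, "group", covariates=covs)
    b = fit_response_model(df, "group", covariates=covs[::-1])
    assert a.estimate("group=1") == pytest.approx(b.estimate("group=1"),
                                                 rel=1e-8)


def test_no_events_non_estimable():
    df = pd.DataFrame({
        "group": [1, 2, 3, 1],
        "os_time_months": [1.0, 2.0, 3.0, 4.0],
        "os_event": [0, 0, 0, 0],
    })
    res = fit_survival_model(df, "os", "group", covariates=())
    assert not res.estimable and res.message == "no events"


def test_km_product_limit_hand_computed():
    df = pd.DataFrame({"os_time_months": list(range(1, 11)),
                       "os_event": [1] * 10})
    km = km_estimate(df, "os")
    # 10 uncensored times: steps of 0.1, median at the first t with S <= 0.5
    surv = km.curve.set_index("time")["survival"]
    assert surv.loc[5.0] == pytest.approx(0.5)
    assert km.median == 5.0
    # no censoring: KM equals the empirical survival function exactly
    for t in range(1, 11):
        assert surv.loc[float(t)] == pytest.approx(1 - t / 10)


def test_km_all_censored_median_not_reached():
    df = pd.DataFrame({"os_time_months": [3.0, 6.0, 9.0],
                       "os_event": [0, 0, 0]})
    km = km_estimate(df, "os")
    assert math.isinf(km.median)


def test_chi_square_examples():
    res = chi_square_assoc([[10, 10], [10, 10]])
    assert res.statistic == 0.0 and res.p == 1.0
    res = chi_square_assoc([[20, 5], [5, 20]])
    assert res.statistic == pytest.approx(18.0)
    assert res.dof == 1
    assert chi_square_assoc([[5, 10, 5], [10, 5, 10]]).dof == 2
    assert chi_square_assoc([[1, 0], [0, 1]]).low_expected


def test_kruskal_wallis_examples():
    # identical value everywhere
    h, p = kruskal_wallis([1, 1], [1, 1], [1, 1])
    assert h == 0.0 and p == 1.0
    # maximal separation of three groups of three: brute-force rank H
    groups = ([1, 2, 3], [10, 11, 12], [100, 101, 102])
    h, _ = kruskal_wallis(*groups)
    ranks = {v: r for r, v in enumerate(sorted(sum(map(list, groups), [])), 1)}
    n = 9
    h_brute = 12 / (n * (n + 1)) * sum(
        len(g) * (np.mean([ranks[v] for v in g]) - (n + 1) / 2) ** 2
        for g in groups)
    assert h == pytest.approx(h_brute)
    assert h == pytest.approx(7.2)
    with pytest.raises(DataError):
        kruskal_wallis([1.0])


def test_kruskal_wallis_null_p_uniformity():
    # identical distributions: p-values roughly uniform over replicates
    rng = np.random.default_rng(0)
    ps = []
    for _ in range(200):
        g = [rng.normal(size=30) for _ in range(3)]
        ps.append(kruskal_wallis(*g)[1])
    ps = np.array(ps)
    assert 0.35 < (ps > 0.5).mean() < 0.65
    assert (ps < 0.05).mean() < 0.12
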