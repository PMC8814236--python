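"""Cohort identification, propensity matching, and covariate balance."""

import numpy as np
import pandas as pd
import pytest

import emrpheno as ep
from emrpheno.cohort import covariates, smd
from emrpheno.synthetic import EmrTables


def _tables(patients_rows, dx_rows):
    patients = pd.DataFrame(
        patients_rows,
        columns=["patient_id", "sex", "birth_year", "race", "death_status",
                 "n_encounters", "span_years"])
    dx = pd.DataFrame(dx_rows, columns=["patient_id", "code", "date"])
    empty_med = pd.DataFrame(columns=["patient_id", "order_string", "date"])
    empty_lab = pd.DataFrame(columns=["patient_id", "test_name", "value", "date"])
    hier = pd.DataFrame(columns=["code", "level", "name", "parent"])
    return EmrTables(patients, dx, empty_med, empty_lab, hier)


def test_case_definition_age_and_codes():
    t = _tables(
        [("p1", "F", 1950, "Other", "alive", 5, 2.0),   # age 70, AD code
         ("p2", "M", 1960, "Other", "alive", 5, 2.0),   # age 60, AD code
         ("p3", "F", 1950, "Other", "alive", 5, 2.0),   # age 70, non-case code
         ("p4", "M", 1940, "Other", "alive", 5, 2.0)],  # age 80, no diagnoses
        [("p1", "G30.9", "2015-01-01"), ("p2", "G30.9", "2015-01-01"),
         ("p3", "G31.0", "2015-01-01")])
    assert ep.identify_cases(t) == {"p1"}
    pool = ep.eligible_controls(t)
    assert pool == {"p3", "p4"}
    assert not pool & ep.identify_cases(t)


def test_all_cases_empty_pool_error():
    t = _tables([("p1", "F", 1950, "Other", "alive", 5, 2.0)],
                [("p1", "G30.9", "2015-01-01")])
    with pytest.raises(ValueError, match="empty control pool"):
        ep.eligible_controls(t)


def test_propensity_intercept_only_equals_case_fraction():
    n = 40
    cov = pd.DataFrame({"sex": ["F"] * n, "age": [80.0] * n,
                        "race": ["Other"] * n, "death_status": ["alive"] * n},
                       index=[f"p{i}" for i in range(n)])
    cases = {f"p{i}" for i in range(10)}
    ps = ep.fit_propensity(cov, cases)
    assert np.allclose(ps, 0.25, atol=1e-6)
    assert ((ps > 0) & (ps < 1)).all()


def test_propensity_separation_falls_back_monotone(caplog):
    n = 40
    marker = ["yes"] * 20 + ["no"] * 20
    cov = pd.DataFrame({"sex": marker, "age": [80.0] * n,
                        "race": ["Other"] * n, "death_status": ["alive"] * n},
                       index=[f"p{i}" for i in range(n)])
    cases = {f"p{i}" for i in range(20)}  # perfectly predicted by marker
    with caplog.at_level("WARNING"):
        ps = ep.fit_propensity(cov, cases)
    assert "ridge" in caplog.text
    assert ps.iloc[:20].min() > ps.iloc[20:].max()
    assert ((ps > 0) & (ps < 1)).all()


def test_match_ratio_determinism_and_duplicate_balance():
    # pool contains two exact covariate duplicates of each case
    rows, dx = [], []
    for i in range(30):
        age_year = 1950 - (i % 10)
        rows.append((f"c{i}", "F" if i % 2 else "M", age_year, "Other",
                     "alive", 5, 2.0))
        dx.append((f"c{i}", "G30.9", "2015-01-01"))
        for j in range(2):
            rows.append((f"k{i}_{j}", "F" if i % 2 else "M", age_year, "Other",
                         "alive", 5, 2.0))
    t = _tables(rows, dx)
    cases, pool = ep.identify_cases(t), ep.eligible_controls(t)
    cov = covariates(t.patients)
    ps = ep.fit_propensity(cov, cases)
    m1 = ep.nn_match(ps, cases, pool, ratio=2, seed=9)
    m2 = ep.nn_match(ps, cases, pool, ratio=2, seed=9)
    assert m1.matched == m2.matched  # same seed -> identical result
    assert m1.complete
    assert len(m1.control_ids) == 2 * len(m1.case_ids)
    assert len(set(m1.control_ids)) == len(m1.control_ids)  # without replacement
    assert not set(m1.control_ids) & cases
    rep = ep.balance_report(cov, cases, pool, m1)
    assert rep.max_after == pytest.approx(0.0, abs=1e-12)


def test_smd_values():
    assert smd([1, 2, 3], [1, 2, 3], "continuous") == 0.0
    a = np.random.default_rng(0).normal(1, 1, 100000)
    b = np.random.default_rng(1).normal(0, 1, 100000)
    assert smd(a, b, "continuous") == pytest.approx(1.0, abs=0.02)
    # binary proportions 0.3 vs 0.2 -> 0.1/sqrt((0.21+0.16)/2)
    g1 = ["x"] * 30 + ["y"] * 70
    g2 = ["x"] * 20 + ["y"] * 80
    assert smd(g1, g2, "categorical") == pytest.approx(0.23250, abs=1e-4)
    assert smd([1, 1], [2, 2], "continuous") == float("inf")


def test_encounter_filter_boundaries():
    pats = pd.DataFrame({
        "patient_id": ["a", "b", "c"],
        "n_encounters": [10, 9, 12],
        "span_years": [1.5, 5.0, 1.0]})
    kept = ep.encounter_filter(pats, min_encounters=10, min_span_years=1.0)
    assert kept == {"a"}  # b: too few encounters; c: span not strictly > 1


def test_matching_improves_confounded_balance():
    # covariates confounded with case status: averaged over 10 seeds,
    # matching shrinks every SMD that starts above 0.1
    befores, afters = [], []
    for seed in range(1, 11):
        cfg = ep.confounded_config(n_patients=2000)
        t, _ = ep.generate_site(cfg, seed)
        cases, pool = ep.identify_cases(t), ep.eligible_controls(t)
        cov = covariates(t.patients)
        ps = ep.fit_propensity(cov, cases)
        m = ep.nn_match(ps, cases, pool, 2, seed=seed)
        rep = ep.balance_report(cov, cases, pool, m).table.set_index("covariate")
        befores.append(rep.smd_before)
        afters.append(rep.smd_after)
    mean_before = pd.concat(befores, axis=1).mean(axis=1)
    mean_after = pd.concat(afters, axis=1).mean(axis=1)
    big = mean_before[mean_before > 0.1]
    assert len(big) > 0, "confounding should imbalance some covariate"
    assert (mean_after[big.index] < big).all()
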