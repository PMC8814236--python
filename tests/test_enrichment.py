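"""2x2 association scans: tests, odds ratios, multiplicity, stratification."""

from itertools import product
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emrpheno as ep
from emrpheno.enrichment import ContingencyTable


def fisher_bruteforce(a, b, c, d):
    """Independent oracle: exact conditional two-sided p by enumerating all
    tables with the observed margins (hypergeometric)."""
    n1, n2, m1 = a + b, c + d, a + c
    n = n1 + n2
    denom = comb(n, m1)
    probs = {}
    for k in range(max(0, m1 - n2), min(n1, m1) + 1):
        probs[k] = comb(n1, k) * comb(n2, m1 - k) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs + 1e-12)


def test_build_table_counts():
    cases = {f"a{i}": ({"X"} if i < 4 else set()) for i in range(10)}
    controls = {f"b{i}": ({"X"} if i < 2 else set()) for i in range(20)}
    t = ep.build_table("X", cases, controls)
    assert (t.a, t.b, t.c, t.d) == (4, 6, 2, 18)
    swapped = ep.build_table("X", controls, cases)
    assert (swapped.a, swapped.b, swapped.c, swapped.d) == (2, 18, 4, 6)
    with pytest.raises(ValueError, match="overlap"):
        ep.build_table("X", cases, {"a0": set()})


def test_method_rule_and_examples():
    method, p = ep.test_table(ContingencyTable(5, 5, 5, 5))
    assert method == "chi2" and p == pytest.approx(1.0)
    method, p = ep.test_table(ContingencyTable(3, 0, 0, 3))
    assert method == "fisher" and p == pytest.approx(0.1)
    method, _ = ep.test_table(ContingencyTable(4, 100, 90, 100))
    assert method == "fisher"  # min cell 4 < 5
    method, p = ep.test_table(ContingencyTable(0, 10, 0, 10))
    assert p == 1.0  # zero margin


def test_fisher_matches_bruteforce_small_margins():
    for a, b, c, d in product(range(5), repeat=4):
        t = ContingencyTable(a, b, c, d)
        if t.n_cases == 0 or t.n_controls == 0:
            continue
        method, p = ep.test_table(t)
        if method == "fisher":
            assert p == pytest.approx(fisher_bruteforce(a, b, c, d), abs=1e-10)


def test_odds_ratio_values():
    assert ep.odds_ratio(ContingencyTable(5, 5, 5, 5)) == 1.0
    assert ep.odds_ratio(ContingencyTable(4, 6, 2, 18)) == pytest.approx(6.0)
    # Haldane-Anscombe: (10.5*5.5)/(0.5*5.5)
    assert ep.odds_ratio(ContingencyTable(10, 0, 5, 5)) == pytest.approx(21.0)


@given(st.tuples(*[st.integers(0, 40)] * 4))
@settings(max_examples=200, deadline=None)
def test_odds_ratio_reciprocal_under_group_swap(cells):
    a, b, c, d = cells
    if (a + b) == 0 or (c + d) == 0:
        return
    orig = ep.odds_ratio(ContingencyTable(a, b, c, d))
    swapped = ep.odds_ratio(ContingencyTable(c, d, a, b))
    assert orig * swapped == pytest.approx(1.0)


@given(st.tuples(st.integers(1, 30), st.integers(1, 30),
                 st.integers(1, 30), st.integers(1, 30)))
@settings(max_examples=200, deadline=None)
def test_odds_ratio_monotone_in_a(cells):
    a, b, c, d = cells
    assert ep.odds_ratio(ContingencyTable(a + 1, b, c, d)) >= \
        ep.odds_ratio(ContingencyTable(a, b, c, d))


def test_bonferroni_and_printed_cutoff():
    adj, thr = ep.bonferroni([0.01, 0.5], 10)
    assert adj == pytest.approx([0.1, 1.0])
    assert thr == pytest.approx(0.005)
    # the full-diagnosis family of 47,439 features gives the printed 1e-6 cutoff
    _, thr = ep.bonferroni([], 47439)
    assert f"{thr:.0e}" == "1e-06"


def test_classification_rule():
    assert ep.classify(0.001, 2.5) == "case_enriched"
    assert ep.classify(0.001, 0.4) == "control_enriched"
    assert ep.classify(0.001, 1.5) == "significant_other"
    assert ep.classify(0.2, 9.0) == "not_significant"


def test_scan_classifies_planted_or(small_site):
    from conftest import cohort_feature_sets
    _, tables, truth = small_site
    case_sets, ctrl_sets = cohort_feature_sets(
        tables, drop=("G30.1", "G30.8", "G30.9"))
    res = ep.scan(case_sets, ctrl_sets, level="full_name")
    assert set(res.feature) <= {f for s in (case_sets | ctrl_sets).values() for f in s}
    strong = truth.features[truth.features.or_overall >= 2.5]
    merged = res.merge(strong, left_on="feature", right_on="code")
    # at this size the strongest planted effects come out case-enriched
    assert (merged.direction == "case_enriched").mean() > 0.6
    # family size = number of tested features
    assert np.allclose(res.p_bonferroni,
                       np.minimum(1.0, res.p * len(res)))


def test_scan_family_wise_error_controlled():
    # 200 planted-null features: the Bonferroni scan should essentially
    # never reject
    rng = np.random.default_rng(5)
    n1, n2, prev = 300, 600, 0.1
    fwer_hits = 0
    for _ in range(50):
        case_sets = {f"a{i}": set() for i in range(n1)}
        ctrl_sets = {f"b{i}": set() for i in range(n2)}
        feats = [f"F{j:03d}" for j in range(200)]
        for sets in (case_sets, ctrl_sets):
            for s in sets.values():
                s.update(f for f in feats if rng.random() < prev)
        res = ep.scan(case_sets, ctrl_sets)
        fwer_hits += int((res.p_bonferroni < 0.05).any())
    assert fwer_hits / 50 <= 0.05


def test_sex_stratified_equal_groups_and_determinism():
    rng = np.random.default_rng(1)
    sex_map = {}
    case_sets, ctrl_sets = {}, {}
    for i in range(300):
        pid = f"a{i}"
        sex_map[pid] = "F" if i < 200 else "M"
        case_sets[pid] = {"X"} if rng.random() < 0.3 else set()
    for i in range(700):
        pid = f"b{i}"
        sex_map[pid] = "F" if i < 500 else "M"
        ctrl_sets[pid] = {"X"} if rng.random() < 0.1 else set()
    out1 = ep.sex_stratified_scan(case_sets, ctrl_sets, sex_map, seed=3)
    out2 = ep.sex_stratified_scan(case_sets, ctrl_sets, sex_map, seed=3)
    for sex in ("F", "M"):
        row = out1[sex].iloc[0]
        assert row.a + row.b == row.c + row.d  # equalized groups
        assert out1[sex].equals(out2[sex])
    assert out1["F"].iloc[0].a + out1["F"].iloc[0].b == 200


def test_sex_interaction_detected_in_matching_sex_only():
    # planted OR=3 in females, OR=1 in males
    feat = ep.Feature("A10.0", "female-specific condition", 0.15,
                      0.0, np.log(3.0))
    cfg = ep.SimConfig(n_patients=4000, ad_prevalence=1 / 3, under_age_frac=0.0,
                       features=(feat,), medications=(), labs=())
    tables, _ = ep.generate_site(cfg, seed=6)
    from conftest import cohort_feature_sets
    case_sets, ctrl_sets = cohort_feature_sets(
        tables, drop=("G30.1", "G30.8", "G30.9"))
    sex_map = dict(zip(tables.patients.patient_id, tables.patients.sex))
    out = ep.sex_stratified_scan(case_sets, ctrl_sets, sex_map, seed=0)
    f_row = out["F"][out["F"].feature == "A10.0"].iloc[0]
    m_row = out["M"][out["M"].feature == "A10.0"].iloc[0]
    assert f_row.p_bonferroni < 0.05
    assert m_row.p_bonferroni > 0.05


@pytest.mark.parametrize("raw,expected", [
    ("Donepezil 10 MG Oral Tablet", "donepezil"),
    ("VITAMIN D3 1000 unit capsule", "vitamin d3"),
    ("memantine", "memantine"),
    ("dexamethasone 10 mg/ml injection solution", "dexamethasone"),
])
def test_normalize_medication(raw, expected):
    assert ep.normalize_medication(raw) == expected


def test_normalize_medication_empty_error():
    with pytest.raises(ValueError):
        ep.normalize_medication("10 MG Oral Tablet")
    with pytest.raises(ValueError):
        ep.normalize_medication("   ")
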