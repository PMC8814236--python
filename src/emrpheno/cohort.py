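"""Case/control cohort construction with propensity-score matching.

Cases are elderly patients (estimated age strictly above a cutoff, 64 by
default) carrying any of the qualifying diagnosis codes (G30.1, G30.8,
G30.9 by default).  Controls are drawn from the remaining age-eligible
population by 1:2 nearest-neighbor matching on the propensity score — the
logistic-regression probability of case status given sex, estimated age,
race and death status (plus, for the encounter sensitivity analysis, the
encounter count and record span).  Balance is reported as standardized
mean differences (SMD) before and after matching; the conventional target
is SMD < 0.1.

Matching is greedy nearest-neighbor without replacement with a seeded
random case processing order, which is the conventional reproducible
default; an optional caliper is exposed but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import DEFAULT_AD_CODES, EmrTables

log = logging.getLogger(__name__)

MATCH_COVARIATES = ("sex", "age", "race", "death_status")
CATEGORICAL = ("sex", "race", "death_status")


@dataclass
class MatchResult:
    case_ids: list[str]
    control_ids: list[str]
    matched: dict[str, list[str]]        # case -> matched control ids
    scores: pd.Series                    # propensity score per patient
    ratio: int
    complete: bool = True


@dataclass
class BalanceReport:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)  # covariate, smd_before, smd_after

    @property
    def max_after(self) -> float:
        return float(self.table["smd_after"].max()) if len(self.table) else 0.0


def covariates(patients: pd.DataFrame, reference_year: int = 2020,
               include_encounters: bool = False) -> pd.DataFrame:
    """Covariate frame indexed by patient id.

    Estimated age is reference year minus birth year; sex is the (single,
    most recent) sex assignment recorded in the patients table.
    """
    cov = pd.DataFrame({
        "sex": patients["sex"].astype(str).to_numpy(),
        "age": (reference_year - patients["birth_year"]).astype(float).to_numpy(),
        "race": patients["race"].astype(str).to_numpy(),
        "death_status": patients["death_status"].astype(str).to_numpy(),
    }, index=patients["patient_id"].astype(str))
    if include_encounters:
        cov["n_encounters"] = patients["n_encounters"].astype(float).to_numpy()
        cov["span_years"] = patients["span_years"].astype(float).to_numpy()
    return cov


def _patients_with_codes(diagnoses: pd.DataFrame, codes) -> set[str]:
    mask = diagnoses["code"].astype(str).isin(set(codes))
    return set(diagnoses.loc[mask, "patient_id"].astype(str))


def identify_cases(tables: EmrTables, case_codes=DEFAULT_AD_CODES,
                   min_age: int = 64, reference_year: int = 2020) -> set[str]:
    """Patients with any qualifying code and estimated age strictly > min_age."""
    coded = _patients_with_codes(tables.diagnoses, case_codes)
    age = reference_year - tables.patients["birth_year"]
    old = set(tables.patients.loc[age > min_age, "patient_id"].astype(str))
    return coded & old


def eligible_controls(tables: EmrTables, case_codes=DEFAULT_AD_CODES,
                      min_age: int = 64, reference_year: int = 2020) -> set[str]:
    """Age-eligible patients without any qualifying diagnosis; disjoint from cases."""
    coded = _patients_with_codes(tables.diagnoses, case_codes)
    age = reference_year - tables.patients["birth_year"]
    old = set(tables.patients.loc[age > min_age, "patient_id"].astype(str))
    pool = old - coded
    if not pool:
        raise ValueError("empty control pool: every age-eligible patient is a case")
    return pool


def _design_matrix(cov: pd.DataFrame) -> pd.DataFrame:
    cat = [c for c in cov.columns if cov[c].dtype == object or c in CATEGORICAL]
    X = pd.get_dummies(cov, columns=[c for c in cat if c in cov.columns],
                       drop_first=True, dtype=float)
    X = X.astype(float)
    return X.loc[:, X.nunique() > 1]  # constants are collinear with the intercept


def fit_propensity(cov: pd.DataFrame, case_ids: set[str]) -> pd.Series:
    """Maximum-likelihood logistic propensity scores P(case | covariates).

    Falls back to a ridge-penalized fit (logged) when the MLE fails to
    converge or separates perfectly.
    """
    X = _design_matrix(cov)
    y = cov.index.isin(set(case_ids)).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 patients per class to fit the propensity model")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = fit.params.to_numpy()
        if not (np.all(np.isfinite(params)) and fit.mle_retvals.get("converged", False)
                and np.max(np.abs(params)) < 50):
            raise RuntimeError("non-converged or separated")
        scores = np.asarray(fit.predict(Xc))
    except Exception:
        log.warning("propensity MLE failed (likely separation); using ridge-penalized fit")
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=1.0, max_iter=1000)
        lr.fit(X.to_numpy(), y)
        scores = lr.predict_proba(X.to_numpy())[:, 1]
    return pd.Series(scores, index=cov.index, name="ps")


def nn_match(scores: pd.Series, case_ids, pool_ids, ratio: int = 2,
             seed: int = 0, caliper: float | None = None) -> MatchResult:
    """Greedy nearest-neighbor matching on |propensity difference|.

    Without replacement; the case processing order is randomized by *seed*.
    When the pool is too small for a complete match the result is returned
    partial with ``complete=False`` and a logged warning.
    """
    case_ids = sorted(set(case_ids))
    pool_ids = sorted(set(pool_ids) - set(case_ids))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))

    pool_scores = scores.loc[pool_ids].to_numpy(dtype=float)
    pool_arr = np.array(pool_ids)
    available = np.ones(len(pool_ids), dtype=bool)
    matched: dict[str, list[str]] = {}
    complete = True
    for k in order:
        cid = case_ids[k]
        s = float(scores.loc[cid])
        diffs = np.abs(pool_scores - s)
        diffs[~available] = np.inf
        take = min(ratio, int(available.sum()))
        if take < ratio:
            complete = False
        if take == 0:
            matched[cid] = []
            continue
        idx = np.argpartition(diffs, take - 1)[:take]
        idx = idx[np.argsort(diffs[idx], kind="stable")]
        if caliper is not None:
            idx = idx[diffs[idx] <= caliper]
            if len(idx) < ratio:
                complete = False
        available[idx] = False
        matched[cid] = list(pool_arr[idx])
    if not complete:
        log.warning("nn_match: control pool too small for a complete %d:1 match", ratio)
    control_ids = [c for cid in case_ids for c in matched[cid]]
    return MatchResult(case_ids, control_ids, matched, scores, ratio, complete)


def smd(group_a, group_b, kind: str = "continuous") -> float:
    """Standardized mean difference between two samples.

    continuous: |m_a - m_b| / sqrt((s_a^2 + s_b^2)/2) with sample (n-1)
    variances.  categorical: the max over observed levels of the binary SMD
    on level indicators, using p(1-p) variances.  Zero pooled variance with
    unequal means returns +inf.
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("smd requires nonempty groups")
    if kind == "continuous":
        a = a.astype(float)
        b = b.astype(float)
        va = a.var(ddof=1) if a.size > 1 else 0.0
        vb = b.var(ddof=1) if b.size > 1 else 0.0
        pooled = np.sqrt((va + vb) / 2.0)
        diff = abs(a.mean() - b.mean())
        if pooled == 0:
            return 0.0 if diff == 0 else float("inf")
        return float(diff / pooled)
    if kind == "categorical":
        levels = sorted(set(a.tolist()) | set(b.tolist()))
        if len(levels) < 2:
            return 0.0
        worst = 0.0
        for lev in levels:
            pa = float(np.mean(a == lev))
            pb = float(np.mean(b == lev))
            pooled = np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
            diff = abs(pa - pb)
            if pooled == 0:
                worst = max(worst, 0.0 if diff == 0 else float("inf"))
            else:
                worst = max(worst, diff / pooled)
        return float(worst)
    raise ValueError("kind must be 'continuous' or 'categorical'")


def balance_report(cov: pd.DataFrame, case_ids, pool_ids,
                   match: MatchResult) -> BalanceReport:
    """Per-covariate SMD before (cases vs full pool) and after matching."""
    case_ids = sorted(set(case_ids))
    pool_ids = sorted(set(pool_ids))
    matched_cases = [c for c in match.case_ids if match.matched.get(c)]
    rows = []
    for col in cov.columns:
        kind = "categorical" if col in CATEGORICAL or cov[col].dtype == object \
            else "continuous"
        before = smd(cov.loc[case_ids, col], cov.loc[pool_ids, col], kind)
        after = smd(cov.loc[matched_cases, col], cov.loc[match.control_ids, col], kind)
        rows.append({"covariate": col, "smd_before": before, "smd_after": after})
    return BalanceReport(pd.DataFrame(rows))


def encounter_filter(patients: pd.DataFrame, min_encounters: int = 10,
                     min_span_years: float = 1.0) -> set[str]:
    """Sensitivity filter: >= min_encounters encounters AND span strictly
    greater than min_span_years."""
    keep = (patients["n_encounters"] >= min_encounters) & \
        (patients["span_years"] > min_span_years)
    return set(patients.loc[keep, "patient_id"].astype(str))
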