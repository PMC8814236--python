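"""Feature-by-feature 2x2 case/control association scans.

For each feature (a diagnosis at some hierarchy level, or a medication by
normalized generic name) the proportions of patients carrying it are
compared between cases and controls with a two-sided Fisher's exact test
when any 2x2 cell is below 5, otherwise a Yates-corrected chi-squared
test.  Directionality comes from the odds ratio (Haldane-Anscombe
corrected when a cell is zero), multiplicity from a Bonferroni family
equal to the number of features tested in that specific scan, and each
significant feature is classed as case-enriched (OR > 2), control-enriched
(OR < 1/2), or significant-other.

The sex-stratified variant first down-samples the larger of (cases,
controls) within each sex to equal sizes (seeded simple random sampling),
excludes unknown-sex patients, and runs independent scans per sex.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DIRECTIONS = ("case_enriched", "control_enriched", "significant_other", "not_significant")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a/b = cases with/without, c/d = controls with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


def build_table(feature: str, case_sets: dict[str, set[str]],
                control_sets: dict[str, set[str]]) -> ContingencyTable:
    """Count feature presence in each group; groups must be disjoint."""
    overlap = set(case_sets) & set(control_sets)
    if overlap:
        raise ValueError(f"case and control groups overlap ({len(overlap)} patients)")
    a = sum(1 for s in case_sets.values() if feature in s)
    c = sum(1 for s in control_sets.values() if feature in s)
    return ContingencyTable(a, len(case_sets) - a, c, len(control_sets) - c)


def test_table(table: ContingencyTable, yates: bool = True) -> tuple[str, float]:
    """Two-sided test of the 2x2 table.

    Fisher's exact (conditional hypergeometric, summing tables no more
    probable than the observed one) when any cell is below 5; otherwise the
    Pearson chi-squared test on 1 df, Yates-corrected by default.  A zero
    margin on the chi-squared branch returns p = 1 by convention.
    """
    cells = np.array([[table.a, table.b], [table.c, table.d]])
    if cells.min() < 5:
        _, p = stats.fisher_exact(cells, alternative="two-sided")
        return "fisher", float(p)
    if 0 in cells.sum(axis=0) or 0 in cells.sum(axis=1):
        log.warning("chi-squared branch with a zero margin; returning p=1")
        return "chi2", 1.0
    _, p, _, _ = stats.chi2_contingency(cells, correction=yates)
    return "chi2", float(p)


def odds_ratio(table: ContingencyTable) -> float:
    """ad/(bc); Haldane-Anscombe (+1/2 to every cell) when any cell is zero."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def bonferroni(p_values, family_size: int) -> tuple[np.ndarray, float]:
    """Adjusted p-values min(1, m*p) and the corrected threshold 0.05/m."""
    p = np.asarray(p_values, dtype=float)
    if family_size < p.size:
        raise ValueError("family_size must be at least the number of tests")
    return np.minimum(1.0, family_size * p), 0.05 / family_size


def classify(p_bonferroni: float, or_value: float, or_high: float = 2.0,
             or_low: float = 0.5, alpha: float = 0.05) -> str:
    """Direction class from the adjusted p and odds ratio."""
    if p_bonferroni >= alpha:
        return "not_significant"
    if or_value > or_high:
        return "case_enriched"
    if or_value < or_low:
        return "control_enriched"
    return "significant_other"


def scan(case_sets: dict[str, set[str]], control_sets: dict[str, set[str]],
         features=None, level: str | None = None, alpha: float = 0.05,
         or_high: float = 2.0, or_low: float = 0.5,
         yates: bool = True) -> pd.DataFrame:
    """Scan every feature observed in at least one patient.

    The Bonferroni family is the number of features tested in this scan.
    Returns one row per feature: counts, method, p, p_bonferroni, odds
    ratio and direction.
    """
    if features is None:
        features = sorted(set().union(*case_sets.values(), *control_sets.values())
                          if (case_sets or control_sets) else set())
    else:
        features = sorted(features)
    rows = []
    for f in features:
        t = build_table(f, case_sets, control_sets)
        if t.a + t.c == 0:
            continue  # observed in no patient
        method, p = test_table(t, yates=yates)
        rows.append({"feature": f, "level": level, "a": t.a, "b": t.b,
                     "c": t.c, "d": t.d, "method": method, "p": p,
                     "odds_ratio": odds_ratio(t)})
    out = pd.DataFrame(rows, columns=["feature", "level", "a", "b", "c", "d",
                                      "method", "p", "odds_ratio"])
    if out.empty:
        out["p_bonferroni"] = []
        out["direction"] = []
        return out
    family = len(out)
    out["p_bonferroni"], _ = bonferroni(out["p"].to_numpy(), family)
    out["direction"] = [
        classify(pb, orv, or_high, or_low, alpha)
        for pb, orv in zip(out["p_bonferroni"], out["odds_ratio"])
    ]
    return out


def equalize_by_sex(ids, sex_map: dict[str, str], target_sex: str,
                    n_keep: int, rng: np.random.Generator) -> list[str]:
    members = sorted(i for i in ids if sex_map.get(i) == target_sex)
    if len(members) <= n_keep:
        return members
    return sorted(rng.choice(np.array(members), size=n_keep, replace=False))


def sex_stratified_scan(case_sets: dict[str, set[str]],
                        control_sets: dict[str, set[str]],
                        sex_map: dict[str, str], seed: int = 0,
                        level: str | None = None,
                        **scan_kwargs) -> dict[str, pd.DataFrame]:
    """Independent per-sex scans on equal-sized case/control subsets.

    Within each sex the larger of (cases, controls) is down-sampled to the
    smaller by seeded simple random sampling; unknown-sex patients are
    excluded.  A sex with zero cases or zero controls is skipped with a
    warning.
    """
    out: dict[str, pd.DataFrame] = {}
    for sex in ("F", "M"):
        rng = np.random.default_rng(np.random.SeedSequence([seed, ord(sex)]))
        cases = sorted(i for i in case_sets if sex_map.get(i) == sex)
        controls = sorted(i for i in control_sets if sex_map.get(i) == sex)
        if not cases or not controls:
            log.warning("sex_stratified_scan: no %s in %s group; skipped",
                        "cases" if not cases else "controls", sex)
            continue
        n = min(len(cases), len(controls))
        cases = equalize_by_sex(case_sets, sex_map, sex, n, rng)
        controls = equalize_by_sex(control_sets, sex_map, sex, n, rng)
        out[sex] = scan({i: case_sets[i] for i in cases},
                        {i: control_sets[i] for i in controls},
                        level=level, **scan_kwargs)
    return out


# ---------------------------------------------------------------------------
# medications

_UNIT_WORDS = {"mg", "mcg", "g", "ml", "unit", "units", "%", "hr", "mg/ml",
               "meq", "iu"}
_ROUTE_WORDS = {"oral", "tablet", "tablets", "capsule", "capsules", "injection",
                "injectable", "solution", "iv", "intravenous", "topical",
                "patch", "cream", "suspension", "syringe", "chewable",
                "subcutaneous", "ophthalmic", "disintegrating"}
_DOSE_RE = re.compile(r"^\d+(\.\d+)?(mg|mcg|g|ml|%|unit|units|meq|iu)?(/\w+)?$")


def normalize_medication(order_string: str) -> str:
    """Reduce a decorated medication order string to its generic name.

    Lowercases, strips dose tokens (number + unit) and route/form tokens,
    and collapses whitespace; raises if nothing is left.
    """
    if not order_string or not order_string.strip():
        raise ValueError("empty medication order string")
    kept = []
    for tok in order_string.lower().split():
        if tok in _UNIT_WORDS or tok in _ROUTE_WORDS or _DOSE_RE.match(tok):
            continue
        kept.append(tok)
    name = " ".join(kept).strip()
    if not name:
        raise ValueError(f"order string reduced to nothing: {order_string!r}")
    return name


def medication_sets(medications: pd.DataFrame) -> dict[str, set[str]]:
    """Per-patient sets of normalized generic names from the orders table."""
    if medications.empty:
        return {}
    generics = medications["order_string"].map(normalize_medication)
    frame = pd.DataFrame({"patient_id": medications["patient_id"].astype(str),
                          "generic": generics})
    return {pid: set(grp["generic"]) for pid, grp in frame.groupby("patient_id")}
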