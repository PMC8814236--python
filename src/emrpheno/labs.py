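"""Lab-value comparison and significance of hierarchical clustering.

Per patient, each numeric lab test is summarized by its median.  Tests
missing in 95% or more of patients are dropped.  Three two-sided
Mann-Whitney contrasts are run per lab (cases vs controls overall, and
within each sex), Bonferroni-corrected over labs x contrasts.  Labs
significant in any contrast are profiled as the z-score (sample sd)
across the four group means (female/male x case/control) of per-patient
medians, then clustered (Euclidean distance, average linkage) with a
Monte-Carlo significance test of each cluster break:

At each dendrogram node, top-down, the statistic is the 2-group cluster
index — within-children sum of squares over total sum of squares about
the node mean.  The null is n_sim draws from a Gaussian with the node's
column means and a diagonal covariance whose variances are floored at a
background level (squared MAD of the centered entries / 0.6745^2, the
simplest sigclust-style estimator); each draw is re-clustered and its
root-split statistic recorded; p is the fraction of null statistics at or
below the observed one.  Family-wise error is controlled by testing a
node only when its parent rejected, at level
alpha * (leaves under node - 1) / (total leaves - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

log = logging.getLogger(__name__)

CONTRASTS = ("overall", "female", "male")
GROUPS4 = ("case_F", "case_M", "control_F", "control_M")


def patient_medians(labs: pd.DataFrame) -> pd.DataFrame:
    """Patients x tests matrix of per-patient median values (NaN = missing)."""
    if labs.empty:
        return pd.DataFrame()
    return labs.pivot_table(index="patient_id", columns="test_name",
                            values="value", aggfunc="median")


def coverage_filter(matrix: pd.DataFrame, max_missing_frac: float = 0.95
                    ) -> pd.DataFrame:
    """Drop labs missing in >= max_missing_frac of patients.

    A lab observed in exactly 5 of 100 patients (95% missing) is dropped.
    """
    if matrix.empty:
        return matrix
    missing = matrix.isna().mean(axis=0)
    keep = missing < max_missing_frac
    if not keep.any():
        log.warning("coverage_filter: every lab dropped at %.0f%% missingness",
                    100 * max_missing_frac)
    return matrix.loc[:, keep]


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided MWU: exact when both sides are small and tie-free,
    otherwise asymptotic with midrank tie correction and no continuity
    correction (identical samples then give p = 1 exactly)."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    tie_free = len(np.unique(pooled)) == pooled.size
    if tie_free and max(len(x), len(y)) <= 20:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def compare_labs(matrix: pd.DataFrame, case_ids, sex_map: dict[str, str]
                 ) -> pd.DataFrame:
    """Three contrasts per lab with Bonferroni over labs x contrasts.

    Contrasts: cases vs controls overall, female cases vs female controls,
    male cases vs male controls (unknown-sex patients enter only the
    overall contrast).  A contrast arm with fewer than 2 observed values is
    skipped with a flag.
    """
    if matrix.empty:
        return pd.DataFrame(columns=["lab", "contrast", "n_a", "n_b", "U", "p",
                                     "p_bonferroni", "skipped"])
    cases = matrix.index.isin(set(case_ids))
    sex = np.array([sex_map.get(str(i), "U") for i in matrix.index])
    arms = {
        "overall": (cases, ~cases),
        "female": (cases & (sex == "F"), ~cases & (sex == "F")),
        "male": (cases & (sex == "M"), ~cases & (sex == "M")),
    }
    family = matrix.shape[1] * len(CONTRASTS)
    rows = []
    for lab in matrix.columns:
        col = matrix[lab].to_numpy(dtype=float)
        obs = np.isfinite(col)
        for contrast, (ma, mb) in arms.items():
            va = col[ma & obs]
            vb = col[mb & obs]
            if len(va) < 2 or len(vb) < 2:
                rows.append({"lab": lab, "contrast": contrast, "n_a": len(va),
                             "n_b": len(vb), "U": np.nan, "p": np.nan,
                             "p_bonferroni": np.nan, "skipped": True})
                continue
            u, p = _mwu(va, vb)
            rows.append({"lab": lab, "contrast": contrast, "n_a": len(va),
                         "n_b": len(vb), "U": u, "p": p,
                         "p_bonferroni": min(1.0, family * p), "skipped": False})
    return pd.DataFrame(rows)


def significant_labs(compared: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Labs Bonferroni-significant in at least one contrast."""
    if compared.empty:
        return []
    sig = compared[(~compared["skipped"]) & (compared["p_bonferroni"] < alpha)]
    return sorted(sig["lab"].unique())


def group_z(matrix: pd.DataFrame, labs: list[str], case_ids,
            sex_map: dict[str, str]) -> pd.DataFrame:
    """Z-scored group means: labs x (case_F, case_M, control_F, control_M).

    The group mean is the arithmetic mean over patients of per-patient
    medians; each row is z-scored across its groups with sample (n-1) sd.
    A zero-sd row becomes all zeros (flagged in the log).
    """
    cases = matrix.index.isin(set(case_ids))
    sex = np.array([sex_map.get(str(i), "U") for i in matrix.index])
    masks = {
        "case_F": cases & (sex == "F"), "case_M": cases & (sex == "M"),
        "control_F": ~cases & (sex == "F"), "control_M": ~cases & (sex == "M"),
    }
    rows = {}
    for lab in labs:
        col = matrix[lab].to_numpy(dtype=float)
        means = []
        for g in GROUPS4:
            vals = col[masks[g] & np.isfinite(col)]
            means.append(vals.mean() if len(vals) else np.nan)
        means = np.asarray(means)
        if np.isnan(means).any():
            log.warning("group_z: lab %s lacks data in some group; skipped", lab)
            continue
        sd = means.std(ddof=1)
        if sd == 0:
            log.warning("group_z: lab %s has identical group means; z = 0", lab)
            rows[lab] = np.zeros(len(GROUPS4))
        else:
            rows[lab] = (means - means.mean()) / sd
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(GROUPS4))


# ---------------------------------------------------------------------------
# significance of hierarchical cluster breaks

@dataclass
class ClusterBreak:
    node_id: int
    members_left: tuple[str, ...]
    members_right: tuple[str, ...]
    statistic: float
    p: float | None
    alpha_level: float | None
    significant: bool
    tested: bool


def _cluster_index(X: np.ndarray, left: np.ndarray, right: np.ndarray) -> float:
    """Within-children SS over total SS about the overall mean; in (0, 1],
    equal to 1 when the two children coincide in mean."""
    total = ((X - X.mean(axis=0)) ** 2).sum()
    if total <= 1e-12 * max(1.0, float((X * X).sum())):
        return 1.0
    within = sum(((X[m] - X[m].mean(axis=0)) ** 2).sum() for m in (left, right))
    return float(within / total)


def _root_split_stat(X: np.ndarray) -> float:
    Z = linkage(X, method="average", metric="euclidean")
    lab = fcluster(Z, t=2, criterion="maxclust")
    return _cluster_index(X, lab == 1, lab != 1)


def _null_stats(X: np.ndarray, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """Root-split statistics of Gaussian null draws matched to X.

    Diagonal covariance with per-column variances floored at the squared
    MAD of all centered entries divided by 0.6745^2.
    """
    k, p = X.shape
    mu = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    centered = (X - mu).ravel()
    mad = np.median(np.abs(centered - np.median(centered)))
    floor = (mad / 0.6745) ** 2
    var = np.maximum(var, floor)
    sd = np.sqrt(var)
    out = np.empty(n_sim)
    for s in range(n_sim):
        draw = rng.normal(mu, sd, size=(k, p))
        out[s] = _root_split_stat(draw)
    return out


def cluster_breaks(profile: pd.DataFrame, n_sim: int = 1000,
                   alpha: float = 0.05, seed: int = 0
                   ) -> tuple[np.ndarray, list[ClusterBreak]]:
    """Average-linkage clustering of labs with Monte-Carlo break significance.

    Returns the scipy linkage matrix and one :class:`ClusterBreak` per
    internal node.  Nodes with fewer than 3 members are reported untested;
    a node is tested only if its parent rejected (the root's parent counts
    as rejected), at FWER level alpha * (leaves - 1) / (total leaves - 1).
    """
    if len(profile) < 3:
        raise ValueError("need at least 3 labs to cluster")
    X = profile.to_numpy(dtype=float)
    names = list(profile.index)
    n_total = len(names)
    Z = linkage(X, method="average", metric="euclidean")
    root, nodes = to_tree(Z, rd=True)
    rng = np.random.default_rng(seed)

    breaks: list[ClusterBreak] = []

    def visit(node, parent_rejected: bool):
        if node.is_leaf():
            return
        left = np.array(node.left.pre_order())
        right = np.array(node.right.pre_order())
        members = np.concatenate([left, right])
        k = len(members)
        ml = tuple(names[i] for i in left)
        mr = tuple(names[i] for i in right)
        if k < 3 or not parent_rejected:
            breaks.append(ClusterBreak(node.id, ml, mr, np.nan, None, None,
                                       False, False))
            visit(node.left, False)
            visit(node.right, False)
            return
        sub = X[members]
        lmask = np.isin(members, left)
        observed = _cluster_index(sub, lmask, ~lmask)
        null = _null_stats(sub, n_sim, rng)
        # add-one Monte-Carlo p so P(p <= a) <= a holds at finite n_sim
        p = float((1 + np.sum(null <= observed)) / (n_sim + 1))
        level = alpha * (k - 1) / (n_total - 1)
        rejected = p <= level
        breaks.append(ClusterBreak(node.id, ml, mr, observed, p, level,
                                   rejected, True))
        visit(node.left, rejected)
        visit(node.right, rejected)

    visit(root, True)
    return Z, breaks


def combine_sites(profile_a: pd.DataFrame, profile_b: pd.DataFrame,
                  suffixes: tuple[str, str] = ("_siteA", "_siteB")
                  ) -> pd.DataFrame:
    """Join two site profiles on shared labs, concatenating group columns.

    Rows are the labs of *profile_a* (the discovery-site significant set)
    also present at the validation site; labs absent at the validation
    site are excluded with a log line.
    """
    shared = [lab for lab in profile_a.index if lab in profile_b.index]
    if not shared:
        raise ValueError("no shared labs between the two site profiles")
    dropped = set(profile_a.index) - set(shared)
    if dropped:
        log.info("combine_sites: %d labs absent at validation site excluded",
                 len(dropped))
    a = profile_a.loc[shared].add_suffix(suffixes[0])
    b = profile_b.loc[shared].add_suffix(suffixes[1])
    return pd.concat([a, b], axis=1)
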