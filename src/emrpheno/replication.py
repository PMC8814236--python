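"""Two-site replication of enrichment results.

Discovery-site significant features are mapped through the inter-site
code map; the validation scan is restricted to the mapped features with a
Bonferroni threshold of 0.05 divided by the number of mapped
discovery-significant features (exact integer arithmetic).  Effect-size
agreement is summarized by the Spearman rank correlation of log odds
ratios (Haldane-corrected via the scan itself) across the mapped pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import build_table, odds_ratio, test_table
from .hierarchy import map_between_sites


@dataclass
class ReplicationReport:
    n_significant_discovery: int
    n_mapped: int
    n_replicated: int
    threshold: float
    spearman_rho: float
    spearman_p: float
    pairs: pd.DataFrame  # feature, target, OR_discovery, OR_validation, p_validation, replicated

    @property
    def replicated_fraction(self) -> float:
        return self.n_replicated / self.n_mapped if self.n_mapped else float("nan")


def replicate(discovery: pd.DataFrame,
              validation_case_sets: dict[str, set[str]],
              validation_control_sets: dict[str, set[str]],
              code_map: dict[str, str], alpha: float = 0.05,
              use_log_or: bool = True) -> ReplicationReport:
    """Apply the replication rule to one discovery scan.

    Parameters
    ----------
    discovery
        Output of :func:`emrpheno.enrichment.scan` at the discovery site.
    validation_case_sets, validation_control_sets
        Rolled-up feature sets at the validation site (same level,
        validation-site code dialect).
    code_map
        Discovery code -> validation code; features absent from the map are
        excluded from both numerator and denominator and reported in the
        mapped count.
    use_log_or
        Correlate log odds ratios (symmetric in direction) rather than raw
        ORs; toggleable.
    """
    sig = discovery[discovery["p_bonferroni"] < alpha]
    n_sig = len(sig)
    if n_sig == 0:
        raise ValueError("no significant discovery features to replicate")
    mapped, _unmapped = map_between_sites(sig["feature"], code_map)
    n_mapped = len(mapped)
    if n_mapped == 0:
        raise ValueError("zero mapped features: cannot replicate")
    threshold = alpha / n_mapped

    disc_or = dict(zip(sig["feature"], sig["odds_ratio"]))
    rows = []
    for src, tgt in mapped.items():
        t = build_table(tgt, validation_case_sets, validation_control_sets)
        _, p = test_table(t)
        orv = odds_ratio(t)
        rows.append({"feature": src, "target": tgt,
                     "or_discovery": disc_or[src], "or_validation": orv,
                     "p_validation": p, "replicated": p < threshold})
    pairs = pd.DataFrame(rows)
    n_rep = int(pairs["replicated"].sum())
    x = pairs["or_discovery"].to_numpy(dtype=float)
    y = pairs["or_validation"].to_numpy(dtype=float)
    if use_log_or:
        x, y = np.log(x), np.log(y)
    if len(pairs) >= 3 and (np.ptp(x) > 0 or np.ptp(y) > 0):
        rho, sp = stats.spearmanr(x, y)
    else:
        rho, sp = (1.0, 0.0) if np.allclose(x, y) else (float("nan"), float("nan"))
    return ReplicationReport(n_sig, n_mapped, n_rep, threshold,
                             float(rho), float(sp), pairs)
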