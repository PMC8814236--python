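# Methods

This note records the models, conventions and design choices behind
`emrpheno`, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic EMR generator

The generator emulates the statistical structure that the downstream
analyses assume, with every effect planted on a scale the analyses can
recover exactly.

**Demographics.** Ages are truncated-normal above 64 (mean 86.5, sd 6.4 —
the elderly hospital population the case definition targets), with a
configurable sub-65 ineligible fraction (default 5%) to exercise the age
filter.  Sex (F/M/U ≈ 63/37/0.3%), race (seven categories dominated by
White/Caucasian at 64%), and death status (24% deceased) follow the
demographic mix of a large metropolitan EMR.  Encounter counts are
negative-binomial (mean 30, dispersion 3) and record spans uniform on
0.5–15 years, giving the encounter-sensitivity filter something to cut.

**Case status.** Among age-eligible patients, AD status is Bernoulli on
the logit scale: logit p = logit(prevalence) + β_age·(age − 85) +
β_female·1[F].  With both coefficients zero (the default) assignment is
unconfounded; `confounded_config()` sets β_age = 0.06/yr and β_female =
0.5, which drives pre-match SMDs for age and sex above 0.2.  Every case
carries one of the qualifying codes (G30.1/G30.8/G30.9) so cohort
identification runs on codes alone, as it would on real data.

**Diagnoses.** Feature j for patient i is Bernoulli with
logit p = logit(prev_j) + β_j·A_i + γ_j·A_i·1[female] + module boosts.
Because presence is logistic in case status given sex, the marginal 2×2
odds ratio of a module-free feature equals exp(β_j) *exactly* — the
planted truth is the estimand of the enrichment scan, not an
approximation to it.  Unknown-sex patients receive no interaction
effect.  Present diagnoses are emitted as 1–3 dated duplicate records
(dates uniform within the patient's record span) so earliest-entry
deduplication is exercised; latent comorbidity modules add a shared
logit boost to member codes when active (activation probability differs
between cases and controls), planting excess co-occurrence without a
copula.

**Medications and labs.** Medication presence follows the same logistic
scheme; orders are emitted as decorated strings (dose/route noise) that
the normalizer must strip.  Labs are Gaussian per (case-status × sex)
group with per-lab missingness; unknown-sex patients draw from the
average of the two sex means.

**Sites and dialects.** A site pair shares one planted truth; site B's
diagnoses are renamed per level-3 family (so its hierarchy stays
coherent) and a configurable fraction of codes is left out of the
inter-site map.  Case codes are never renamed: both sites define the
phenotype identically.

**Randomness.** One `SeedSequence` child per table (demographics,
diagnoses, medications, labs, dialect), so extending one catalog never
perturbs the other tables, and identical (config, seed) reproduce
byte-identical TSVs across platforms.

**What the generator does not emulate** — and hence what passing tests do
not establish about real EMR data: realistic clinical vocabularies,
free-text noise, visit-level temporal structure (dates are uniform within
the span; the de-identification date-shifting of real EMRs is irrelevant
to these non-temporal analyses), code co-occurrence driven by billing
practice rather than biology, informative missingness in labs, and
cross-covariate correlations beyond those induced by the planted
logistic model.

## Cohorts and matching

The propensity model is a maximum-likelihood logistic regression on
one-hot covariates (reference level dropped; constant columns removed as
collinear with the intercept).  Separation or non-convergence triggers a
logged ridge-penalized fallback (scikit-learn, C = 1); with seven race
levels including very rare ones, quasi-separation is routine at a few
thousand patients, and the ridge scores preserve the ordering matching
needs.  Matching is greedy nearest-neighbor on |score difference|,
without replacement, case order shuffled by seed; no caliper by default
(one is exposed).  These are the conventional reproducible defaults for
"nearest neighbors" matching when the original order and replacement
policy are not specified.

SMDs use sample (n−1) variances for continuous covariates and p(1−p)
variances for level indicators, reporting the max over levels for
categoricals; zero pooled variance with unequal means returns +∞ rather
than hiding the degeneracy.

The balance experiment (`confounded_config`, 16,000 patients) is sized
so that the between-sex balance check — a maximum over ~13 category
indicators between the matched female and male subgroups — measures what
matching does rather than order-statistic sampling noise; at a few
thousand patients that maximum has noise sd ≈ 0.04–0.06 per indicator
and its worst-over-seeds value can cross 0.2 with matching working
perfectly.

## Enrichment

The Fisher/χ² switch is "any 2×2 cell < 5"; the Fisher p is the
two-sided conditional hypergeometric (sum of tables no more probable
than observed), the χ² branch uses the Yates continuity correction
(toggleable) and returns p = 1 by convention on a zero margin.  Odds
ratios use the Haldane–Anscombe +½ correction only when a cell is zero,
which keeps OR(swapped groups) = 1/OR exactly.  The Bonferroni family is
the number of features tested in the specific scan (per level, per sex
stratum, per domain) — the printed thresholds of large real cohorts
(e.g. 0.05/47,439 ≈ 1e−6 for a full-code family) follow from the same
rule.  Sex-stratified scans down-sample the larger group to the smaller
within each sex by seeded simple random sampling and exclude unknown-sex
patients.

Medication normalization lowercases, strips numeric dose tokens,
unit words and route/form words, and collapses whitespace; an order
string that strips to nothing is an error, not an empty feature.

## Networks

Thresholds are strict (> , not ≥), so a pair shared by exactly the
threshold fraction is excluded.  Metric conventions follow the Cytoscape
Network Analyzer definitions: closeness is (reachable count)/(sum of
distances) within the node's component (0 for isolated nodes);
eccentricity is the component-restricted max distance; stress counts
shortest paths between unordered pairs of other nodes passing through
the node; the topological coefficient of n averages (shared-neighbor
count + adjacency bonus)/degree(n) over nodes sharing ≥ 1 neighbor with
n, 0 when degree < 2.  All six are validated against a brute-force
path-enumeration oracle on random graphs.

Metric distributions are compared with the asymptotic tie-corrected
Mann–Whitney U *without* continuity correction, so identical networks
give p = 1 exactly; pooled-constant samples return p = 1 by convention.
Cross-site comparison z-scores each metric pooled over all listed
networks (constant metrics z-score to 0) and correlates sites by
Spearman rank on per-network mean z; node-level aggregation is exposed
as an alternative since either pooling is defensible.

## Labs and significance of clustering

Per-patient medians use the standard even-count mean-of-middles; the
coverage filter drops labs missing in ≥ 95% of patients (exactly 95%
missing is dropped).  The three contrasts are Bonferroni-corrected over
labs × contrasts; arms with < 2 observations are skipped with a flag.
Mann–Whitney uses the exact distribution when both arms are ≤ 20 and
tie-free, otherwise the midrank/tie-corrected normal approximation
without continuity correction (identical samples ⇒ p = 1).

Group z-profiles are the arithmetic mean over patients of per-patient
medians, z-scored across the row's groups with sample sd; a zero-sd row
becomes zeros and is flagged.

Cluster-break significance re-implements the sigclust-style test as a
hierarchical Monte-Carlo procedure: average linkage on Euclidean
distances; at each internal node (≥ 3 members, top-down), the statistic
is the 2-group cluster index (within-children SS / total SS about the
node mean, in (0, 1], equal to 1 when the children coincide in mean);
the null is a diagonal Gaussian with the node's column means and
variances floored at (MAD of centered entries / 0.6745)² — the simplest
published background-variance estimator; each of n_sim draws is
re-clustered and its root-split statistic recorded.  The Monte-Carlo p
uses the add-one convention (1 + #{null ≤ obs})/(n_sim + 1), which makes
P(p ≤ α) ≤ α at finite n_sim.  A node is tested only if its parent
rejected, at level α·(leaves − 1)/(total leaves − 1), which controls the
family-wise error of the whole tree at α.

## Replication

The validation threshold is exactly 0.05 divided by the number of mapped
discovery-significant features (integer count, no rounding); unmappable
features are excluded from both numerator and denominator and reported.
Effect correlation uses log odds ratios (symmetric under direction
reversal) by default, toggleable to raw ORs.  Map collisions merge
presence by logical OR, matching the presence/absence semantics of the
2×2 scan.

## Pipeline, sizes, and limitations

`run_all` executes cohort → rollup → {embedding, enrichment, networks,
labs} → replication from one flat config, logging every dropped record
and writing a manifest of row counts; identical configs reproduce
identical manifests.  The 2-D embedding defaults to a deterministic
projection onto the top-2 principal directions (sign-fixed SVD), so
pipelines and tests are seed-independent; UMAP is used only when
explicitly requested and installed.

Experiment sizes used by the test suite and acceptance script (chosen as
the smallest that separate signal from the relevant noise): balance runs
at 16,000 patients × 10 seeds; parameter recovery at 6,000 patients ×
100 features × 5 seeds; module detection at 4,000 patients × 20 seeds;
replication at 5,000 patients/site; cluster-break calibration at 200
replicates × 500 null draws.

Known limitations: no covariate-adjusted (regression) association — the
scans assume independence given group, as stated; Bonferroni only (no
FDR); no ICD-9 conversion or real-vocabulary normalization; greedy
matching is order-dependent by design (seeded); the cluster-break null
assumes a diagonal Gaussian, so correlated-group nulls are tested only
through the variance floor.
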