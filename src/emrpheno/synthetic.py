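"""Seeded synthetic EMR generator with planted, recoverable effects.

Emulates the statistical structure of an elderly case/control EMR study of
Alzheimer's disease (AD): demographics of an over-64 hospital population,
per-diagnosis baseline prevalences with planted case/control odds ratios and
sex-interaction effects, latent comorbidity modules that raise diagnosis
co-occurrence in cases, medication order strings decorated with dose/route
noise, per-lab Gaussian group shifts with missingness, and a second "site"
that shares all planted effects but speaks a different code dialect.

Diagnosis presence for patient *i* and feature *j* is Bernoulli with

    logit p_ij = logit(prev_j) + beta_j * A_i + gamma_j * A_i * 1[female_i] + module boost

where ``A_i`` is AD status.  Because presence is a logistic function of AD
status alone (given sex), the marginal 2x2 odds ratio of a feature with no
module membership equals ``exp(beta_j)`` exactly — the generator's planted
truth is recoverable by the downstream enrichment scan.

All randomness flows from one master seed through per-table
``numpy.random.SeedSequence`` children, so adding a catalog entry perturbs
only its own table and identical (config, seed) reproduce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

DEFAULT_AD_CODES = ("G30.1", "G30.8", "G30.9")
SEX_LEVELS = ("F", "M", "U")
DEATH_LEVELS = ("alive", "deceased", "unknown")


class SimConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise SimConfigError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class Feature:
    """One diagnosis code in the catalog with its planted effect sizes."""

    code: str
    name: str
    baseline_prevalence: float
    log_or_case: float = 0.0
    log_or_case_female: float = 0.0  # interaction on top of log_or_case


@dataclass(frozen=True)
class ComorbidityModule:
    """Latent module: when active, member codes get an additive logit boost."""

    name: str
    members: tuple[str, ...]
    p_active_case: float
    p_active_control: float
    logit_boost: float


@dataclass(frozen=True)
class Medication:
    generic: str
    order_strings: tuple[str, ...]
    baseline_prevalence: float
    log_or_case: float = 0.0
    log_or_case_female: float = 0.0


@dataclass(frozen=True)
class LabTest:
    """Gaussian lab with per-(group x sex) means; unknown sex gets the average."""

    name: str
    mean_case_female: float
    mean_case_male: float
    mean_control_female: float
    mean_control_male: float
    sd: float
    draws_per_patient: int = 3
    missing_prob: float = 0.3


@dataclass(frozen=True)
class SiteDialect:
    """Code dialect of a second site: a fraction of level-3 families renamed,
    a fraction of catalog codes left out of the inter-site map."""

    renamed_frac: float = 0.3
    unmappable_frac: float = 0.05


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 4000
    ad_prevalence: float = 0.25
    # elderly age model: truncated normal above age_min, plus an ineligible tail
    age_mean: float = 86.5
    age_sd: float = 6.4
    age_min: int = 64
    under_age_frac: float = 0.05
    sex_probs: tuple[float, float, float] = (0.631, 0.366, 0.003)  # F, M, U
    race_probs: dict[str, float] = field(
        default_factory=lambda: {
            "White/Caucasian": 0.640,
            "Asian": 0.103,
            "Other": 0.087,
            "Unknown": 0.076,
            "Black/African American": 0.069,
            "Native Hawaiian/Pacific Islander": 0.053,
            "American Indian/Alaska Native": 0.001,
        }
    )
    death_prob: float = 0.237
    encounters_mean: float = 30.0
    encounters_dispersion: float = 3.0  # negative-binomial size parameter
    span_years_range: tuple[float, float] = (0.5, 15.0)
    reference_year: int = 2020
    # optional confounding of case assignment (logit scale)
    ad_age_logit_per_year: float = 0.0  # per year of age above 85
    ad_female_logit: float = 0.0
    case_codes: tuple[str, ...] = DEFAULT_AD_CODES
    features: tuple[Feature, ...] = ()
    modules: tuple[ComorbidityModule, ...] = ()
    medications: tuple[Medication, ...] = ()
    labs: tuple[LabTest, ...] = ()
    dialect: SiteDialect | None = None

    def validate(self) -> None:
        _check(self.n_patients >= 10, "n_patients", "must be >= 10")
        _check(0 < self.ad_prevalence < 1, "ad_prevalence", "must be in (0,1)")
        _check(self.age_sd > 0, "age_sd", "must be > 0")
        _check(0 <= self.under_age_frac < 1, "under_age_frac", "must be in [0,1)")
        _check(abs(sum(self.sex_probs) - 1) < 1e-9, "sex_probs", "must sum to 1")
        _check(all(p >= 0 for p in self.sex_probs), "sex_probs", "must be non-negative")
        total_race = sum(self.race_probs.values())
        _check(total_race > 0, "race_probs", "must have positive mass")
        _check(0 <= self.death_prob <= 1, "death_prob", "must be in [0,1]")
        _check(self.encounters_mean > 0, "encounters_mean", "must be > 0")
        _check(self.encounters_dispersion > 0, "encounters_dispersion", "must be > 0")
        lo, hi = self.span_years_range
        _check(0 < lo <= hi, "span_years_range", "must satisfy 0 < lo <= hi")
        codes = [f.code for f in self.features]
        _check(len(codes) == len(set(codes)), "features", "codes must be unique")
        for f in self.features:
            _check(0 < f.baseline_prevalence < 1, "features",
                   f"{f.code}: baseline_prevalence must be in (0,1)")
        member_codes = {c for m in self.modules for c in m.members}
        _check(member_codes <= set(codes), "modules",
               "member codes must exist in the feature catalog")
        for m in self.modules:
            _check(0 <= m.p_active_case <= 1 and 0 <= m.p_active_control <= 1,
                   "modules", f"{m.name}: activation probabilities must be in [0,1]")
        for med in self.medications:
            _check(0 < med.baseline_prevalence < 1, "medications",
                   f"{med.generic}: baseline_prevalence must be in (0,1)")
            _check(len(med.order_strings) > 0, "medications",
                   f"{med.generic}: needs at least one order string")
        for lab in self.labs:
            _check(lab.sd > 0, "labs", f"{lab.name}: sd must be > 0")
            _check(0 <= lab.missing_prob <= 1, "labs",
                   f"{lab.name}: missing_prob must be in [0,1]")
            _check(lab.draws_per_patient >= 1, "labs",
                   f"{lab.name}: draws_per_patient must be >= 1")
        if self.dialect is not None:
            _check(0 <= self.dialect.renamed_frac <= 1, "dialect.renamed_frac",
                   "must be in [0,1]")
            _check(0 <= self.dialect.unmappable_frac <= 1, "dialect.unmappable_frac",
                   "must be in [0,1]")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth: what the downstream analysis should recover."""

    features: pd.DataFrame     # code, baseline_prevalence, log_or, or, or_female, or_male, in_module
    medications: pd.DataFrame  # generic, baseline_prevalence, log_or, or, or_female, or_male
    labs: pd.DataFrame         # name, four group means, sd
    modules: pd.DataFrame      # name, members, p_active_case, p_active_control, logit_boost

    def to_frame(self) -> pd.DataFrame:
        """Single tidy truth table for serialization (truth.tsv)."""
        rows = []
        for r in self.features.itertuples(index=False):
            rows.append(("diagnosis", r.code, r.log_or, r.or_overall, r.or_female, r.or_male))
        for r in self.medications.itertuples(index=False):
            rows.append(("medication", r.generic, r.log_or, r.or_overall, r.or_female, r.or_male))
        return pd.DataFrame(rows, columns=["kind", "item", "log_or", "or_overall",
                                           "or_female", "or_male"])


@dataclass
class EmrTables:
    """The four per-site event tables plus the hierarchy emitted alongside."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    medications: pd.DataFrame
    labs: pd.DataFrame
    hierarchy: pd.DataFrame

    def equals(self, other: "EmrTables") -> bool:
        return all(
            getattr(self, t).reset_index(drop=True).equals(
                getattr(other, t).reset_index(drop=True))
            for t in ("patients", "diagnoses", "medications", "labs", "hierarchy")
        )


# ---------------------------------------------------------------------------
# catalog helpers

def default_config(**overrides) -> SimConfig:
    """The study-conditions default: a small clinically flavored catalog with
    effect sizes in the range the enrichment scan reports for real cohorts."""
    features = (
        Feature("I10.0", "Essential (primary) hypertension", 0.30, np.log(2.5)),
        Feature("E78.5", "Hyperlipidemia, unspecified", 0.25, np.log(2.0)),
        Feature("N39.0", "Urinary tract infection, site not specified", 0.15, np.log(2.8), np.log(1.5)),
        Feature("E11.9", "Type 2 diabetes mellitus without complications", 0.18, np.log(1.8)),
        Feature("M81.0", "Age-related osteoporosis without current pathological fracture", 0.10, np.log(2.2), np.log(1.8)),
        Feature("F01.5", "Vascular dementia", 0.03, np.log(6.0)),
        Feature("F32.9", "Major depressive disorder, single episode, unspecified", 0.12, np.log(2.0), np.log(1.4)),
        Feature("R55.0", "Syncope and collapse", 0.10, np.log(2.3)),
        Feature("E03.9", "Hypothyroidism, unspecified", 0.12, np.log(1.7)),
        Feature("D64.9", "Anemia, unspecified", 0.14, np.log(1.9)),
        Feature("G47.3", "Sleep apnoea", 0.08, np.log(1.6), -np.log(1.6)),
        Feature("I48.9", "Atrial fibrillation, unspecified", 0.12, np.log(1.5), np.log(1.3)),
        Feature("C71.9", "Malignant neoplasm of brain, unspecified", 0.02, -np.log(3.0)),
        Feature("C22.9", "Malignant neoplasm of liver, unspecified", 0.02, -np.log(2.5)),
        Feature("J06.9", "Acute upper respiratory infection, unspecified", 0.20, np.log(1.4)),
        Feature("H91.9", "Unspecified hearing loss", 0.10, np.log(1.6), -np.log(1.3)),
        Feature("K21.9", "Gastro-esophageal reflux disease without esophagitis", 0.22, 0.0),
        Feature("M17.9", "Osteoarthritis of knee, unspecified", 0.15, 0.0),
        Feature("J45.9", "Asthma, unspecified", 0.08, 0.0),
        Feature("L30.9", "Dermatitis, unspecified", 0.10, 0.0),
    )
    modules = (
        ComorbidityModule("vascular", ("I10.0", "E78.5", "E11.9", "I48.9"), 0.45, 0.10, 1.5),
    )
    medications = (
        Medication("donepezil", ("Donepezil 10 MG Oral Tablet", "donepezil 5 mg oral tablet"),
                   0.02, np.log(12.0)),
        Medication("memantine", ("Memantine 10 MG Oral Tablet",), 0.015, np.log(10.0)),
        Medication("sertraline", ("Sertraline 50 MG Oral Tablet",), 0.08, np.log(2.0), np.log(1.5)),
        Medication("quetiapine", ("QUETIAPINE 25 mg oral tablet",), 0.04, np.log(3.0)),
        Medication("vitamin d3", ("VITAMIN D3 1000 unit capsule",), 0.15, np.log(1.8)),
        Medication("melatonin", ("Melatonin 3 MG Oral Tablet",), 0.06, np.log(2.2), -np.log(1.5)),
        Medication("dexamethasone", ("Dexamethasone 4 MG Oral Tablet", "dexamethasone 10 mg/ml injection solution"),
                   0.08, -np.log(2.5)),
        Medication("furosemide", ("Furosemide 20 MG Oral Tablet",), 0.12, -np.log(1.5)),
        Medication("lisinopril", ("Lisinopril 10 MG Oral Tablet",), 0.15, 0.0),
        Medication("omeprazole", ("Omeprazole 20 MG Oral Capsule",), 0.15, 0.0),
    )
    labs = (
        LabTest("calcium", 9.7, 9.4, 9.3, 9.3, 0.5),
        LabTest("glucose", 98.0, 100.0, 108.0, 112.0, 18.0),
        LabTest("hematocrit", 39.5, 41.5, 38.0, 40.0, 3.5),
        LabTest("albumin", 4.1, 4.0, 3.8, 3.8, 0.4),
        LabTest("alt", 18.0, 22.0, 24.0, 30.0, 8.0),
        LabTest("ast", 21.0, 24.0, 26.0, 31.0, 8.0),
        LabTest("aptt", 28.0, 31.0, 31.0, 33.0, 4.0),
        LabTest("cholesterol", 185.0, 175.0, 172.0, 165.0, 30.0),
        LabTest("sodium", 139.0, 139.0, 138.5, 138.5, 2.5),
        LabTest("creatinine", 1.0, 1.2, 1.0, 1.2, 0.3),
    )
    cfg = SimConfig(features=features, modules=modules,
                    medications=medications, labs=labs)
    return replace(cfg, **overrides) if overrides else cfg


def confounded_config(n_patients: int = 16000) -> SimConfig:
    """Study conditions for the covariate-balance experiment.

    Case probability depends on age (+0.06 logit per year above 85) and on
    female sex (+0.5 logit), inducing pre-match imbalance in age and sex
    well above SMD 0.2, with a control pool comfortably larger than twice
    the case count so 1:2 matching is complete.  The site size defaults to
    16000: between-sex balance is read off a max over many category
    indicators, an extreme order statistic whose sampling noise at small
    cohorts would swamp what matching actually does.
    """
    return default_config(n_patients=n_patients, ad_prevalence=0.08,
                          ad_age_logit_per_year=0.06, ad_female_logit=0.5)


def planted_or_catalog(n_features: int, seed: int, baseline_range=(0.02, 0.30),
                       log_or_range=(-1.1, 1.1)) -> tuple[Feature, ...]:
    """A catalog of *n_features* codes with planted log-ORs spread uniformly —
    the input for parameter-recovery experiments."""
    rng = np.random.default_rng(seed)
    letters = [c for c in "ABDEFHIJKLMNQRSTVWXY"]  # skip G (reserved for case codes)
    feats = []
    for i in range(n_features):
        letter = letters[i % len(letters)]
        num = 10 + (i // len(letters))
        code = f"{letter}{num:02d}.{i % 10}"
        prev = rng.uniform(*baseline_range)
        lor = rng.uniform(*log_or_range)
        feats.append(Feature(code, f"Synthetic condition {code}", float(prev), float(lor)))
    return tuple(feats)


def shared_effect_catalog(n_features: int = 40, seed: int = 7) -> tuple[Feature, ...]:
    """Catalog for two-site replication experiments: alternating strong
    planted effects (OR ~ 1.8-6) and exact nulls, prevalences 5-25%.

    The effect spread is wide relative to log-OR estimation noise at a few
    thousand patients per site, so rank correlation across sites reflects
    the shared truth rather than sampling jitter."""
    rng = np.random.default_rng(seed)
    letters = "ABDEFHIJKLMNQRSTVW"
    feats = []
    for i in range(n_features):
        code = f"{letters[i % len(letters)]}{20 + i // len(letters):02d}.{i % 10}"
        prev = float(rng.uniform(0.05, 0.25))
        lor = float(rng.uniform(0.6, 1.8)) if i % 2 == 0 else 0.0
        feats.append(Feature(code, f"Condition {code}", prev, lor))
    return tuple(feats)


def null_catalog(n_features: int, prevalence: float = 0.10) -> tuple[Feature, ...]:
    """A catalog of planted-null features (log-OR exactly 0)."""
    letters = [c for c in "ABDEFHIJKLMNQRSTVWXY"]
    return tuple(
        Feature(f"{letters[i % len(letters)]}{10 + i // len(letters):02d}.{i % 10}",
                f"Null condition {i}", prevalence)
        for i in range(n_features)
    )


# ---------------------------------------------------------------------------
# generation

def _build_hierarchy_frame(config: SimConfig) -> pd.DataFrame:
    """Hierarchy table covering every catalog code plus the case codes."""
    full_codes: dict[str, str] = {f.code: f.name for f in config.features}
    for c in config.case_codes:
        full_codes.setdefault(c, "Alzheimer's disease")
    rows = []
    level3_seen: dict[str, None] = {}
    for code in sorted(full_codes):
        level3 = code[:3]
        rows.append((code, "full_name", full_codes[code], level3))
        level3_seen.setdefault(level3, None)
    level2_seen: dict[str, None] = {}
    for level3 in level3_seen:
        letter, num = level3[0], int(level3[1:3])
        lo = (num // 10) * 10
        level2 = f"{letter}{lo:02d}-{letter}{lo + 9:02d}"
        name = "Alzheimer's disease and related categories" if level3 == "G30" \
            else f"Synthetic category group {level2}"
        rows.append((level3, "level3_category",
                     "Alzheimer's disease" if level3 == "G30" else f"Synthetic category {level3}",
                     level2))
        if level2 not in level2_seen:
            level2_seen[level2] = None
            rows.append((level2, "level2_category", name, f"{letter}00-{letter}99"))
    for level2 in list(level2_seen):
        letter = level2[0]
        block = f"{letter}00-{letter}99"
        if not any(r[0] == block for r in rows):
            rows.append((block, "chapter_block", f"Synthetic chapter {block}", ""))
    frame = pd.DataFrame(rows, columns=["code", "level", "name", "parent"])
    return frame.drop_duplicates(subset=["code"]).sort_values(
        ["level", "code"]).reset_index(drop=True)


def _dates_within_span(rng: np.random.Generator, start_days: np.ndarray,
                       end_days: np.ndarray) -> np.ndarray:
    """Uniform ISO dates between per-row start/end day offsets from epoch."""
    offs = rng.integers(start_days, np.maximum(end_days, start_days + 1))
    return (np.datetime64("1970-01-01") + offs.astype("timedelta64[D]")).astype(str)


def _bernoulli_events(rng: np.random.Generator, present_idx: np.ndarray,
                      code: str, start_days: np.ndarray, end_days: np.ndarray,
                      ids: np.ndarray, max_dups: int = 3):
    """Emit 1..max_dups dated duplicate records per present patient."""
    if present_idx.size == 0:
        return [], [], []
    ndup = rng.integers(1, max_dups + 1, size=present_idx.size)
    rep = np.repeat(present_idx, ndup)
    dates = _dates_within_span(rng, start_days[rep], end_days[rep])
    return ids[rep], [code] * rep.size, dates


def generate_site(config: SimConfig, seed: int, site: str = "A") -> tuple[EmrTables, SimTruth]:
    """Generate one synthetic EMR site and its planted truth.

    Identical (config, seed) reproduce byte-identical tables.  One RNG stream
    is split from the master seed per table so catalogs evolve independently.
    """
    config.validate()
    ss = np.random.SeedSequence([seed, ord(site)])
    s_demo, s_dx, s_med, s_lab = [np.random.default_rng(c) for c in ss.spawn(4)]
    n = config.n_patients
    ids = np.array([f"{site}{i:06d}" for i in range(n)])

    # --- demographics -------------------------------------------------------
    under = s_demo.random(n) < config.under_age_frac
    # truncated normal above age_min for the eligible majority
    from scipy.stats import truncnorm
    a = (config.age_min + 1 - config.age_mean) / config.age_sd
    ages = truncnorm.rvs(a, np.inf, loc=config.age_mean, scale=config.age_sd,
                         size=n, random_state=s_demo)
    ages[under] = s_demo.uniform(40, config.age_min, size=int(under.sum()))
    ages = np.floor(ages).astype(int)
    birth_year = config.reference_year - ages

    sex = s_demo.choice(np.array(SEX_LEVELS), size=n, p=np.asarray(config.sex_probs))
    races = np.array(list(config.race_probs))
    rp = np.array(list(config.race_probs.values()), dtype=float)
    race = s_demo.choice(races, size=n, p=rp / rp.sum())
    death = np.where(s_demo.random(n) < config.death_prob, "deceased", "alive")

    n_enc = s_demo.negative_binomial(
        config.encounters_dispersion,
        config.encounters_dispersion / (config.encounters_dispersion + config.encounters_mean),
        size=n) + 1
    span = np.round(s_demo.uniform(*config.span_years_range, size=n), 2)

    # AD status: only age-eligible patients can be cases; optionally confounded
    eligible = ages > config.age_min
    lg = logit(config.ad_prevalence) \
        + config.ad_age_logit_per_year * (ages - 85) \
        + config.ad_female_logit * (sex == "F")
    ad = (s_demo.random(n) < expit(lg)) & eligible

    patients = pd.DataFrame({
        "patient_id": ids, "sex": sex, "birth_year": birth_year, "race": race,
        "death_status": death, "n_encounters": n_enc, "span_years": span,
    })

    # record span in day offsets from epoch, ending 2019-12-31
    end_days = np.full(n, (np.datetime64("2019-12-31") - np.datetime64("1970-01-01"))
                       // np.timedelta64(1, "D"), dtype=np.int64)
    start_days = end_days - (span * 365.25).astype(np.int64)

    # --- diagnoses ----------------------------------------------------------
    female = sex == "F"
    boost = np.zeros((n, len(config.features)))
    code_index = {f.code: j for j, f in enumerate(config.features)}
    for mod in config.modules:
        p_act = np.where(ad, mod.p_active_case, mod.p_active_control)
        active = s_dx.random(n) < p_act
        for c in mod.members:
            boost[active, code_index[c]] += mod.logit_boost

    dx_pid, dx_code, dx_date = [], [], []
    for j, f in enumerate(config.features):
        lp = logit(f.baseline_prevalence) + f.log_or_case * ad \
            + f.log_or_case_female * (ad & female) + boost[:, j]
        present = np.flatnonzero(s_dx.random(n) < expit(lp))
        p, c, d = _bernoulli_events(s_dx, present, f.code, start_days, end_days, ids)
        dx_pid.extend(p); dx_code.extend(c); dx_date.extend(d)
    # AD patients always carry one of the case codes
    ad_idx = np.flatnonzero(ad)
    if ad_idx.size:
        chosen = s_dx.choice(np.array(config.case_codes), size=ad_idx.size)
        for cc in config.case_codes:
            sub = ad_idx[chosen == cc]
            p, c, d = _bernoulli_events(s_dx, sub, cc, start_days, end_days, ids)
            dx_pid.extend(p); dx_code.extend(c); dx_date.extend(d)
    diagnoses = pd.DataFrame({"patient_id": dx_pid, "code": dx_code, "date": dx_date})
    diagnoses = diagnoses.sort_values(["patient_id", "code", "date"]).reset_index(drop=True)

    # --- medications --------------------------------------------------------
    md_pid, md_str, md_date = [], [], []
    for med in config.medications:
        lp = logit(med.baseline_prevalence) + med.log_or_case * ad \
            + med.log_or_case_female * (ad & female)
        present = np.flatnonzero(s_med.random(n) < expit(lp))
        if present.size == 0:
            continue
        ndup = s_med.integers(1, 3, size=present.size)
        rep = np.repeat(present, ndup)
        strings = s_med.choice(np.array(med.order_strings), size=rep.size)
        dates = _dates_within_span(s_med, start_days[rep], end_days[rep])
        md_pid.extend(ids[rep]); md_str.extend(strings); md_date.extend(dates)
    medications = pd.DataFrame(
        {"patient_id": md_pid, "order_string": md_str, "date": md_date}
    ).sort_values(["patient_id", "order_string", "date"]).reset_index(drop=True)

    # --- labs ---------------------------------------------------------------
    lb_pid, lb_name, lb_val, lb_date = [], [], [], []
    for lab in config.labs:
        observed = np.flatnonzero(s_lab.random(n) >= lab.missing_prob)
        if observed.size == 0:
            continue
        mf = np.where(ad[observed], lab.mean_case_female, lab.mean_control_female)
        mm = np.where(ad[observed], lab.mean_case_male, lab.mean_control_male)
        mu = np.where(female[observed], mf,
                      np.where(sex[observed] == "M", mm, (mf + mm) / 2.0))
        rep = np.repeat(observed, lab.draws_per_patient)
        mu_rep = np.repeat(mu, lab.draws_per_patient)
        vals = np.round(s_lab.normal(mu_rep, lab.sd), 3)
        dates = _dates_within_span(s_lab, start_days[rep], end_days[rep])
        lb_pid.extend(ids[rep]); lb_name.extend([lab.name] * rep.size)
        lb_val.extend(vals); lb_date.extend(dates)
    labs = pd.DataFrame(
        {"patient_id": lb_pid, "test_name": lb_name, "value": lb_val, "date": lb_date}
    ).sort_values(["patient_id", "test_name", "date"]).reset_index(drop=True)

    tables = EmrTables(patients, diagnoses, medications, labs,
                       _build_hierarchy_frame(config))
    return tables, _make_truth(config)


def _make_truth(config: SimConfig) -> SimTruth:
    in_module = {c for m in config.modules for c in m.members}
    feats = pd.DataFrame([
        {"code": f.code, "baseline_prevalence": f.baseline_prevalence,
         "log_or": f.log_or_case, "or_overall": float(np.exp(f.log_or_case)),
         "or_female": float(np.exp(f.log_or_case + f.log_or_case_female)),
         "or_male": float(np.exp(f.log_or_case)),
         "in_module": f.code in in_module}
        for f in config.features
    ])
    meds = pd.DataFrame([
        {"generic": m.generic, "baseline_prevalence": m.baseline_prevalence,
         "log_or": m.log_or_case, "or_overall": float(np.exp(m.log_or_case)),
         "or_female": float(np.exp(m.log_or_case + m.log_or_case_female)),
         "or_male": float(np.exp(m.log_or_case))}
        for m in config.medications
    ])
    labs = pd.DataFrame([
        {"name": lb.name, "mean_case_female": lb.mean_case_female,
         "mean_case_male": lb.mean_case_male,
         "mean_control_female": lb.mean_control_female,
         "mean_control_male": lb.mean_control_male, "sd": lb.sd}
        for lb in config.labs
    ])
    mods = pd.DataFrame([
        {"name": m.name, "members": ";".join(m.members),
         "p_active_case": m.p_active_case, "p_active_control": m.p_active_control,
         "logit_boost": m.logit_boost}
        for m in config.modules
    ])
    return SimTruth(feats, meds, labs, mods)


def _dialect_rename(config: SimConfig, seed: int) -> tuple[dict[str, str], dict[str, str]]:
    """Build the site-B rename (applied to tables) and the inter-site code map.

    Renaming happens per level-3 family so the hierarchy stays coherent;
    case codes are never renamed (both sites define AD the same way).
    Returns (rename: siteA code -> siteB code, code_map: siteA -> siteB
    restricted to the mappable fraction).
    """
    dialect = config.dialect or SiteDialect(0.0, 0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    codes = [f.code for f in config.features]
    level3s = sorted({c[:3] for c in codes})
    n_ren = int(round(dialect.renamed_frac * len(level3s)))
    renamed3 = set(rng.choice(np.array(level3s), size=n_ren, replace=False)) if n_ren else set()
    new3 = {}
    used = set(level3s) | {c[:3] for c in config.case_codes}
    counter = 0
    for l3 in sorted(renamed3):
        while True:
            cand = f"{'UVWXYZ'[counter % 6]}{40 + counter // 6:02d}"
            counter += 1
            if cand not in used:
                used.add(cand)
                break
        new3[l3] = cand
    rename = {c: (new3[c[:3]] + c[3:] if c[:3] in new3 else c) for c in codes}
    n_unmap = int(round(dialect.unmappable_frac * len(codes)))
    unmappable = set(rng.choice(np.array(codes), size=n_unmap, replace=False)) if n_unmap else set()
    code_map = {c: rename[c] for c in codes if c not in unmappable}
    return rename, code_map


def generate_site_pair(config: SimConfig, seed: int
                       ) -> tuple[EmrTables, EmrTables, dict[str, str], SimTruth]:
    """Generate two sites sharing the same planted truth but differing in
    code dialect.  Returns (site_a, site_b, code_map a->b, truth)."""
    config.validate()
    tables_a, truth = generate_site(config, seed, site="A")
    tables_b, _ = generate_site(config, seed + 1, site="B")
    rename, code_map = _dialect_rename(config, seed)
    if rename:
        tables_b.diagnoses["code"] = tables_b.diagnoses["code"].map(
            lambda c: rename.get(c, c))
        tables_b.diagnoses = tables_b.diagnoses.sort_values(
            ["patient_id", "code", "date"]).reset_index(drop=True)
        renamed_cfg = replace(
            config,
            features=tuple(replace(f, code=rename.get(f.code, f.code))
                           for f in config.features),
            modules=tuple(replace(m, members=tuple(rename.get(c, c) for c in m.members))
                          for m in config.modules),
        )
        tables_b.hierarchy = _build_hierarchy_frame(renamed_cfg)
    return tables_a, tables_b, code_map, truth
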