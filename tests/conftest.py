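import numpy as np
import pandas as pd
import pytest

import emrpheno as ep
import emrpheno.hierarchy as hi


@pytest.fixture(scope="session")
def small_site():
    """A small default-catalog site shared by read-only tests."""
    cfg = ep.default_config(n_patients=800)
    tables, truth = ep.generate_site(cfg, seed=11)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def icd_mini_hierarchy():
    """A miniature real-ICD-style hierarchy with the G30-G32 sub-chapter."""
    frame = pd.DataFrame(
        [
            ("G00-G99", "chapter_block", "Diseases of the nervous system", ""),
            ("G30-G32", "level2_category",
             "Other degenerative diseases of the nervous system", "G00-G99"),
            ("G30", "level3_category", "Alzheimer's disease", "G30-G32"),
            ("G30.9", "full_name", "Alzheimer's disease, unspecified", "G30"),
            ("I00-I99", "chapter_block", "Diseases of the circulatory system", ""),
            ("I10-I16", "level2_category", "Hypertensive diseases", "I00-I99"),
            ("I10", "level3_category", "Essential (primary) hypertension", "I10-I16"),
        ],
        columns=["code", "level", "name", "parent"],
    )
    return hi.Hierarchy.from_frame(frame)


def cohort_feature_sets(tables, level="full_name", drop=()):
    """Roll up a synthetic site into case/control feature-set dicts."""
    cases = ep.identify_cases(tables)
    controls = ep.eligible_controls(tables)
    hier = hi.Hierarchy.from_frame(tables.hierarchy)
    rolled = hi.rollup(tables.diagnoses, level, hier)
    sets = hi.feature_sets(rolled, patient_ids=cases | controls)
    for s in sets.values():
        for code in drop:
            s.discard(code)
    return ({p: sets[p] for p in cases}, {p: sets[p] for p in controls})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
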