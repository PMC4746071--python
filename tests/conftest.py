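import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import healthimpact as hi

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return hi.default_catalog()


@pytest.fixture(scope="session")
def pub_weights():
    return hi.published_weights()


@pytest.fixture(scope="session")
def pub_model():
    return hi.published_model()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """Hand-built 5-subject cohort covering missing patterns."""
    base = {cid: 0.0 for cid in catalog.ids}
    for cid in catalog.age_restricted_ids:
        base[cid] = np.nan
    rows = []
    spec = [
        ("a", 0, 30.0, 1.2, 1, 4, {"asthma": 1.0}),
        ("b", 1, 45.0, np.nan, np.nan, 3, {"angina": 1.0, "diabetes": 1.0}),
        ("c", 0, 62.0, 2.5, 4, 2, {"fibromyalgia": 1.0}),
        ("d", 1, 75.0, 1.5, 2, 2, {"parkinsons_disease": 1.0, "migraine": 1.0}),
        ("e", 0, 51.0, np.nan, np.nan, np.nan, {}),
    ]
    for sid, sex, age, mhi, mcat, srh, conds in spec:
        row = dict(base)
        row.update(
            subject_id=sid, sex=float(sex), age=age, mhi_score=mhi,
            mhi_category=float(mcat) if not np.isnan(np.float64(mcat)) else np.nan,
            srh=float(srh) if not np.isnan(np.float64(srh)) else np.nan,
        )
        if age > 70:
            for cid in catalog.age_restricted_ids:
                row[cid] = 0.0
        row.update(conds)
        rows.append(row)
    return hi.CohortTable(pd.DataFrame(rows), catalog)


@pytest.fixture(scope="session")
def sim_cohort_20k(pub_model, pub_weights):
    """Default-generator cohort at the reference-study model, n=20,000."""
    cfg = hi.default_tromso4_config(n=20_000, seed=20_160_205)
    return hi.generate(cfg)
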