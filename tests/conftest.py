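import numpy as np
import pandas as pd
import pytest

import icvnorm as iv
from icvnorm.normalization import _wrap_unvalidated


@pytest.fixture(scope="session")
def three_point_cohort():
    """Exactly collinear fixture: V = 1000 + 1e-3 * ICV, slope known in closed form."""
    df = pd.DataFrame({
        "subject_id": ["a", "b", "c"],
        "gender": ["F", "F", "M"],
        "age": 75.0,
        "diagnosis": "CTL",
        "icv": [1.0e6, 1.5e6, 2.0e6],
        "voi": [3000.0, 3500.0, 4000.0],
    })
    return iv.Cohort(df, regions=("voi",))


@pytest.fixture(scope="session")
def pivus_small():
    """Default single-age cohort at reduced size; shared across read-only tests."""
    return iv.generate_cohort(iv.pivus_like_spec(n_per_cell=150, seed=11))


@pytest.fixture(scope="session")
def adni_small():
    """Three-diagnosis cohort with age variation and atrophy, 60 subjects per cell."""
    return iv.generate_cohort(iv.adni_like_spec(n_per_cell=60, seed=13))


@pytest.fixture(scope="session")
def adni_adjusted(adni_small):
    model = iv.fit_reference_model(adni_small, "CTL")
    return {m: iv.adjust(adni_small, m, model=model) for m in ("raw", "proportion", "residual")}


def single_region_cohort(values, icv, genders=None, diagnosis="CTL", region="vol"):
    """Helper for hand-built one-region tables (unvalidated, any numeric values)."""
    n = len(values)
    df = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "gender": genders if genders is not None else ["F"] * n,
        "age": 75.0,
        "diagnosis": diagnosis,
        "icv": np.asarray(icv, dtype=float),
        region: np.asarray(values, dtype=float),
    })
    return _wrap_unvalidated(df, (region,), ())
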