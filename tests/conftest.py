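import numpy as np
import pandas as pd
import pytest

import vestibench as vb
from vestibench.cohort import Cohort


@pytest.fixture(scope="session")
def schema():
    return vb.default_schema()


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-sized cohort (108 patients, 5% MCAR missingness)."""
    return vb.generate_cohort(vb.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Study-sized cohort without missingness, for logical-consistency checks."""
    return vb.generate_cohort(vb.GeneratorConfig(seed=13, missing_rate=0.0))


def build_cohort(schema, n, overrides, y, missing=None, id_prefix="P"):
    """Hand-built cohort: all features zero except explicit overrides.

    ``overrides`` maps feature name -> array-like of length n; ``y`` is the
    0/1 stroke indicator; ``missing`` maps feature name -> boolean mask.
    """
    ids = pd.Index([f"{id_prefix}{i:03d}" for i in range(n)], name="patient_id")
    vals = pd.DataFrame(0.0, index=ids, columns=list(schema.names))
    for name, col in overrides.items():
        vals[name] = np.asarray(col, float)
    if missing:
        for name, m in missing.items():
            vals.loc[np.asarray(m, bool), name] = np.nan
    labels = pd.Series(np.where(np.asarray(y) == 1, "stroke", "neuritis"), index=ids)
    return Cohort(vals, schema, labels)


@pytest.fixture(scope="session")
def separable_cohort(schema):
    """20-patient toy cohort, linearly separable on one gain feature."""
    rng = np.random.default_rng(42)
    y = np.array([0, 1] * 10)
    gain = np.where(y == 1, 1.2, 0.4) + rng.normal(0, 0.02, 20)
    age = np.where(y == 1, 70.0, 45.0) + rng.normal(0, 2.0, 20)
    return build_cohort(schema, 20, {"vhit_gain_right": gain, "age": age}, y)
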