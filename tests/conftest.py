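import numpy as np
import pandas as pd
import pytest

import medmod as mm


@pytest.fixture(scope="session")
def study_spec():
    return mm.study_moment_spec()


@pytest.fixture(scope="session")
def exact_study_df(study_spec):
    """Study-sized dataset whose sample moments equal the published ones
    exactly, with age and sex appended."""
    return mm.generate_scale_level(
        study_spec,
        mm.STUDY_N,
        seed=20240,
        demographics=mm.study_demographics(),
        exact_moments=True,
    )


@pytest.fixture(scope="session")
def sampled_study_df(study_spec):
    """Plain (non-exact) draw from the study moments."""
    return mm.generate_scale_level(
        study_spec, mm.STUDY_N, seed=907, demographics=mm.study_demographics()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_regression_frame(seed=5, n=60, k=2):
    """Small generic frame for regression plumbing tests."""
    g = np.random.default_rng(seed)
    data = {f"x{i}": g.normal(size=n) for i in range(1, k + 1)}
    df = pd.DataFrame(data)
    df["y"] = sum(0.5 * i * df[f"x{i}"] for i in range(1, k + 1)) + g.normal(size=n)
    return df
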