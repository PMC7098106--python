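import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import healthineq as hi

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ds() -> hi.SurveyDataset:
    """300-woman stratified two-stage sample with the default outcome models."""
    return hi.simulate_survey(
        hi.DesignParams(n_strata=2, psus_per_stratum=10, households_per_psu=15, seed=7)
    )


@pytest.fixture(scope="session")
def wealth_ds(small_ds) -> hi.SurveyDataset:
    """Copy of the small sample with wealth index columns added."""
    import copy

    ds = hi.SurveyDataset(small_ds.table.copy(), copy.deepcopy(small_ds.config))
    hi.add_wealth_index(ds)
    return ds


@pytest.fixture()
def toy_frame() -> pd.DataFrame:
    """4-row equal-weight frame whose index values are known in closed form."""
    return pd.DataFrame({
        "y": [0, 0, 1, 1],
        "x": [1.0, 2.0, 3.0, 4.0],
        "w": [1.0, 1.0, 1.0, 1.0],
    })


def anova_icc(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way random-effects ANOVA estimator of the intracluster correlation."""
    df = pd.DataFrame({"v": values, "g": groups})
    grand = df["v"].mean()
    sizes = df.groupby("g")["v"].count()
    means = df.groupby("g")["v"].mean()
    k = len(sizes)
    n = len(df)
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df["v"] - means.loc[df["g"]].to_numpy()) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - float((sizes**2).sum()) / n) / (k - 1)
    return (msb - msw) / (msb + (n0 - 1) * msw)


def double_sum_conc_index(y, x, w) -> float:
    """Independent O(n^2) pairwise form of the weighted concentration index."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    W = w.sum()
    ybar = np.sum(w * y) / W
    total = 0.0
    for i in range(len(y)):
        for j in range(len(y)):
            total += w[i] * w[j] * (y[i] - y[j]) * np.sign(x[i] - x[j])
    return total / (2.0 * W**2 * ybar)
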