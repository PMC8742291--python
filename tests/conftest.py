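import numpy as np
import pytest

import ognmf as og
from ognmf.cohort_io import ColumnScaling, FeatureMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic screening cohort at the published group sizes."""
    cohort, truth = og.generate_cohort(seed=7)
    return cohort, truth


@pytest.fixture(scope="session")
def encoded(default_cohort):
    cohort, _ = default_cohort
    return og.encode_features(cohort)


def make_lowrank_fm(n=60, k=3, seed=0, ratio_bounds=(1.8, 8.6)):
    """A fully observed low-rank feature matrix whose last column plays the
    CHOL/HDL ratio (scaled into clinical ratio units), plus per-row sex.

    Used to validate imputation-driven risk prediction where the rank-k
    structure is real.
    """
    p = 14
    X, M, truth = og.generate_lowrank(n, p, k, seed=seed)
    # normalize columns into [0, 1] so the affine ratio decoding is sensible
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    Xs = (X - lo) / np.where(hi > lo, hi - lo, 1.0)
    columns = [f"f{j}" for j in range(p - 1)] + ["chol_hdl"]
    scaling = {c: ColumnScaling("continuous", lo=0.0, hi=1.0) for c in columns}
    scaling["chol_hdl"] = ColumnScaling(
        "continuous", lo=ratio_bounds[0], hi=ratio_bounds[1]
    )
    fm = FeatureMatrix(X=Xs, M=np.ones_like(Xs), columns=columns, scaling=scaling)
    rng = np.random.default_rng(seed + 1)
    sex = list(rng.choice(["M", "F"], size=n))
    return fm, sex
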