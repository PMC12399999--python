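import numpy as np
import pandas as pd
import pytest

from quintrisk.config import RiskFactorSpec
from quintrisk.io import ChildTable, CoverageTable


@pytest.fixture
def binary_factor():
    return RiskFactorSpec("exposure", ("no", "yes"), rr_case=(1.0, 2.0), rr_death=(1.0, 2.0))


@pytest.fixture
def stunting3():
    return RiskFactorSpec(
        "stunting", ("none", "moderate", "severe"),
        rr_case=(1.0, 1.3, 1.6), rr_death=(1.0, 1.35, 1.7),
    )


@pytest.fixture
def wasting3():
    return RiskFactorSpec(
        "wasting", ("none", "moderate", "severe"),
        rr_case=(1.0, 1.25, 1.5), rr_death=(1.0, 1.4, 1.8),
    )


@pytest.fixture
def two_factor_table(stunting3, wasting3):
    """A 9-profile table with product-form counts, exactly consistent with
    the multiplicative truth."""
    from quintrisk.profiles import ProfileTable, enumerate_profiles

    prof = enumerate_profiles([stunting3, wasting3])
    marg_s = np.array([0.5, 0.3, 0.2])
    marg_w = np.array([0.6, 0.3, 0.1])
    n = 1000.0 * marg_s[prof.levels[:, 0]] * marg_w[prof.levels[:, 1]]
    counts = np.tile((n / 5.0)[:, None], (1, 5))
    return ProfileTable(prof.factors, prof.levels, counts)


@pytest.fixture
def flat_coverage():
    return CoverageTable(
        vaccine_coverage={"mcv": np.full(5, 0.6)},
        careseek={"diarrhoea": np.full(5, 0.4), "ari": np.full(5, 0.6),
                  "fever": np.full(5, 0.5)},
    )


def make_children(rows: list[tuple], factor_names: tuple[str, ...]) -> ChildTable:
    """rows: (quintile, *levels, weight)"""
    cols = ["quintile", *factor_names, "weight"]
    return ChildTable(pd.DataFrame(rows, columns=cols), factor_names)
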