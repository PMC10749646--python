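import numpy as np
import pytest
from hypothesis import settings

from kanocca import CategoryTally, KanoCategory

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_tally(a=0, o=0, m=0, i=0, r=0, q=0) -> CategoryTally:
    return CategoryTally(
        {
            KanoCategory.ATTRACTIVE: a,
            KanoCategory.ONE_DIMENSIONAL: o,
            KanoCategory.MUST_BE: m,
            KanoCategory.INDIFFERENT: i,
            KanoCategory.REVERSE: r,
            KanoCategory.QUESTIONABLE: q,
        }
    )


@pytest.fixture
def case_study():
    from kanocca import load_case_study

    return load_case_study()


@pytest.fixture
def case_study_tallies(case_study):
    """Published percentage rows as tallies (percentages used as counts)."""
    return {
        attr: make_tally(row.pct_a, row.pct_o, row.pct_m, row.pct_i, row.pct_r, row.pct_q)
        for attr, row in case_study.iterrows()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
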