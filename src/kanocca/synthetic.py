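"""Synthetic Kano surveys: deterministic fixtures and GCM-driven generators.

Two kinds of data make the whole pipeline testable without any external
download:

* **Deterministic fixtures** rebuilt from published per-attribute category
  percentage rows: each category's share of respondents is placed on one
  fixed, canonical cell of the pair-classification grid, so tallying the
  fixture reproduces the input row exactly.
* **Stochastic surveys** driven by the General Condorcet Model: binary
  relevance is drawn per respondent x item, then a Kano category is emitted
  from a high-relevancy (M/O/A) or low-relevancy (I/R/Q) distribution and
  written as its canonical answer pair.  By construction the relevance
  dichotomization of the survey equals the generating binary matrix, which
  is what makes exact parameter-recovery harnesses possible.

The module also ships the vaccine-messaging case-study reference table (14
attributes: per-category percentages, published classifications, consensus
item truths and difficulties) and cohort-level generating distributions
matching that study's reported estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .gcm import GCMParameters, simulate_gcm
from .survey import (
    AttributeSpec,
    KanoCategory,
    ResponseOption,
    ResponsePair,
    SurveyDataset,
    classify_pair,
)

__all__ = [
    "EmissionModel",
    "fixture_from_percentages",
    "generate_gcm_survey",
    "generate_two_culture_survey",
    "load_case_study",
    "case_study_fixture",
    "case_study_gcm_parameters",
    "beta_from_moments",
    "COMPETENCY_MEAN",
    "COMPETENCY_SD",
    "GUESSING_MEAN",
    "GUESSING_SD",
]

_A = KanoCategory.ATTRACTIVE
_O = KanoCategory.ONE_DIMENSIONAL
_M = KanoCategory.MUST_BE
_I = KanoCategory.INDIFFERENT
_R = KanoCategory.REVERSE
_Q = KanoCategory.QUESTIONABLE

#: Cohort-level generating distributions: the case study's reported
#: mean/SD of respondent competency and guessing bias.
COMPETENCY_MEAN = 0.34
COMPETENCY_SD = 0.14
GUESSING_MEAN = 0.34
GUESSING_SD = 0.172

#: One fixed grid cell per category (all six are cells of that category).
CANONICAL_PAIRS: dict[KanoCategory, ResponsePair] = {
    _A: ResponsePair(ResponseOption.LIKE, ResponseOption.NEUTRAL),
    _O: ResponsePair(ResponseOption.LIKE, ResponseOption.DISLIKE),
    _M: ResponsePair(ResponseOption.MUST_BE, ResponseOption.DISLIKE),
    _I: ResponsePair(ResponseOption.NEUTRAL, ResponseOption.NEUTRAL),
    _R: ResponsePair(ResponseOption.DISLIKE, ResponseOption.LIKE),
    _Q: ResponsePair(ResponseOption.LIKE, ResponseOption.LIKE),
}

# All grid cells per category, for uniform-within-category stress emission.
_CELLS_BY_CATEGORY: dict[KanoCategory, list[ResponsePair]] = {}
for _f in ResponseOption:
    for _d in ResponseOption:
        _p = ResponsePair(_f, _d)
        _CELLS_BY_CATEGORY.setdefault(classify_pair(_p), []).append(_p)
del _f, _d, _p


@dataclass
class EmissionModel:
    """Bridge from binary GCM relevance to six-category Kano answers.

    ``high`` is the category distribution emitted when the drawn relevance
    bit is 1 (over M, O, A), ``low`` when it is 0 (over I, R, Q).  Emitted
    categories are written as their canonical answer-pair cell, keeping
    fixtures deterministic and classification-invariant; set
    ``uniform_cells=True`` to sample uniformly among all grid cells of the
    category instead (stress testing).
    """

    high: dict[KanoCategory, float] = field(
        default_factory=lambda: {_M: 1 / 3, _O: 1 / 3, _A: 1 / 3}
    )
    low: dict[KanoCategory, float] = field(
        default_factory=lambda: {_I: 0.8, _R: 0.1, _Q: 0.1}
    )
    uniform_cells: bool = False

    def __post_init__(self) -> None:
        if set(self.high) != {_M, _O, _A}:
            raise ValueError("high distribution must cover exactly M, O, A")
        if set(self.low) != {_I, _R, _Q}:
            raise ValueError("low distribution must cover exactly I, R, Q")
        for dist in (self.high, self.low):
            vals = np.array(list(dist.values()), dtype=float)
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError("emission distributions must be nonnegative and sum to 1")

    def emit(self, relevant: bool, rng: np.random.Generator) -> tuple[KanoCategory, ResponsePair]:
        dist = self.high if relevant else self.low
        cats = list(dist)
        cat = cats[rng.choice(len(cats), p=list(dist.values()))]
        if self.uniform_cells:
            cells = _CELLS_BY_CATEGORY[cat]
            return cat, cells[rng.integers(len(cells))]
        return cat, CANONICAL_PAIRS[cat]


_CATEGORY_ORDER = (_A, _O, _M, _I, _R, _Q)


def fixture_from_percentages(
    rows: dict[str, tuple[float, float, float, float, float, float]],
    n_respondents: int = 100,
) -> SurveyDataset:
    """Deterministic survey whose tallies reproduce percentage rows exactly.

    ``rows`` maps attribute id to six percentages in A, O, M, I, R, Q
    order.  Each percentage must convert to an integer count at the chosen
    ``n_respondents`` (with n=100, percentages are used as counts
    directly); a non-integer count raises an error naming the row.  Rows
    summing to less than 100 leave trailing respondents' pairs missing.
    """
    respondents = [f"r{i + 1:04d}" for i in range(n_respondents)]
    attributes = [AttributeSpec(id=a) for a in rows]
    pairs: dict[tuple[str, str], ResponsePair] = {}
    for attr, pcts in rows.items():
        if len(pcts) != 6:
            raise ValueError(f"row {attr!r}: expected 6 percentages (A,O,M,I,R,Q)")
        counts = []
        for cat, pct in zip(_CATEGORY_ORDER, pcts):
            c = pct * n_respondents / 100.0
            if pct < 0 or abs(c - round(c)) > 1e-9:
                raise ValueError(
                    f"row {attr!r}: {pct}% of {n_respondents} respondents "
                    f"is not an integer count for category {cat}"
                )
            counts.append(int(round(c)))
        if sum(counts) > n_respondents:
            raise ValueError(f"row {attr!r}: counts exceed n_respondents")
        i = 0
        for cat, count in zip(_CATEGORY_ORDER, counts):
            for _ in range(count):
                pairs[(respondents[i], attr)] = CANONICAL_PAIRS[cat]
                i += 1
    return SurveyDataset(respondents=respondents, attributes=attributes, pairs=pairs)


def generate_gcm_survey(
    params: GCMParameters,
    emission: EmissionModel | None = None,
    seed: int | np.random.Generator = 0,
    attribute_ids: list[str] | None = None,
) -> tuple[SurveyDataset, pd.DataFrame]:
    """Draw a survey from the GCM and return it with its binary matrix.

    A relevance bit is drawn per respondent x item from the GCM; the
    emission model turns it into a Kano category written as an answer-pair
    cell.  The returned binary DataFrame equals the relevance-scheme
    dichotomization of the returned survey exactly, for every seed.
    """
    emission = emission or EmissionModel()
    rng = np.random.default_rng(seed)
    binary = simulate_gcm(params, rng)
    n, m = binary.shape
    respondents = [f"r{i + 1:04d}" for i in range(n)]
    attribute_ids = attribute_ids or [f"item{k + 1:02d}" for k in range(m)]
    if len(attribute_ids) != m:
        raise ValueError("attribute_ids length must match the item count")
    attributes = [AttributeSpec(id=a) for a in attribute_ids]
    pairs: dict[tuple[str, str], ResponsePair] = {}
    for i, resp in enumerate(respondents):
        for k, attr in enumerate(attribute_ids):
            _, pair = emission.emit(bool(binary[i, k]), rng)
            pairs[(resp, attr)] = pair
    survey = SurveyDataset(respondents=respondents, attributes=attributes, pairs=pairs)
    matrix = pd.DataFrame(binary.astype(float), index=respondents, columns=attribute_ids)
    return survey, matrix


def generate_two_culture_survey(
    params_a: GCMParameters,
    params_b: GCMParameters,
    mixing: float = 0.5,
    seed: int | np.random.Generator = 0,
    emission: EmissionModel | None = None,
) -> tuple[SurveyDataset, np.ndarray]:
    """Survey whose respondents split between two consensus cultures.

    ``params_a`` and ``params_b`` must describe the same respondents and
    items but may differ in truth vectors (and anything else); each
    respondent is assigned to culture A with proportion ``mixing`` (exact
    split, randomized membership) and answers from that culture's
    parameters.  Returns the survey and the per-respondent culture labels
    (``"A"``/``"B"``) for oracle checks.
    """
    if not 0.0 < mixing < 1.0:
        raise ValueError("mixing must lie strictly between 0 and 1")
    if params_a.n_respondents != params_b.n_respondents:
        raise ValueError("parameter sets must cover the same respondents")
    if params_a.n_items != params_b.n_items:
        raise ValueError("parameter sets must cover the same items")
    if np.array_equal(params_a.z, params_b.z):
        warnings.warn(
            "both cultures share one truth vector; they are indistinguishable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = params_a.n_respondents
    n_a = int(round(mixing * n))
    n_a = min(max(n_a, 1), n - 1)
    labels = np.array(["B"] * n, dtype=object)
    labels[rng.permutation(n)[:n_a]] = "A"

    survey_a, _ = generate_gcm_survey(params_a, emission, rng)
    survey_b, _ = generate_gcm_survey(params_b, emission, rng)
    pairs = {
        key: (survey_a.pairs[key] if labels[int(key[0][1:]) - 1] == "A" else survey_b.pairs[key])
        for key in survey_a.pairs
    }
    survey = SurveyDataset(
        respondents=survey_a.respondents,
        attributes=survey_a.attributes,
        pairs=pairs,
    )
    return survey, labels


# ---------------------------------------------------------------------------
# Case-study reference data
# ---------------------------------------------------------------------------


def load_case_study() -> pd.DataFrame:
    """Published per-attribute results of the vaccine-messaging case study.

    Columns: six category percentages (``pct_a`` .. ``pct_q``), the three
    published classifications, the consensus binary truth, posterior item
    truth and item difficulty, indexed by attribute id (the privacy
    attribute appears in recoded form, B4R).
    """
    with resources.files("kanocca.data").joinpath("case_study.csv").open() as fh:
        return pd.read_csv(fh, index_col="attribute_id")


def case_study_fixture(n_respondents: int = 100) -> SurveyDataset:
    """Exact fixture for the case-study rows whose percentages sum to 100.

    Rows summing to 99, 98 or 101 (printed rounding) cannot be reproduced
    as exact counts and are excluded.
    """
    df = load_case_study()
    rows = {}
    for attr, row in df.iterrows():
        pcts = tuple(row[c] for c in ("pct_a", "pct_o", "pct_m", "pct_i", "pct_r", "pct_q"))
        if abs(sum(pcts) - 100.0) < 1e-9:
            rows[str(attr)] = pcts
    return fixture_from_percentages(rows, n_respondents=n_respondents)


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters (a, b) of the Beta distribution with given mean/SD."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly in (0, 1)")
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError("sd too large for a Beta distribution with this mean")
    return mean * nu, (1.0 - mean) * nu


def case_study_gcm_parameters(
    seed: int | np.random.Generator = 0,
    n_respondents: int = 205,
    difficulty: np.ndarray | None = None,
) -> GCMParameters:
    """Generating GCM parameters at the case study's reported cohort levels.

    Competencies and guessing biases are Beta draws moment-matched to the
    reported cohort mean/SD; truths are the published binary truth column;
    difficulties default to the published per-item difficulty column (pass
    an array to override, e.g. an even spread for recovery harnesses).
    """
    rng = np.random.default_rng(seed)
    df = load_case_study()
    theta = rng.beta(*beta_from_moments(COMPETENCY_MEAN, COMPETENCY_SD), n_respondents)
    g = rng.beta(*beta_from_moments(GUESSING_MEAN, GUESSING_SD), n_respondents)
    if difficulty is None:
        difficulty = df["item_difficulty"].to_numpy(dtype=float)
        # Difficulties of exactly 0/1 would make items deterministic; the
        # published column stays inside (0, 1) so no clipping is needed.
    z = df["binary_truth"].to_numpy(dtype=int)
    return GCMParameters(theta=theta, g=g, delta=np.asarray(difficulty, float), z=z)
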