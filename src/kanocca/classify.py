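"""Attribute-level Kano classification rules and dichotomization schemes.

Three rules turn a per-attribute category tally into a single classification:

* **original** — the modal category of individual classifications;
* **revised** (Blauth) — pool high-relevancy categories (M, O, A) against
  low-relevancy ones (I, R, Q); if the high pool strictly outweighs the low
  pool take the largest high category, otherwise the largest low category;
* **consensus-based** — same two-branch structure, but the branch is chosen
  by the consensus model's posterior item truth (> 0.5 means the group's
  culturally true answer is "relevant for satisfaction").

All rules share a fixed tie-break priority M > O > A > I > R > Q; ties and
exact boundary conditions raise ``tie_flag`` so fragile classifications are
surfaced rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .survey import (
    CategoryTally,
    KanoCategory,
    SurveyDataset,
    classify_pair,
    recode_reverse,
)

__all__ = [
    "ClassificationResult",
    "DichotomizationScheme",
    "classify_original",
    "classify_revised",
    "classify_cca",
    "classify_attribute",
    "dichotomize",
    "binary_matrix",
]

_M = KanoCategory.MUST_BE
_O = KanoCategory.ONE_DIMENSIONAL
_A = KanoCategory.ATTRACTIVE
_I = KanoCategory.INDIFFERENT
_R = KanoCategory.REVERSE
_Q = KanoCategory.QUESTIONABLE

#: Tie-break priority for modal and inner-max decisions.
PRIORITY: tuple[KanoCategory, ...] = (_M, _O, _A, _I, _R, _Q)

HIGH_RELEVANCY: tuple[KanoCategory, ...] = (_M, _O, _A)
LOW_RELEVANCY: tuple[KanoCategory, ...] = (_I, _R, _Q)


class DichotomizationScheme(Enum):
    """Mappings from Kano categories to binary relevance.

    ``RELEVANCE`` codes M, O, A as relevant (1) and I, R, Q as not (0); it
    feeds the consensus model.  ``RELEVANCE_WITH_REVERSE`` additionally codes
    R as relevant, guarding against underestimating respondents for whom an
    attribute matters negatively; it feeds the scree/eigenvalue analysis.
    """

    RELEVANCE = "relevance"
    RELEVANCE_WITH_REVERSE = "relevance_with_reverse"

    @property
    def mapping(self) -> dict[KanoCategory, int]:
        ones = (
            {_M, _O, _A}
            if self is DichotomizationScheme.RELEVANCE
            else {_M, _O, _A, _R}
        )
        return {cat: int(cat in ones) for cat in KanoCategory}


def dichotomize(category: KanoCategory, scheme: DichotomizationScheme) -> int:
    """Map one category to its binary relevance bit under ``scheme``."""
    return scheme.mapping[category]


def binary_matrix(dataset: SurveyDataset, scheme: DichotomizationScheme) -> pd.DataFrame:
    """Respondent x attribute matrix of relevance bits under ``scheme``.

    Each cell classifies the respondent's answer pair (reverse recoding
    applied per the manifest) and maps the category through the scheme;
    missing pairs become NaN.  Columns are effective attribute ids.
    """
    mapping = scheme.mapping
    columns = [spec.effective_id for spec in dataset.attributes]
    out = pd.DataFrame(np.nan, index=list(dataset.respondents), columns=columns)
    for spec in dataset.attributes:
        for resp, pair in dataset.pairs_for(spec.id).items():
            if spec.reverse_recoded:
                pair = recode_reverse(pair)
            out.loc[resp, spec.effective_id] = mapping[classify_pair(pair)]
    return out


def _argmax(tally: CategoryTally, pool: tuple[KanoCategory, ...]) -> tuple[KanoCategory, bool]:
    """Largest-count category within ``pool``; ties broken by PRIORITY order."""
    ordered = [c for c in PRIORITY if c in pool]
    best = max(ordered, key=lambda c: tally[c])
    tie = sum(tally[c] == tally[best] for c in ordered) > 1
    return best, tie


def classify_original(tally: CategoryTally) -> KanoCategory:
    """Modal classification: the category most respondents chose."""
    return _argmax(tally, PRIORITY)[0]


def classify_revised(tally: CategoryTally) -> KanoCategory:
    """Blauth's revised rule.

    If ``M + O + A > I + R + Q`` (strictly) return the largest of M, O, A,
    else the largest of I, R, Q.  Equality of the pools takes the else
    branch.
    """
    high = sum(tally[c] for c in HIGH_RELEVANCY)
    low = sum(tally[c] for c in LOW_RELEVANCY)
    pool = HIGH_RELEVANCY if high > low else LOW_RELEVANCY
    return _argmax(tally, pool)[0]


def classify_cca(tally: CategoryTally, item_truth: float) -> KanoCategory:
    """Consensus-based rule.

    If the posterior item truth exceeds 0.5 (strictly) the group consensus
    deems the attribute relevant: return the largest of M, O, A; otherwise
    the largest of I, R, Q.
    """
    if not 0.0 <= item_truth <= 1.0:
        raise ValueError(f"item_truth must be in [0, 1], got {item_truth}")
    pool = HIGH_RELEVANCY if item_truth > 0.5 else LOW_RELEVANCY
    return _argmax(tally, pool)[0]


@dataclass
class ClassificationResult:
    """Per-attribute outcome of the classification rules.

    ``cca`` is None when no item-truth estimate was supplied.  ``tie_flag``
    is True when any applied rule met a tie or an exact boundary (modal tie,
    equal relevancy pools, inner-max tie, or item truth exactly 0.5).
    """

    attribute_id: str
    original: KanoCategory
    revised: KanoCategory
    cca: KanoCategory | None
    tally: CategoryTally
    tie_flag: bool


def classify_attribute(
    attribute_id: str,
    tally: CategoryTally,
    item_truth: float | None = None,
) -> ClassificationResult:
    """Apply all classification rules to one attribute and record ties."""
    original, tie_modal = _argmax(tally, PRIORITY)

    high = sum(tally[c] for c in HIGH_RELEVANCY)
    low = sum(tally[c] for c in LOW_RELEVANCY)
    pool = HIGH_RELEVANCY if high > low else LOW_RELEVANCY
    revised, tie_inner = _argmax(tally, pool)
    tie_pools = high == low

    cca: KanoCategory | None = None
    tie_cca = False
    if item_truth is not None:
        cca = classify_cca(tally, item_truth)
        cca_pool = HIGH_RELEVANCY if item_truth > 0.5 else LOW_RELEVANCY
        tie_cca = _argmax(tally, cca_pool)[1] or item_truth == 0.5

    return ClassificationResult(
        attribute_id=attribute_id,
        original=original,
        revised=revised,
        cca=cca,
        tally=tally,
        tie_flag=tie_modal or tie_pools or tie_inner or tie_cca,
    )
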