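"""Domain types for two-question (functional/dysfunctional) Kano surveys.

A Kano questionnaire asks two questions per product attribute: how the
respondent would feel if the attribute were present (functional question)
and how they would feel if it were absent (dysfunctional question), each on
a five-option scale from "I like it that way" to "I dislike it that way".
The answer pair places the respondent's view of the attribute into one of
six categories: attractive (A), one-dimensional (O), must-be (M),
indifferent (I), reverse (R) or questionable (Q).

This module holds the atomic types (response options, categories, answer
pairs, attribute manifests, datasets), the 5x5 pair-classification grid,
reverse-attribute recoding, and per-attribute tallying.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum, IntEnum

__all__ = [
    "ResponseOption",
    "KanoCategory",
    "ResponsePair",
    "AttributeSpec",
    "SurveyDataset",
    "CategoryTally",
    "classify_pair",
    "recode_reverse",
    "tally_attribute",
]


class ResponseOption(IntEnum):
    """The five answer options, coded 1-5 in questionnaire order."""

    LIKE = 1        #: "I like it that way."
    MUST_BE = 2     #: "It must be that way."
    NEUTRAL = 3     #: "I am neutral."
    LIVE_WITH = 4   #: "I can live with it that way."
    DISLIKE = 5     #: "I dislike it that way."


class KanoCategory(str, Enum):
    """The six Kano quality-attribute categories."""

    ATTRACTIVE = "A"
    ONE_DIMENSIONAL = "O"
    MUST_BE = "M"
    INDIFFERENT = "I"
    REVERSE = "R"
    QUESTIONABLE = "Q"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Pair-classification grid: row = functional answer, column = dysfunctional
# answer, both in code order 1..5.  E.g. (Like, Dislike) -> one-dimensional.
_A = KanoCategory.ATTRACTIVE
_O = KanoCategory.ONE_DIMENSIONAL
_M = KanoCategory.MUST_BE
_I = KanoCategory.INDIFFERENT
_R = KanoCategory.REVERSE
_Q = KanoCategory.QUESTIONABLE

_CLASSIFICATION_GRID: dict[tuple[int, int], KanoCategory] = {}
for _f, _row in zip(
    range(1, 6),
    [
        [_Q, _A, _A, _A, _O],
        [_R, _I, _I, _I, _M],
        [_R, _I, _I, _I, _M],
        [_R, _I, _I, _I, _M],
        [_R, _R, _R, _R, _Q],
    ],
):
    for _d, _cat in zip(range(1, 6), _row):
        _CLASSIFICATION_GRID[(_f, _d)] = _cat
del _f, _d, _row, _cat


@dataclass(frozen=True)
class ResponsePair:
    """One respondent's (functional, dysfunctional) answer pair for one attribute."""

    functional: ResponseOption
    dysfunctional: ResponseOption

    def __post_init__(self) -> None:
        object.__setattr__(self, "functional", ResponseOption(self.functional))
        object.__setattr__(self, "dysfunctional", ResponseOption(self.dysfunctional))


@dataclass(frozen=True)
class AttributeSpec:
    """Manifest entry for one surveyed attribute.

    Parameters
    ----------
    id
        Short identifier, e.g. ``"A4"`` or ``"B2"``.
    label
        Human-readable attribute name.
    group
        Attribute family: ``characteristics``, ``distribution`` or ``content``.
    reverse_recoded
        If True the attribute is analysed with functional and dysfunctional
        answers swapped (the negated attribute), and reported under the
        derived id ``id + "R"``.
    """

    id: str
    label: str = ""
    group: str = ""
    reverse_recoded: bool = False

    @property
    def effective_id(self) -> str:
        """Id under which the attribute is analysed (``"R"`` suffix if recoded)."""
        return f"{self.id}R" if self.reverse_recoded else self.id


class SurveyError(ValueError):
    """Raised for malformed or inconsistent survey data."""


@dataclass
class CategoryTally:
    """Per-attribute counts over the six Kano categories.

    ``counts`` maps every category to a nonnegative count and the counts sum
    to ``n``, the number of classified (non-missing) answer pairs.
    """

    counts: dict[KanoCategory, int]
    n: int = field(init=False)

    def __post_init__(self) -> None:
        full = {cat: int(self.counts.get(cat, 0)) for cat in KanoCategory}
        if any(v < 0 for v in full.values()):
            raise SurveyError("category counts must be nonnegative")
        self.counts = full
        self.n = sum(full.values())
        if self.n == 0:
            raise SurveyError("a tally needs at least one classified pair")

    def __getitem__(self, category: KanoCategory) -> int:
        return self.counts[category]

    @property
    def percentages(self) -> dict[KanoCategory, float]:
        return {cat: 100.0 * c / self.n for cat, c in self.counts.items()}

    @classmethod
    def from_pairs(cls, pairs: Iterable[ResponsePair]) -> "CategoryTally":
        counts: dict[KanoCategory, int] = {}
        for pair in pairs:
            cat = classify_pair(pair)
            counts[cat] = counts.get(cat, 0) + 1
        return cls(counts)


@dataclass
class SurveyDataset:
    """A long-format Kano survey.

    ``pairs`` maps ``(respondent_id, attribute_id)`` to a :class:`ResponsePair`;
    missing pairs are simply absent from the mapping.  Attribute ids in
    ``pairs`` refer to the manifest ``id`` (before any reverse recoding).
    """

    respondents: list[str]
    attributes: list[AttributeSpec]
    pairs: dict[tuple[str, str], ResponsePair]

    def __post_init__(self) -> None:
        if not self.respondents or not self.attributes:
            raise SurveyError("dataset needs at least one respondent and one attribute")
        ids = [a.id for a in self.attributes]
        if len(set(ids)) != len(ids):
            raise SurveyError("attribute ids must be unique within a manifest")
        if len(set(self.respondents)) != len(self.respondents):
            raise SurveyError("respondent ids must be unique")
        known_r = set(self.respondents)
        known_a = set(ids)
        for resp, attr in self.pairs:
            if resp not in known_r:
                raise SurveyError(f"pair references unknown respondent {resp!r}")
            if attr not in known_a:
                raise SurveyError(f"pair references unknown attribute {attr!r}")

    def attribute(self, attribute_id: str) -> AttributeSpec:
        for spec in self.attributes:
            if spec.id == attribute_id or spec.effective_id == attribute_id:
                return spec
        raise SurveyError(f"unknown attribute id {attribute_id!r}")

    def pairs_for(self, attribute_id: str) -> dict[str, ResponsePair]:
        """Non-missing pairs for one attribute, keyed by respondent id."""
        spec = self.attribute(attribute_id)
        return {
            r: p
            for (r, a), p in self.pairs.items()
            if a == spec.id
        }

    def drop_attributes(self, attribute_ids: Iterable[str]) -> "SurveyDataset":
        """Return a copy with the listed attributes removed."""
        drop = set(attribute_ids)
        known = {a.id for a in self.attributes} | {a.effective_id for a in self.attributes}
        unknown = drop - known
        if unknown:
            raise SurveyError(f"unknown attribute ids in drop list: {sorted(unknown)}")
        kept = [
            a for a in self.attributes
            if a.id not in drop and a.effective_id not in drop
        ]
        if len(kept) < 2:
            raise SurveyError("dropping these attributes leaves fewer than 2 items")
        kept_ids = {a.id for a in kept}
        return SurveyDataset(
            respondents=list(self.respondents),
            attributes=kept,
            pairs={k: v for k, v in self.pairs.items() if k[1] in kept_ids},
        )


def classify_pair(pair: ResponsePair) -> KanoCategory:
    """Classify one (functional, dysfunctional) answer pair.

    The mapping is the standard 5x5 assignment grid; e.g. liking the
    attribute's presence while disliking its absence marks the attribute as
    one-dimensional for that respondent, and contradictory answers (liking
    both presence and absence) are questionable.
    """
    return _CLASSIFICATION_GRID[(int(pair.functional), int(pair.dysfunctional))]


def recode_reverse(pair: ResponsePair) -> ResponsePair:
    """Swap functional and dysfunctional answers (analyse the negated attribute).

    Applying the recoding twice returns the original pair.
    """
    return ResponsePair(functional=pair.dysfunctional, dysfunctional=pair.functional)


def tally_attribute(
    dataset: SurveyDataset,
    attribute_id: str,
    apply_reverse: bool | None = None,
) -> CategoryTally:
    """Tally one attribute's pair classifications over all respondents.

    Missing pairs are excluded pairwise, so ``n`` may differ between
    attributes.  ``apply_reverse=None`` follows the manifest's
    ``reverse_recoded`` flag; passing True/False overrides it.
    """
    spec = dataset.attribute(attribute_id)
    if apply_reverse is None:
        apply_reverse = spec.reverse_recoded
    pairs = dataset.pairs_for(spec.id).values()
    if not pairs:
        raise SurveyError(f"attribute {attribute_id!r} has no non-missing pairs")
    if apply_reverse:
        pairs = [recode_reverse(p) for p in pairs]
    return CategoryTally.from_pairs(pairs)


def tally_all(dataset: SurveyDataset) -> dict[str, CategoryTally]:
    """Tally every attribute, keyed by effective id (reverse recoding applied)."""
    return {
        spec.effective_id: tally_attribute(dataset, spec.id)
        for spec in dataset.attributes
    }
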