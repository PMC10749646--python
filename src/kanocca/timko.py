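"""Timko better/worse importance coefficients and the quadrant plot.

The *better* coefficient, (A + O) / (A + O + M + I), estimates how much
end-user satisfaction rises when an attribute is provided; the *worse*
coefficient, (O + M) / (A + O + M + I), how much satisfaction falls when it
is not.  Reverse and questionable answers are excluded from both.  Both
coefficients live in [0, 1]; worse is reported as a magnitude (no negative
sign).  Plotting worse (x) against better (y) splits attributes into four
quadrants at 0.5: attractive (top left), one-dimensional (top right),
must-be (bottom right) and indifferent (bottom left).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .survey import CategoryTally, KanoCategory, SurveyDataset, tally_all

__all__ = [
    "Quadrant",
    "TimkoPoint",
    "UndefinedCoefficientError",
    "better_coefficient",
    "worse_coefficient",
    "quadrant_of",
    "coefficient_table",
]

_A = KanoCategory.ATTRACTIVE
_O = KanoCategory.ONE_DIMENSIONAL
_M = KanoCategory.MUST_BE
_I = KanoCategory.INDIFFERENT


class Quadrant(str, Enum):
    ATTRACTIVE_TOPLEFT = "attractive_topleft"
    ONE_DIMENSIONAL_TOPRIGHT = "one_dimensional_topright"
    MUST_BE_BOTTOMRIGHT = "must_be_bottomright"
    INDIFFERENT_BOTTOMLEFT = "indifferent_bottomleft"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class UndefinedCoefficientError(ValueError):
    """All responses are reverse/questionable; coefficients are undefined."""


def _denominator(tally: CategoryTally) -> int:
    denom = tally[_A] + tally[_O] + tally[_M] + tally[_I]
    if denom == 0:
        raise UndefinedCoefficientError(
            "better/worse are undefined when all responses are R or Q"
        )
    return denom


def better_coefficient(tally: CategoryTally) -> float:
    """(A + O) / (A + O + M + I): satisfaction gain from providing the attribute."""
    return (tally[_A] + tally[_O]) / _denominator(tally)


def worse_coefficient(tally: CategoryTally) -> float:
    """(O + M) / (A + O + M + I): satisfaction loss from omitting the attribute."""
    return (tally[_O] + tally[_M]) / _denominator(tally)


def quadrant_of(better: float, worse: float) -> Quadrant:
    """Quadrant of the (worse, better) plane, split strictly at 0.5.

    Coordinates exactly at 0.5 fall to the lower/left side; callers should
    surface such boundary cases (see :class:`TimkoPoint.on_boundary`).
    """
    for v, name in ((better, "better"), (worse, "worse")):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} coefficient must be in [0, 1], got {v}")
    if better > 0.5:
        return (
            Quadrant.ONE_DIMENSIONAL_TOPRIGHT
            if worse > 0.5
            else Quadrant.ATTRACTIVE_TOPLEFT
        )
    return (
        Quadrant.MUST_BE_BOTTOMRIGHT if worse > 0.5 else Quadrant.INDIFFERENT_BOTTOMLEFT
    )


@dataclass
class TimkoPoint:
    """One attribute's importance coefficients and quadrant placement.

    ``better``/``worse``/``quadrant`` are None for attributes whose responses
    were entirely reverse/questionable (undefined coefficients are exported
    as explicit markers, never as zero).  ``on_boundary`` flags coefficients
    lying exactly on a 0.5 split, where the quadrant is a convention rather
    than a finding.
    """

    attribute_id: str
    better: float | None
    worse: float | None
    quadrant: Quadrant | None
    on_boundary: bool = False


def _point(attribute_id: str, tally: CategoryTally) -> TimkoPoint:
    better = better_coefficient(tally)
    worse = worse_coefficient(tally)
    return TimkoPoint(
        attribute_id=attribute_id,
        better=better,
        worse=worse,
        quadrant=quadrant_of(better, worse),
        on_boundary=(better == 0.5 or worse == 0.5),
    )


def coefficient_table(
    dataset_or_tallies: SurveyDataset | dict[str, CategoryTally],
    on_undefined: str = "raise",
) -> list[TimkoPoint]:
    """Compute one :class:`TimkoPoint` per attribute.

    Parameters
    ----------
    dataset_or_tallies
        Either a :class:`SurveyDataset` (tallied with reverse recoding per
        the manifest) or precomputed tallies keyed by attribute id.
    on_undefined
        ``"raise"`` re-raises undefined-coefficient errors naming the
        attribute; ``"mark"`` emits a point with None coefficients instead.
    """
    if on_undefined not in ("raise", "mark"):
        raise ValueError("on_undefined must be 'raise' or 'mark'")
    tallies = (
        tally_all(dataset_or_tallies)
        if isinstance(dataset_or_tallies, SurveyDataset)
        else dataset_or_tallies
    )
    points: list[TimkoPoint] = []
    for attr_id, tally in tallies.items():
        try:
            points.append(_point(attr_id, tally))
        except UndefinedCoefficientError as exc:
            if on_undefined == "raise":
                raise UndefinedCoefficientError(
                    f"attribute {attr_id!r}: {exc}"
                ) from exc
            points.append(TimkoPoint(attr_id, None, None, None))
    return points
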