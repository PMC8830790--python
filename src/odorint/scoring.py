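"""Plate-assay scoring: choice indices, choice classification, integration index.

A two-sided chemotaxis plate carries an odor spot on one side and a buffer
control on the other.  After one hour the worms on the plate are counted in
three areas: the strip containing the odor ("toward"), the opposite strip
("away"), and the middle strip.  The choice index (CI) is the signed fraction

    CI = (n_toward - n_away) / N

with N the total worm count (all three areas by default).  CI = +1 means all
worms reached the odor side, CI = -1 all worms avoided it.

The integration index quantifies how completely a repellent blocks an
attractant when the two odorants are paired on the same side:

    I = 100 * (CI_pairing - CI_attractant) / (CI_repellent - CI_attractant)

I = 0% means pairing behaves like the attractant alone (no blocking);
I = 100% means pairing behaves like the repellent alone (complete blocking).
The formula is unbounded and values outside [0, 100] are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Literal, Sequence

__all__ = [
    "AssayType",
    "PlateCount",
    "ChoiceSummary",
    "IntegrationInputs",
    "IntegrationResult",
    "choice_index",
    "classify_choices",
    "integration_index",
    "group_integration",
    "UndefinedIndexError",
    "EmptyPlateError",
]

AssayType = Literal["attractant", "repellent", "pairing"]
ASSAY_TYPES: tuple[str, ...] = ("attractant", "repellent", "pairing")

#: assays in which the odor side is the *correct* destination
_TOWARD_CORRECT = {"attractant": True, "repellent": False, "pairing": False}


class EmptyPlateError(ValueError):
    """Raised when a plate has no scored worms."""


class UndefinedIndexError(ZeroDivisionError):
    """Raised when CI_repellent and CI_attractant are indistinguishable."""


@dataclass(frozen=True)
class PlateCount:
    """Worm counts for one assay plate.

    ``n_toward`` counts worms in the odor-side area, ``n_away`` worms in the
    control-side area, ``n_middle`` worms in between.
    """

    plate_id: str
    genotype: str
    assay_type: str
    n_toward: int
    n_away: int
    n_middle: int

    def __post_init__(self) -> None:
        for name in ("n_toward", "n_away", "n_middle"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(
                f"unknown assay_type {self.assay_type!r}; expected one of {ASSAY_TYPES}"
            )

    @property
    def total(self) -> int:
        return self.n_toward + self.n_away + self.n_middle


@dataclass(frozen=True)
class ChoiceSummary:
    """Percentage breakdown of the choices made on one plate."""

    choice_index: float
    pct_correct: float
    pct_wrong: float
    pct_no_choice: float
    pct_incorrect: float


@dataclass(frozen=True)
class IntegrationInputs:
    ci_attractant: float
    ci_repellent: float
    ci_pairing: float


@dataclass(frozen=True)
class IntegrationResult:
    integration_index_pct: float
    per_plate_values: list[float] = field(default_factory=list)
    median_pct: float = float("nan")


def choice_index(counts: PlateCount, denominator: str = "all") -> float:
    """Choice index of one plate.

    Parameters
    ----------
    counts
        Worm counts for the plate.
    denominator
        ``"all"`` (default) divides by all counted worms including the middle
        area; ``"decided_only"`` divides by toward + away only.
    """
    if counts.total == 0:
        raise EmptyPlateError(f"plate {counts.plate_id}: no worms counted")
    if denominator == "all":
        denom = counts.total
    elif denominator == "decided_only":
        denom = counts.n_toward + counts.n_away
        if denom == 0:
            raise EmptyPlateError(
                f"plate {counts.plate_id}: no worms outside the middle area"
            )
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    return (counts.n_toward - counts.n_away) / denom


def classify_choices(
    counts: PlateCount, assay_type: str | None = None, denominator: str = "all"
) -> ChoiceSummary:
    """Classify the worms on a plate as correct / wrong / no choice.

    In an attractant assay moving to the odor side is the correct choice; in
    repellent and pairing assays the odor side is the wrong choice (the odor,
    or the mixture containing it, should be avoided).  Middle-area worms made
    no choice.  The incorrect-choice percentage is the sum of wrong and
    no-choice percentages.
    """
    atype = assay_type if assay_type is not None else counts.assay_type
    if atype not in _TOWARD_CORRECT:
        raise ValueError(f"unknown assay_type {atype!r}")
    total = counts.total
    if total == 0:
        raise EmptyPlateError(f"plate {counts.plate_id}: no worms counted")
    if _TOWARD_CORRECT[atype]:
        n_correct, n_wrong = counts.n_toward, counts.n_away
    else:
        n_correct, n_wrong = counts.n_away, counts.n_toward
    pct_correct = 100.0 * n_correct / total
    pct_wrong = 100.0 * n_wrong / total
    pct_no = 100.0 * counts.n_middle / total
    return ChoiceSummary(
        choice_index=choice_index(counts, denominator=denominator),
        pct_correct=pct_correct,
        pct_wrong=pct_wrong,
        pct_no_choice=pct_no,
        pct_incorrect=pct_wrong + pct_no,
    )


def integration_index(inputs: IntegrationInputs, tolerance: float = 1e-6) -> float:
    """Integration index in percent.

    Requires the repellent and attractant choice indices to differ by more
    than ``tolerance``; otherwise the ratio is undefined (the two single
    odorants are behaviorally indistinguishable and blocking cannot be
    expressed relative to their difference).
    """
    denom = inputs.ci_repellent - inputs.ci_attractant
    if abs(denom) <= tolerance:
        raise UndefinedIndexError(
            "integration index undefined: CI_repellent and CI_attractant differ "
            f"by {denom!r} (<= tolerance {tolerance})"
        )
    return 100.0 * (inputs.ci_pairing - inputs.ci_attractant) / denom


def group_integration(
    att_plates: Sequence[PlateCount],
    rep_plates: Sequence[PlateCount],
    pair_plates: Sequence[PlateCount],
    mode: str = "per_plate",
    tolerance: float = 1e-6,
    denominator: str = "all",
) -> IntegrationResult:
    """Integration index for groups of plates.

    ``mode="per_plate"`` computes one index per pairing plate against the
    group-mean attractant and repellent CIs, reporting the per-plate list and
    its median; ``mode="point"`` evaluates the formula once on the three group
    means.  Both modes carry the per-plate list for plotting.
    """
    if not (att_plates and rep_plates and pair_plates):
        raise ValueError("each plate group must be nonempty")
    if mode not in ("per_plate", "point"):
        raise ValueError(f"unknown aggregation mode {mode!r}")

    def _mean_ci(plates: Sequence[PlateCount]) -> float:
        return sum(choice_index(p, denominator) for p in plates) / len(plates)

    ci_att = _mean_ci(att_plates)
    ci_rep = _mean_ci(rep_plates)
    per_plate = [
        integration_index(
            IntegrationInputs(ci_att, ci_rep, choice_index(p, denominator)), tolerance
        )
        for p in pair_plates
    ]
    med = median(per_plate)
    if mode == "per_plate":
        value = med
    else:
        value = integration_index(
            IntegrationInputs(ci_att, ci_rep, _mean_ci(pair_plates)), tolerance
        )
    return IntegrationResult(
        integration_index_pct=value, per_plate_values=per_plate, median_pct=med
    )
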