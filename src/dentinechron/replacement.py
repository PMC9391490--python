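"""Tooth-family chronology: replacement rates, longevity, and estimators
for replacement teeth lost before burial.

The replacement rate of a tooth position is the age (in days of dentine
growth) of the functional tooth at the moment its replacement tooth began
depositing dentine — i.e. the functional tooth's total line count minus the
replacement tooth's.  When the replacement tooth itself is missing, two
estimators stand in:

* the resorption-pit (RP) estimator — the developing replacement erodes a
  pit into the functional tooth base whose height tracks the replacement
  crown; the lost crown's height is taken as two-thirds of the RP height
  and overlaid on the functional tooth's exterior edge to count the lines
  it encompasses from the apex down;
* the dentine-extent estimator — the replacement's radial dentine extent
  divided by the functional tooth's mean daily line width.

If neither a replacement tooth nor a resorption pit is present, only a
lower bound is available: the functional tooth's own age, flagged as a
minimum.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from statistics import fmean

import numpy as np

from ._util import round_half_up
from .errors import (
    InconsistentFamilyError,
    InvalidInputError,
    InvalidMeasurementError,
    MissingProfileError,
)

#: Fraction of resorption-pit height taken as the lost replacement crown height.
RP_HEIGHT_FRACTION = 2.0 / 3.0


class JawElement(enum.Enum):
    MAXILLA = "maxilla"
    DENTARY = "dentary"
    PREMAXILLA = "premaxilla"


class EstimationMethod(enum.Enum):
    DIRECT = "direct"
    RP_HEIGHT = "rp_height"
    DENTINE_EXTENT = "dentine_extent"
    MINIMUM = "minimum"


@dataclass(frozen=True)
class ToothRecord:
    """One tooth's chronology and measurements.

    ``age_is_minimum`` marks teeth whose crown apex is missing, so the line
    count (and thus the age) is a lower bound.  ``crown_height`` is the
    morphological tooth-height measurement; ``rp_height`` the height of the
    resorption pit eroded by a (possibly lost) replacement tooth.
    """

    taxon: str
    specimen_id: str
    element: JawElement
    position_label: str
    age_days: int
    age_is_minimum: bool = False
    crown_height: float | None = None
    rp_height: float | None = None
    ankylosed: bool = False
    shed: bool = False

    def __post_init__(self) -> None:
        if self.age_days < 0:
            raise InvalidInputError(f"{self.position_label}: age_days must be >= 0")
        if self.rp_height is not None and self.rp_height < 0:
            raise InvalidMeasurementError(
                f"{self.position_label}: rp_height must be >= 0"
            )
        if self.shed and self.ankylosed:
            raise InvalidInputError(
                f"{self.position_label}: a shed tooth cannot be ankylosed"
            )


@dataclass(frozen=True)
class ToothFamily:
    """A functional tooth plus its replacement tooth/teeth at one position.

    Replacements are ordered oldest first (the immediate successor) to
    youngest last; every replacement is younger than the functional tooth.
    """

    functional: ToothRecord
    replacements: tuple[ToothRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "replacements", tuple(self.replacements))
        ages = [r.age_days for r in self.replacements]
        if any(a >= self.functional.age_days for a in ages):
            raise InconsistentFamilyError(
                f"{self.functional.position_label}: replacement at least as old "
                "as the functional tooth"
            )
        if any(a <= b for a, b in zip(ages, ages[1:])):
            raise InconsistentFamilyError(
                f"{self.functional.position_label}: replacements must be strictly "
                "decreasing in age (oldest first)"
            )


@dataclass(frozen=True)
class ApexProfile:
    """Cumulative crown height at each line, counted down from the apex.

    Entry ``i`` is the height in µm from the crown apex along the exterior
    edge at the ``(i+1)``-th increment line.  Monotone non-decreasing.
    """

    cumulative_heights: tuple[float, ...]

    def __post_init__(self) -> None:
        h = np.asarray(self.cumulative_heights, dtype=float)
        object.__setattr__(self, "cumulative_heights", tuple(h.tolist()))
        if h.size and (h[0] < 0 or np.any(np.diff(h) < 0)):
            raise InvalidInputError(
                "cumulative heights must be non-negative and non-decreasing"
            )

    def __len__(self) -> int:
        return len(self.cumulative_heights)


@dataclass(frozen=True)
class ReplacementEstimate:
    """A replacement-rate estimate with its method and minimum flag."""

    rate_days: int
    method: EstimationMethod
    is_minimum: bool
    replacement_age_used: int

    def __post_init__(self) -> None:
        if self.rate_days < 0:
            raise InvalidInputError("rate_days must be >= 0")
        if self.method is EstimationMethod.MINIMUM and not self.is_minimum:
            raise InvalidInputError("method=minimum implies is_minimum")


def replacement_rate_direct(
    functional_age: int, replacement_age: int, *, is_minimum: bool = False
) -> ReplacementEstimate:
    """Rate by direct subtraction of two measured line counts."""
    if not functional_age > replacement_age >= 0:
        raise InconsistentFamilyError(
            f"need functional_age > replacement_age >= 0, got "
            f"({functional_age}, {replacement_age})"
        )
    return ReplacementEstimate(
        rate_days=functional_age - replacement_age,
        method=EstimationMethod.DIRECT,
        is_minimum=is_minimum,
        replacement_age_used=replacement_age,
    )


def estimated_replacement_height(rp_height: float) -> float:
    """Lost replacement crown height: two-thirds of the resorption-pit height."""
    if rp_height < 0:
        raise InvalidMeasurementError(f"rp_height must be >= 0, got {rp_height}")
    return RP_HEIGHT_FRACTION * rp_height


def count_lines_from_apex(profile: ApexProfile, height: float) -> int:
    """Lines within `height` µm of the apex, inclusive at exact equality."""
    if height < 0:
        raise InvalidMeasurementError(f"height must be >= 0, got {height}")
    h = np.asarray(profile.cumulative_heights)
    return int(np.searchsorted(h, height, side="right"))


def estimate_missing_replacement_age(profile: ApexProfile, rp_height: float) -> int:
    """Age in days of a lost replacement tooth from its resorption pit.

    The estimated crown height (two-thirds of the RP height) is overlaid on
    the functional tooth's exterior edge and the lines it encompasses from
    the apex are counted — each encompassed line is one day the replacement
    had been growing.
    """
    return count_lines_from_apex(profile, estimated_replacement_height(rp_height))


def dentine_extent_age(radial_extent: float, mean_width: float) -> int:
    """Age from total radial dentine extent divided by mean daily width."""
    if radial_extent <= 0 or mean_width <= 0:
        raise InvalidMeasurementError(
            f"radial_extent and mean_width must be > 0, got "
            f"({radial_extent}, {mean_width})"
        )
    return round_half_up(radial_extent / mean_width)


def replacement_rate_for_family(
    family: ToothFamily, profile: ApexProfile | None = None
) -> ReplacementEstimate:
    """Best available replacement-rate estimate for one tooth family.

    Dispatch: a preserved replacement tooth gives the direct subtraction
    (against the oldest, i.e. immediate, replacement); otherwise a
    resorption pit plus an apex profile gives the RP-height estimate;
    otherwise only the minimum-rate lower bound (the functional tooth's own
    age) is returned.  The minimum flag is also propagated whenever the
    functional tooth's age is itself a minimum.
    """
    func = family.functional
    if family.replacements:
        immediate = family.replacements[0]
        return replacement_rate_direct(
            func.age_days, immediate.age_days, is_minimum=func.age_is_minimum
        )
    if func.rp_height is not None:
        if profile is None:
            raise MissingProfileError(
                f"{func.position_label}: rp_height present but no apex profile"
            )
        repl_age = estimate_missing_replacement_age(profile, func.rp_height)
        return ReplacementEstimate(
            rate_days=func.age_days - repl_age,
            method=EstimationMethod.RP_HEIGHT,
            is_minimum=func.age_is_minimum,
            replacement_age_used=repl_age,
        )
    return ReplacementEstimate(
        rate_days=func.age_days,
        method=EstimationMethod.MINIMUM,
        is_minimum=True,
        replacement_age_used=0,
    )


def functional_period(shed_age: int, attachment_ages: list[int]) -> int:
    """Mean functional lifespan: shedding age minus mean attachment age.

    Attachment is dated by ankylosis; several attachment-stage teeth may be
    averaged against one shed tooth.
    """
    if not attachment_ages:
        raise InvalidInputError("attachment_ages must be non-empty")
    if any(shed_age <= a for a in attachment_ages):
        raise InvalidInputError("shed_age must exceed every attachment age")
    return round_half_up(shed_age - fmean(attachment_ages))


def tooth_longevity(family: ToothFamily) -> tuple[int, bool]:
    """Longevity in days of the functional tooth, with its minimum flag."""
    return family.functional.age_days, family.functional.age_is_minimum
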