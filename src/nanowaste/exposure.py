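"""Qualitative exposure rating (Step 5).

Data on release mechanisms are too scarce for quantitative exposure
concentrations, so potential exposure is rated on an ordinal low/medium/high
scale from four factors: the amount of the nanoproduct on the market, the
magnitude of the emission after controls, the proximity of human/ecosystem
receptors to the treatment facility, and the duration of the emission
(frequency is folded into duration, since treatment facilities run
continuously for long periods).

The combination rule is deliberately simple and fully auditable: factors map
to 1/2/3, the arithmetic mean is taken, and half-values round *up*
(precautionary).  The rule and the per-case factor assignments are package
design choices — the underlying assessments are narrative — so every rating
carries its full factor trace and the rubric can be swapped out by the user.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "ExposureLevel",
    "ExposureFactors",
    "ExposureRating",
    "score_exposure",
]


class ExposureLevel(str, enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


_ORDINAL = {ExposureLevel.LOW: 1, ExposureLevel.MEDIUM: 2, ExposureLevel.HIGH: 3}
_LEVEL = {v: k for k, v in _ORDINAL.items()}

FACTOR_NAMES = (
    "amount_on_market",
    "emission_magnitude",
    "receptor_proximity",
    "duration",
)


@dataclass(frozen=True)
class ExposureFactors:
    """The four ordinal drivers of potential exposure."""

    amount_on_market: ExposureLevel
    emission_magnitude: ExposureLevel  # post-control
    receptor_proximity: ExposureLevel
    duration: ExposureLevel
    notes: str = ""

    def __post_init__(self) -> None:
        for name in FACTOR_NAMES:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"exposure factor {name!r} is not set")
            object.__setattr__(self, name, ExposureLevel(value))

    def ordinals(self) -> tuple[int, int, int, int]:
        return tuple(_ORDINAL[getattr(self, name)] for name in FACTOR_NAMES)


@dataclass(frozen=True)
class ExposureRating:
    """An exposure level with its full factor trace and rationale."""

    level: ExposureLevel
    factors: ExposureFactors
    mean_score: float
    rule: str
    narrative: str = ""


def score_exposure(factors: ExposureFactors, narrative: str = "") -> ExposureRating:
    """Combine the four factors into a low/medium/high rating.

    Level = round(mean of the four ordinals), with exact halves rounded up:
    a mean of 1.5 rates medium, 2.5 rates high.  Deterministic and monotone —
    raising any single factor never lowers the rating.
    """
    scores = factors.ordinals()
    mean = sum(scores) / len(scores)
    # round-half-up on a scale of quarters: floor(mean + 0.5) is exact here
    level_score = int(mean + 0.5)
    return ExposureRating(
        level=_LEVEL[level_score],
        factors=factors,
        mean_score=mean,
        rule="round-half-up arithmetic mean of 4 ordinal factors",
        narrative=narrative,
    )
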