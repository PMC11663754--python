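"""Criterion schemes for additive multi-criteria value models.

A scheme fixes the set of prioritisation criteria and the ordinal
performance levels each criterion can take.  The default scheme is the
eight-criterion, five-level scheme used for endemic-pathogen vaccine
R&D prioritisation: three quantitative burden criteria (deaths in
children under five, deaths in people five and older, years lived with
disability) and five qualitative criteria (social and economic burden
per case, disruption due to outbreaks, contribution to inequity,
contribution to antimicrobial resistance, and unmet needs for
prevention and treatment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

#: Identifiers of the eight default prioritisation criteria, in display order.
DEFAULT_CRITERIA: tuple[str, ...] = (
    "deaths_under5",
    "deaths_over5",
    "ylds",
    "socioeconomic_burden",
    "outbreak_disruption",
    "inequity",
    "amr",
    "unmet_needs",
)

#: Human-readable names for the default criteria.
CRITERION_LABELS: dict[str, str] = {
    "deaths_under5": "Annual deaths in children under 5",
    "deaths_over5": "Annual deaths in people older than 5",
    "ylds": "Years lived with disability (all ages)",
    "socioeconomic_burden": "Social and economic burden per case",
    "outbreak_disruption": "Disruption due to outbreaks",
    "inequity": "Contribution to inequity",
    "amr": "Contribution to antimicrobial resistance",
    "unmet_needs": "Unmet needs for prevention and treatment",
}

#: Criteria scored from quantitative burden data rather than a qualitative rubric.
QUANTITATIVE_CRITERIA: tuple[str, ...] = ("deaths_under5", "deaths_over5", "ylds")

DEFAULT_LEVEL_LABELS: tuple[str, ...] = (
    "Very low",
    "Low",
    "Medium",
    "High",
    "Very high",
)


@dataclass(frozen=True)
class CriterionScheme:
    """An ordered set of criteria, each with the same ordered level scale.

    Levels are 1-based: level 1 is the lowest (worst for prioritisation,
    e.g. "Very low" burden) and ``n_levels`` is the highest.
    """

    criteria: tuple[str, ...] = DEFAULT_CRITERIA
    n_levels: int = 5
    level_labels: tuple[str, ...] = field(default=DEFAULT_LEVEL_LABELS)

    def __post_init__(self) -> None:
        if len(self.criteria) < 2:
            raise ValueError("a scheme needs at least 2 criteria")
        if len(set(self.criteria)) != len(self.criteria):
            raise ValueError("criterion identifiers must be unique")
        if self.n_levels < 2:
            raise ValueError("a scheme needs at least 2 levels per criterion")
        if len(self.level_labels) != self.n_levels:
            # Regenerate generic labels when n_levels differs from the default.
            object.__setattr__(
                self,
                "level_labels",
                tuple(f"Level {i}" for i in range(1, self.n_levels + 1)),
            )
        if len(set(self.level_labels)) != len(self.level_labels):
            raise ValueError("level labels must be unique")
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "level_labels", tuple(self.level_labels))

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    def criterion_index(self, criterion: str) -> int:
        try:
            return self.criteria.index(criterion)
        except ValueError:
            raise KeyError(f"unknown criterion: {criterion!r}") from None

    def validate_level(self, level: int) -> None:
        if not (1 <= int(level) <= self.n_levels):
            raise ValueError(
                f"level {level} outside 1..{self.n_levels}"
            )

    @property
    def medium_level(self) -> int:
        """The middle level (level 3 of 5, 'Medium' on the default scale)."""
        return (self.n_levels + 1) // 2


def make_scheme(criteria: Sequence[str] | None = None, n_levels: int = 5) -> CriterionScheme:
    """Convenience constructor accepting any sequence of criterion names."""
    if criteria is None:
        return CriterionScheme(n_levels=n_levels)
    return CriterionScheme(criteria=tuple(criteria), n_levels=n_levels)
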