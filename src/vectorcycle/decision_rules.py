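"""Programme decision rules mapping indicators to control technologies.

Each available or emerging technology has a human-context condition (do
people sleep indoors, keep livestock, stay out after dark, ...) and an
entomological condition — typically that at least one-third of exposure,
blood meals or livestock meals fall in the behavioural fraction the
technology targets. A technology is recommended exactly when all of its
conditions hold; the rationale strings record which passed and failed.

"At least one-third" is an advisory cut-off and includes the boundary:
the comparison is an exact ``>= 1/3`` with no numerical tolerance. Where
both historical and current values of an indicator are available the more
favourable (maximum) applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from vectorcycle.errors import ValidationError

ONE_THIRD = Fraction(1, 3)


def _check_unit(name: str, value: float) -> float:
    v = float(value)
    if not 0.0 <= v <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    return v


@dataclass(frozen=True)
class IndicatorProfile:
    """Surveyed indicators and human-context flags for one setting.

    ``pi_indoor_exposure_historical`` optionally records a pre-intervention
    measurement; indoor-targeting rules use the maximum of historical and
    current values, since houses that vectors attacked before control can
    be proofed against them again.
    """

    pi_indoor_exposure: float
    q_human: float
    f_livestock_meals: float
    sugar_labelling_positive: bool = False
    swarm_labelling_positive: bool = False
    sleeps_indoors: bool = False
    migrant_shelters: bool = False
    outdoor_night_activity: bool = False
    owns_livestock: bool = False
    pi_indoor_exposure_historical: float | None = None

    def __post_init__(self) -> None:
        for name in ("pi_indoor_exposure", "q_human", "f_livestock_meals"):
            object.__setattr__(self, name, _check_unit(name, getattr(self, name)))
        if self.pi_indoor_exposure_historical is not None:
            object.__setattr__(
                self,
                "pi_indoor_exposure_historical",
                _check_unit(
                    "pi_indoor_exposure_historical", self.pi_indoor_exposure_historical
                ),
            )

    @property
    def pi_indoor_best(self) -> float:
        """Max of historical and current indoor exposure proportions."""
        if self.pi_indoor_exposure_historical is None:
            return self.pi_indoor_exposure
        return max(self.pi_indoor_exposure, self.pi_indoor_exposure_historical)


@dataclass(frozen=True)
class Recommendation:
    technology: str
    triggered: bool
    rationale: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "technology": self.technology,
            "triggered": self.triggered,
            "rationale": list(self.rationale),
        }


def _ge_third(value: float) -> bool:
    # exact comparison against the double nearest 1/3 — no tolerance band,
    # so 1/3 itself triggers and any value strictly below it does not
    return value >= float(ONE_THIRD)


def _cond(label: str, ok: bool) -> tuple[str, bool]:
    return (f"{label}: {'PASS' if ok else 'FAIL'}", ok)


def _row(technology: str, conditions: list[tuple[str, bool]]) -> Recommendation:
    return Recommendation(
        technology=technology,
        triggered=all(ok for _, ok in conditions),
        rationale=tuple(msg for msg, _ in conditions),
    )


TECHNOLOGIES = (
    "housing_proofing",
    "shelter_proofing",
    "entry_traps_eave_devices",
    "treated_clothing_emanators",
    "livestock_insecticide",
    "sugar_baits",
    "swarm_sprays",
)


def recommend(profile: IndicatorProfile) -> list[Recommendation]:
    """Evaluate every technology rule against an indicator profile.

    Returns one :class:`Recommendation` per technology, in the fixed
    order of :data:`TECHNOLOGIES`, each with per-condition rationale.
    """
    indoor = _ge_third(profile.pi_indoor_best)
    outdoor = _ge_third(1.0 - profile.pi_indoor_exposure)
    human = _ge_third(profile.q_human)
    livestock = _ge_third(profile.f_livestock_meals)

    rows = [
        _row(
            "housing_proofing",
            [
                _cond("sleeps indoors", profile.sleeps_indoors),
                _cond(">=1/3 of exposure indoors (historical or current)", indoor),
            ],
        ),
        _row(
            "shelter_proofing",
            [
                _cond("migrant lifestyle, sleeps in shelters", profile.migrant_shelters),
                _cond(">=1/3 of exposure indoors (historical or current)", indoor),
            ],
        ),
        _row(
            "entry_traps_eave_devices",
            [
                _cond(
                    "sleeps indoors or in shelters",
                    profile.sleeps_indoors or profile.migrant_shelters,
                ),
                _cond(">=1/3 of exposure indoors (historical or current)", indoor),
                _cond(">=1/3 of blood meals from humans", human),
            ],
        ),
        _row(
            "treated_clothing_emanators",
            [
                _cond("outdoor activity during hours of darkness", profile.outdoor_night_activity),
                _cond(">=1/3 of current exposure outdoors", outdoor),
            ],
        ),
        _row(
            "livestock_insecticide",
            [
                _cond("owns livestock", profile.owns_livestock),
                _cond(">=1/3 of blood meals from identified livestock", livestock),
            ],
        ),
        _row(
            "sugar_baits",
            [_cond("vectors labelled by dyed sugar baits", profile.sugar_labelling_positive)],
        ),
        _row(
            "swarm_sprays",
            [_cond("vectors labelled in mating swarms", profile.swarm_labelling_positive)],
        ),
    ]
    return rows
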