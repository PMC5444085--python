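"""Sequential intervention stacking and behavioural redistribution.

Interventions are applied one layer at a time; each layer reports the full
cycle outcome for the cumulative stack, how residual blood meals have
redistributed onto untargeted compartments (behavioural resilience — the
instantaneous, plastic response within a cycle, as opposed to heritable
behavioural resistance), and a relative transmission proxy

    T_k = [h_k / (1 - s * S_k)] / [h_0 / (1 - s * S_0)]

where h_k is the probability of feeding on a human during the cycle, S_k
the intervention-attributable per-cycle survival, and s the natural
per-cycle survival from all other causes: h/(1 - s*S) is the expected
number of lifetime human feeds under geometric survival, the minimal
cycle-based stand-in for transmission potential (sporogonic delay
deliberately omitted). Without the natural-mortality factor the baseline
expectation diverges (an unperturbed cycle has S_0 = 1), so s < 1 is what
makes the proxy well defined and T_0 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from vectorcycle.compartments import (
    Compartment,
    HUMAN_COMPARTMENTS,
    INDOOR_COMPARTMENTS,
)
from vectorcycle.errors import (
    TotalBlockadeError,
    UndefinedProfileError,
    ValidationError,
)
from vectorcycle.feeding_cycle import (
    BehaviourProfile,
    CycleOutcome,
    Intervention,
    single_cycle,
)


@dataclass(frozen=True)
class Layer:
    """One layer of a stacking trace."""

    index: int
    added: Intervention | None
    outcome: CycleOutcome
    residual_meals: dict[Compartment, float]
    transmission_relative: float

    def to_dict(self) -> dict:
        return {
            "layer": self.index,
            "added": None if self.added is None else self.added.to_dict(),
            "outcome": self.outcome.to_dict(),
            "residual_meals": {j.value: p for j, p in self.residual_meals.items()},
            "transmission_relative": self.transmission_relative,
        }


@dataclass(frozen=True)
class LayerTrace:
    """Trace of cycle outcomes as interventions are layered on.

    Layer 0 is the unprotected baseline; layer k applies the first k
    interventions of the stack. ``transmission_relative`` is 1 at layer 0
    by construction.
    """

    layers: tuple[Layer, ...]

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, k: int) -> Layer:
        return self.layers[k]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per layer x compartment."""
        rows = []
        for layer in self.layers:
            kind = None if layer.added is None else layer.added.kind.value
            for j, share in layer.residual_meals.items():
                rows.append(
                    {
                        "layer": layer.index,
                        "added": kind,
                        "compartment": j.value,
                        "residual_meal_share": share,
                        "p_fed": layer.outcome.p_fed[j],
                        "p_pre_death": layer.outcome.p_pre_death,
                        "p_cycle_survival": layer.outcome.p_cycle_survival,
                        "e_expected": layer.outcome.e_expected,
                        "transmission_relative": layer.transmission_relative,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {"layers": [layer.to_dict() for layer in self.layers]}


#: Default natural per-cycle survival from causes other than the modelled
#: interventions (predation, senescence, weather); a typical value for
#: African malaria vectors. Must be < 1 for lifetime feed expectations to
#: converge.
DEFAULT_NATURAL_SURVIVAL = 0.85


def _lifetime_human_feeds(outcome: CycleOutcome, natural_survival: float) -> float:
    h = outcome.human_fed_probability()
    s = natural_survival * outcome.p_cycle_survival
    return h / (1.0 - s)


def apply_stack(
    profile: BehaviourProfile,
    stack: list[Intervention] | tuple[Intervention, ...],
    natural_cycle_survival: float = DEFAULT_NATURAL_SURVIVAL,
) -> LayerTrace:
    """Apply interventions cumulatively, one layer at a time.

    Returns a trace of length ``len(stack) + 1``; layer k's outcome is
    ``single_cycle`` on the first k interventions. Errors raised by the
    cycle model are annotated with the offending layer index.
    ``natural_cycle_survival`` is the per-cycle survival from causes other
    than the stacked interventions, used only by the transmission proxy.
    """
    if not 0.0 <= natural_cycle_survival < 1.0:
        raise ValidationError(
            "natural_cycle_survival must lie in [0, 1) for the lifetime "
            f"feed expectation to converge, got {natural_cycle_survival!r}"
        )
    stack = tuple(stack)
    layers: list[Layer] = []
    baseline_t = None
    for k in range(len(stack) + 1):
        try:
            outcome = single_cycle(profile, stack[:k])
        except TotalBlockadeError as exc:
            raise TotalBlockadeError(f"layer {k}: {exc}") from exc
        residual = outcome.residual_meal_distribution()
        t_abs = _lifetime_human_feeds(outcome, natural_cycle_survival)
        if baseline_t is None:
            baseline_t = t_abs
        t_rel = 1.0 if baseline_t == 0.0 else t_abs / baseline_t
        layers.append(
            Layer(
                index=k,
                added=stack[k - 1] if k > 0 else None,
                outcome=outcome,
                residual_meals=residual,
                transmission_relative=t_rel,
            )
        )
    return LayerTrace(layers=tuple(layers))


def remeasure(outcome: CycleOutcome) -> BehaviourProfile:
    """Behaviour profile a field survey would observe after intervention.

    The residual meal distribution implies new values of the human blood
    index, the indoor and in-bed exposure proportions and the livestock
    fraction — what entomological remeasurement would now record. The
    resting and sugar-feeding propensities are innate per-compartment
    traits unchanged by where meals ended up, so they carry over from the
    pre-intervention profile.

    Raises
    ------
    UndefinedProfileError
        If no residual feeding remains.
    """
    if outcome.p_fed_total <= 0.0:
        raise UndefinedProfileError("no residual feeding: profile undefined")
    r = outcome.residual_meal_distribution()
    human = sum(r[j] for j in HUMAN_COMPARTMENTS)
    indoor = sum(r[j] for j in INDOOR_COMPARTMENTS)
    in_bed = r[Compartment.HUMAN_INDOOR_IN_BED]
    animal = r[Compartment.LIVESTOCK] + r[Compartment.OTHER_ANIMAL]
    base = outcome.profile
    return BehaviourProfile(
        q_human=human,
        pi_indoor=indoor / human if human > 0.0 else 0.0,
        pi_in_bed=in_bed / indoor if indoor > 0.0 else 0.0,
        f_livestock=r[Compartment.LIVESTOCK] / animal if animal > 0.0 else base.f_livestock,
        r_indoor_rest=base.r_indoor_rest,
        sugar_rate=base.sugar_rate,
    )
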