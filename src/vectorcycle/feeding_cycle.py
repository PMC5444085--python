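"""Closed-form model of a single gonotrophic (feeding) cycle.

The cycle is treated as an absorbing process over blood-feeding attempts.
Each attempt is directed at one of five behavioural compartments with
baseline weights derived from the population's behaviour profile. An
attempt on a resource covered by an intervention can be killed before the
bite, blocked non-lethally (sending the mosquito on a fresh attempt), or
proceed to a successful feed; uncovered attempts always feed. The process
is absorbed when the mosquito either dies or feeds, which yields closed
forms for the pre-feed death probability, the compartment-wise feeding
probabilities and the expected number of attempts per blood meal. Post-bite
mortality (wall contact while resting indoors after IRS, endectocide-treated
livestock blood, toxic sugar baits, swarm sprays) then compounds as
independent hazards.

Two standalone results of the same model are exposed directly:
``expected_encounters`` — how personal protection of a fraction of hosts
multiplies the encounters a mosquito needs per meal — and
``population_coverage`` — the fraction of the mosquito population exposed
to a house-delivered insecticide at least once per cycle.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field

from vectorcycle.compartments import (
    BLOOD_COMPARTMENTS,
    INDOOR_COMPARTMENTS,
    Compartment,
    Phase,
)
from vectorcycle.errors import TotalBlockadeError, ValidationError

#: Tolerance for probability bounds at API boundaries. Inputs outside
#: [0, 1] by more than this are rejected, never clamped.
ATOL = 1e-9

#: Per-encounter probability that an attack on a protected (net-using,
#: in-bed) host is non-lethally blocked. Calibrated so that 80% net usage
#: doubles the expected encounters per blood meal: 1/(1 - 0.8 * 0.625) = 2.
DEFAULT_NET_BLOCK = 0.625


def _check_fraction(name: str, value: float) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name} must be a number, got {value!r}") from exc
    if not math.isfinite(v) or v < -ATOL or v > 1.0 + ATOL:
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    return min(max(v, 0.0), 1.0)


@dataclass(frozen=True)
class BehaviourProfile:
    """Baseline behavioural fractions of a vector population.

    Parameters
    ----------
    q_human
        Human blood index: fraction of blood meals taken on humans.
    pi_indoor
        Proportion of human exposure occurring indoors in the absence of
        any protection (often written pi_h,i,0).
    pi_in_bed
        Proportion of *indoor* human exposure occurring while hosts are
        in bed.
    f_livestock
        Fraction of non-human meals taken on treatable livestock (the
        rest are on wild animals out of reach of veterinary insecticides).
    r_indoor_rest
        Probability of resting indoors (on sprayable surfaces) after an
        indoor feed.
    sugar_rate
        Probability of taking at least one sugar meal per cycle.
    """

    q_human: float
    pi_indoor: float
    pi_in_bed: float
    f_livestock: float = 0.5
    r_indoor_rest: float = 0.5
    sugar_rate: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            object.__setattr__(
                self, f.name, _check_fraction(f.name, getattr(self, f.name))
            )

    def attempt_weights(self) -> dict[Compartment, float]:
        """Baseline attack-attempt weights over the five compartments.

        Non-negative and summing to one by construction:
        ``(q·πi·πb, q·πi·(1−πb), q·(1−πi), (1−q)·fl, (1−q)·(1−fl))``.
        """
        q, pi, pb, fl = self.q_human, self.pi_indoor, self.pi_in_bed, self.f_livestock
        return {
            Compartment.HUMAN_INDOOR_IN_BED: q * pi * pb,
            Compartment.HUMAN_INDOOR_OUT_OF_BED: q * pi * (1.0 - pb),
            Compartment.HUMAN_OUTDOOR: q * (1.0 - pi),
            Compartment.LIVESTOCK: (1.0 - q) * fl,
            Compartment.OTHER_ANIMAL: (1.0 - q) * (1.0 - fl),
        }

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


class InterventionKind(str, enum.Enum):
    LLIN = "LLIN"
    IRS = "IRS"
    SCREENING = "SCREENING"
    EAVE_DEVICE = "EAVE_DEVICE"
    TREATED_CLOTHING = "TREATED_CLOTHING"
    EMANATOR = "EMANATOR"
    LIVESTOCK_INSECTICIDE = "LIVESTOCK_INSECTICIDE"
    SUGAR_BAIT = "SUGAR_BAIT"
    SWARM_SPRAY = "SWARM_SPRAY"


Target = Compartment | Phase

#: Compartments/phases each technology is allowed to act on. A bed net
#: only reaches hosts in bed; screening and eave devices guard house entry
#: (both indoor compartments); clothing and emanators protect people
#: outdoors; endectocides reach mosquitoes through treated livestock blood.
ALLOWED_TARGETS: dict[InterventionKind, frozenset[Target]] = {
    InterventionKind.LLIN: frozenset({Compartment.HUMAN_INDOOR_IN_BED}),
    InterventionKind.IRS: frozenset(INDOOR_COMPARTMENTS),
    InterventionKind.SCREENING: frozenset(INDOOR_COMPARTMENTS),
    InterventionKind.EAVE_DEVICE: frozenset(INDOOR_COMPARTMENTS),
    InterventionKind.TREATED_CLOTHING: frozenset({Compartment.HUMAN_OUTDOOR}),
    InterventionKind.EMANATOR: frozenset({Compartment.HUMAN_OUTDOOR}),
    InterventionKind.LIVESTOCK_INSECTICIDE: frozenset({Compartment.LIVESTOCK}),
    InterventionKind.SUGAR_BAIT: frozenset({Phase.SUGAR}),
    InterventionKind.SWARM_SPRAY: frozenset({Phase.SWARM}),
}


@dataclass(frozen=True)
class Intervention:
    """One control technology in a stack.

    ``coverage`` is the fraction of the targeted resource that is covered
    (net usage U_h for LLINs, house coverage C_h for IRS/screening/eave
    devices, the treated fraction of livestock, ...). ``pre_kill`` and
    ``block`` act per attack on a covered resource, before the bite;
    ``post_kill`` acts after a successful feed at (or rest in) a covered
    resource.
    """

    kind: InterventionKind
    coverage: float
    pre_kill: float = 0.0
    block: float = 0.0
    post_kill: float = 0.0
    targets: frozenset[Target] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        kind = InterventionKind(self.kind)
        object.__setattr__(self, "kind", kind)
        for name in ("coverage", "pre_kill", "block", "post_kill"):
            object.__setattr__(self, name, _check_fraction(name, getattr(self, name)))
        if self.pre_kill + self.block > 1.0 + ATOL:
            raise ValidationError(
                f"pre_kill + block must not exceed 1 "
                f"(got {self.pre_kill} + {self.block})"
            )
        allowed = ALLOWED_TARGETS[kind]
        targets = frozenset(self.targets) or allowed
        if not targets <= allowed:
            bad = {getattr(t, "value", t) for t in targets - allowed}
            raise ValidationError(f"targets {sorted(bad)} not valid for kind {kind.value}")
        object.__setattr__(self, "targets", targets)

    @property
    def blood_targets(self) -> frozenset[Compartment]:
        return frozenset(t for t in self.targets if isinstance(t, Compartment))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "coverage": self.coverage,
            "pre_kill": self.pre_kill,
            "block": self.block,
            "post_kill": self.post_kill,
            "targets": sorted(t.value for t in self.targets),
        }


@dataclass(frozen=True)
class EncounterModel:
    """Host-availability view of personal protection.

    A fraction ``u`` of a host class is protected; an attack on a
    protected host is non-lethally blocked with per-encounter probability
    ``b``. The relative availability of that host class's blood is then
    ``z_relative = 1 − u·b`` and a mosquito needs ``e_expected = 1 /
    z_relative`` encounters (equivalently, house entries) per blood meal.
    """

    u: float
    b: float
    z_relative: float
    e_expected: float


def expected_encounters(u: float, b: float = DEFAULT_NET_BLOCK) -> EncounterModel:
    """Expected encounters per blood meal under partial personal protection.

    Parameters
    ----------
    u
        Usage/coverage of the protection among the host class, in [0, 1].
    b
        Per-encounter probability that an attack on a protected host is
        non-lethally blocked. The default is calibrated so that 80% net
        usage doubles the encounters needed per meal.

    Raises
    ------
    TotalBlockadeError
        If ``u·b >= 1``: every encounter is blocked and no feeding is
        possible.
    """
    u = _check_fraction("u", u)
    b = _check_fraction("b", b)
    z = 1.0 - u * b
    if z <= ATOL:
        raise TotalBlockadeError(
            f"u*b = {u * b:g} leaves no available blood: total blockade"
        )
    return EncounterModel(u=u, b=b, z_relative=z, e_expected=1.0 / z)


def population_coverage(
    c_h: float, profile: BehaviourProfile, e: float = 1.0
) -> float:
    """Mosquito population coverage of a house-delivered insecticide.

    The probability that a mosquito is exposed to the insecticide at least
    once per feeding cycle, when a fraction ``c_h`` of houses is covered,
    a fraction ``pi_indoor`` of human attacks would occur indoors absent
    protection, and each meal requires ``e`` independent house entries:

        C_M = q_human * (1 - (1 - pi_indoor * c_h) ** e)

    At ``e = 1`` this is the simple product ``q_human * pi_indoor * c_h``;
    net-induced repeat house entry (``e > 1``) amplifies it.
    """
    c_h = _check_fraction("c_h", c_h)
    if not isinstance(profile, BehaviourProfile):
        raise ValidationError("profile must be a BehaviourProfile")
    e = float(e)
    if not math.isfinite(e) or e < 1.0 - ATOL:
        raise ValidationError(f"e must be >= 1, got {e!r}")
    return profile.q_human * (1.0 - (1.0 - profile.pi_indoor * c_h) ** e)


@dataclass(frozen=True)
class CycleOutcome:
    """Closed-form fates of one feeding cycle.

    Attributes
    ----------
    p_pre_death
        Probability of dying before feeding (absorbed by a pre-bite kill).
    p_fed
        Per-compartment probability of feeding there; together with
        ``p_pre_death`` these sum to one.
    p_post_death
        Probability of dying between the feed and the next cycle, given fed.
    p_cycle_survival
        Probability of completing the cycle alive having fed.
    e_expected
        Expected attack attempts per blood meal.
    c_m
        Per-intervention population coverage: probability of >= 1 encounter
        with that intervention during the cycle, in stack order.
    profile
        The behaviour profile the cycle was computed for.
    interventions
        The intervention stack applied.
    """

    p_pre_death: float
    p_fed: dict[Compartment, float]
    p_post_death: float
    p_cycle_survival: float
    e_expected: float
    c_m: tuple[float, ...]
    profile: BehaviourProfile
    interventions: tuple[Intervention, ...]

    @property
    def p_fed_total(self) -> float:
        return sum(self.p_fed.values())

    def residual_meal_distribution(self) -> dict[Compartment, float]:
        """The p_fed renormalised over mosquitoes that did feed."""
        total = self.p_fed_total
        if total <= 0.0:
            raise ValidationError("no residual feeding: distribution undefined")
        return {j: p / total for j, p in self.p_fed.items()}

    def human_fed_probability(self) -> float:
        return (
            self.p_fed[Compartment.HUMAN_INDOOR_IN_BED]
            + self.p_fed[Compartment.HUMAN_INDOOR_OUT_OF_BED]
            + self.p_fed[Compartment.HUMAN_OUTDOOR]
        )

    def to_dict(self) -> dict:
        return {
            "p_pre_death": self.p_pre_death,
            "p_fed": {j.value: p for j, p in self.p_fed.items()},
            "p_post_death": self.p_post_death,
            "p_cycle_survival": self.p_cycle_survival,
            "e_expected": self.e_expected,
            "c_m": list(self.c_m),
        }


def _attack_fates(
    weights: dict[Compartment, float], interventions: tuple[Intervention, ...]
) -> tuple[float, float, dict[Compartment, float]]:
    """Per-attempt kill/block/feed masses (K, B, F_j).

    Multiple interventions guarding one compartment compound as independent
    per-attempt hazards met in stack order: an attack passes the first
    layer before it can meet the second.
    """
    K = 0.0
    B = 0.0
    F: dict[Compartment, float] = {}
    for j, a_j in weights.items():
        passing = 1.0
        kill_j = 0.0
        block_j = 0.0
        for iv in interventions:
            if j not in iv.blood_targets:
                continue
            met = iv.coverage
            kill_j += passing * met * iv.pre_kill
            block_j += passing * met * iv.block
            passing *= 1.0 - met * (iv.pre_kill + iv.block)
        K += a_j * kill_j
        B += a_j * block_j
        F[j] = a_j * passing
    return K, B, F


def single_cycle(
    profile: BehaviourProfile,
    interventions: list[Intervention] | tuple[Intervention, ...] = (),
) -> CycleOutcome:
    """Solve one feeding cycle against an ordered intervention stack.

    Per attempt, compartment ``j`` is drawn with its baseline weight; an
    attack on a covered resource is killed pre-bite, blocked (diverted to
    a fresh attempt), or proceeds; uncovered attacks feed. With per-attempt
    masses ``K`` (killed), ``B`` (blocked) and ``F_j`` (fed in j), the
    absorbing process gives::

        p_pre_death = K / (K + sum F),  p_fed[j] = F_j / (K + sum F),
        e_expected  = 1 / (1 - B).

    Post-bite mortality compounds independent hazards: IRS wall contact
    for the indoor-resting fraction of indoor feeds, endectocide-treated
    blood for livestock feeds, toxic sugar baits and swarm sprays for all
    survivors.

    Raises
    ------
    TotalBlockadeError
        If per-attempt blocking mass reaches 1 (endless diversion).
    """
    if not isinstance(profile, BehaviourProfile):
        raise ValidationError("profile must be a BehaviourProfile")
    stack = tuple(
        iv if isinstance(iv, Intervention) else Intervention(**iv)
        for iv in interventions
    )
    weights = profile.attempt_weights()

    K, B, F = _attack_fates(weights, stack)
    absorbed = K + sum(F.values())  # equals 1 - B
    if absorbed <= ATOL:
        raise TotalBlockadeError(
            "all attacks are blocked non-lethally: no feeding possible"
        )
    p_pre_death = K / absorbed
    p_fed = {j: F_j / absorbed for j, F_j in F.items()}
    e_expected = 1.0 / (1.0 - B)

    # Post-bite hazards, conditional on having fed in compartment j.
    fed_total = sum(p_fed.values())
    survive_j = {j: 1.0 for j in weights}
    global_survive = 1.0
    for iv in stack:
        if iv.post_kill <= 0.0:
            continue
        if iv.kind is InterventionKind.SUGAR_BAIT:
            global_survive *= 1.0 - profile.sugar_rate * iv.coverage * iv.post_kill
        elif iv.kind is InterventionKind.SWARM_SPRAY:
            global_survive *= 1.0 - iv.coverage * iv.post_kill
        elif iv.kind is InterventionKind.IRS:
            # only mosquitoes that rest indoors contact sprayed walls
            for j in iv.blood_targets:
                survive_j[j] *= 1.0 - profile.r_indoor_rest * iv.coverage * iv.post_kill
        else:
            for j in iv.blood_targets:
                survive_j[j] *= 1.0 - iv.coverage * iv.post_kill
    if fed_total > 0.0:
        p_survive_post = (
            sum(p_fed[j] * survive_j[j] for j in weights) / fed_total
        ) * global_survive
        p_post_death = 1.0 - p_survive_post
    else:
        p_post_death = 0.0

    p_cycle_survival = (1.0 - p_pre_death) * (1.0 - p_post_death)

    c_m = tuple(_coverage_of(iv, weights, profile, e_expected) for iv in stack)

    return CycleOutcome(
        p_pre_death=p_pre_death,
        p_fed=p_fed,
        p_post_death=p_post_death,
        p_cycle_survival=p_cycle_survival,
        e_expected=e_expected,
        c_m=c_m,
        profile=profile,
        interventions=stack,
    )


def _coverage_of(
    iv: Intervention,
    weights: dict[Compartment, float],
    profile: BehaviourProfile,
    e_expected: float,
) -> float:
    """Probability of >= 1 encounter with ``iv`` during the cycle.

    Blood-compartment interventions are met per attempt with probability
    sum_j a_j * coverage over their targets, compounded over the expected
    attempts per meal; sugar baits and swarm sprays are per-cycle contacts.
    """
    if iv.kind is InterventionKind.SUGAR_BAIT:
        return profile.sugar_rate * iv.coverage
    if iv.kind is InterventionKind.SWARM_SPRAY:
        return iv.coverage
    m = sum(weights[j] for j in iv.blood_targets) * iv.coverage
    return 1.0 - (1.0 - m) ** e_expected
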