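"""Behavioural compartments of the feeding cycle.

A blood-seeking mosquito attacks one of five compartments per attempt:
humans indoors while in bed, humans indoors out of bed, humans outdoors,
treatable livestock, or other (wild) animals. Two further phases of the
cycle — sugar feeding and mating-swarm aggregation — are not attack
targets but can carry per-cycle insecticidal hazards.
"""

from __future__ import annotations

import enum


class Compartment(str, enum.Enum):
    """A blood-feeding attack compartment."""

    HUMAN_INDOOR_IN_BED = "human_indoor_in_bed"
    HUMAN_INDOOR_OUT_OF_BED = "human_indoor_out_of_bed"
    HUMAN_OUTDOOR = "human_outdoor"
    LIVESTOCK = "livestock"
    OTHER_ANIMAL = "other_animal"


class Phase(str, enum.Enum):
    """A non-blood phase of the cycle that an intervention can target."""

    SUGAR = "sugar"
    SWARM = "swarm"


BLOOD_COMPARTMENTS: tuple[Compartment, ...] = tuple(Compartment)

HUMAN_COMPARTMENTS: frozenset[Compartment] = frozenset(
    {
        Compartment.HUMAN_INDOOR_IN_BED,
        Compartment.HUMAN_INDOOR_OUT_OF_BED,
        Compartment.HUMAN_OUTDOOR,
    }
)

INDOOR_COMPARTMENTS: frozenset[Compartment] = frozenset(
    {Compartment.HUMAN_INDOOR_IN_BED, Compartment.HUMAN_INDOOR_OUT_OF_BED}
)
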