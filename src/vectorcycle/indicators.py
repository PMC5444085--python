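"""Estimators for field-surveyed behavioural indicators.

From the standard entomological survey instruments — hourly indoor/outdoor
human biting rates paired with human location time budgets, blood-meal
host identification counts, and indoor/outdoor resting collections — these
estimators recover the quantities the coverage models and decision rules
consume: the human blood index, the indoor/in-bed exposure proportions,
the residual outdoor exposure fraction under house screening, and the
indoor-resting fraction.

All proportions come with Wilson score confidence intervals, which remain
well behaved at the 0/1 boundaries common in small entomological samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from vectorcycle.errors import ValidationError

SURVEY_COLUMNS = (
    "hour",
    "bite_rate_indoor",
    "bite_rate_outdoor",
    "frac_humans_indoor",
    "frac_humans_in_bed",
)

#: Host labels treated as non-treatable ("other") rather than livestock.
DEFAULT_OTHER_HOSTS = frozenset({"other", "wild", "unknown"})


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its two-sided Wilson score interval."""

    estimate: float
    ci_low: float
    ci_high: float
    conf: float
    n: float
    method: str = "wilson"

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "conf": self.conf,
            "n": self.n,
            "method": self.method,
        }


def _wilson(successes: float, total: float, conf: float) -> ProportionEstimate:
    if total <= 0:
        raise ValidationError("total count must be positive")
    if not 0.0 < conf < 1.0:
        raise ValidationError(f"confidence level must be in (0, 1), got {conf!r}")
    low, high = proportion_confint(successes, total, alpha=1.0 - conf, method="wilson")
    return ProportionEstimate(
        estimate=successes / total,
        ci_low=float(max(low, 0.0)),
        ci_high=float(min(high, 1.0)),
        conf=conf,
        n=total,
    )


class SurveyData:
    """Hourly biting rates by location plus human time budgets.

    Exactly 24 rows, one per half-open hour bin [h, h+1). ``bite_rate_*``
    are bites per person-hour measured by all-night collections indoors
    and outdoors; ``frac_humans_indoor`` / ``frac_humans_in_bed`` are the
    fractions of the human population indoors / in bed during that hour,
    with in-bed <= indoors at every hour.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in SURVEY_COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"survey table missing columns: {missing}")
        df = table.loc[:, list(SURVEY_COLUMNS)].copy()
        df["hour"] = df["hour"].astype(int)
        if sorted(df["hour"]) != list(range(24)):
            raise ValidationError("survey must have 24 rows, hours 0..23")
        df = df.sort_values("hour").reset_index(drop=True)
        rates = df[["bite_rate_indoor", "bite_rate_outdoor"]].to_numpy(float)
        if not np.all(np.isfinite(rates)) or (rates < 0).any():
            raise ValidationError("biting rates must be finite and non-negative")
        for col in ("frac_humans_indoor", "frac_humans_in_bed"):
            v = df[col].to_numpy(float)
            if not np.all(np.isfinite(v)) or (v < 0).any() or (v > 1).any():
                raise ValidationError(f"{col} must lie in [0, 1]")
        if (df["frac_humans_in_bed"] > df["frac_humans_indoor"] + 1e-12).any():
            raise ValidationError("frac_humans_in_bed must not exceed frac_humans_indoor")
        self.table = df

    @classmethod
    def from_csv(cls, path) -> "SurveyData":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class BloodMealCounts:
    """Blood-meal host identification counts by host class.

    Mixed meals recorded as ``"a+b"`` count fractionally toward each named
    host (``mixed_weight`` to each, default half). Hosts in ``other_hosts``
    are non-treatable wild/unknown animals; every other non-human host is
    treated as identifiable livestock.
    """

    counts: dict[str, float]
    mixed_weight: float = 0.5
    other_hosts: frozenset = DEFAULT_OTHER_HOSTS

    def __post_init__(self) -> None:
        for host, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative count for host {host!r}")

    def _split(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for host, n in self.counts.items():
            parts = [p.strip().lower() for p in str(host).split("+")]
            w = self.mixed_weight if len(parts) > 1 else 1.0
            for p in parts:
                out[p] = out.get(p, 0.0) + w * n
        return out

    @property
    def human(self) -> float:
        return self._split().get("human", 0.0)

    @property
    def livestock(self) -> float:
        return sum(
            n
            for host, n in self._split().items()
            if host != "human" and host not in self.other_hosts
        )

    @property
    def total(self) -> float:
        return sum(self._split().values())

    @classmethod
    def from_csv(cls, path) -> "BloodMealCounts":
        df = pd.read_csv(path)
        for col in ("host", "count"):
            if col not in df.columns:
                raise ValidationError(f"bloodmeals table missing column {col!r}")
        return cls(counts=dict(zip(df["host"].astype(str), df["count"].astype(float))))


def human_blood_index(counts: BloodMealCounts, conf: float = 0.95) -> ProportionEstimate:
    """Human blood index: the fraction of blood meals taken on humans."""
    return _wilson(counts.human, counts.total, conf)


def livestock_meal_fraction(
    counts: BloodMealCounts, conf: float = 0.95
) -> ProportionEstimate:
    """Fraction of all blood meals obtained from identified livestock."""
    return _wilson(counts.livestock, counts.total, conf)


@dataclass(frozen=True)
class ExposureDistribution:
    """Where and when humans are actually exposed to bites.

    Hourly exposure weights are biting rate times the fraction of people
    in the corresponding location: ``w_in(t) = B_in(t) * H_in(t)`` and
    ``w_out(t) = B_out(t) * (1 - H_in(t))``.
    """

    pi_indoor: float
    pi_in_bed: float
    hourly: pd.DataFrame = field(repr=False)

    @property
    def pi_outdoor(self) -> float:
        return 1.0 - self.pi_indoor


def exposure_distribution(
    survey: SurveyData, net_users_protected_in_bed: bool = False
) -> ExposureDistribution:
    """Estimate the indoor/in-bed exposure proportions from a survey.

    ``pi_indoor`` is the indoor share of total exposure; ``pi_in_bed`` the
    in-bed share of indoor exposure. With ``net_users_protected_in_bed``
    the indoor weight counts only out-of-bed person-time (exposure of a
    net user, whose in-bed hours are protected); ``pi_in_bed`` is always
    reported for the unprotected population.
    """
    t = survey.table
    b_in = t["bite_rate_indoor"].to_numpy(float)
    b_out = t["bite_rate_outdoor"].to_numpy(float)
    h_in = t["frac_humans_indoor"].to_numpy(float)
    h_bed = t["frac_humans_in_bed"].to_numpy(float)

    w_in_full = b_in * h_in
    w_bed = b_in * h_bed
    w_in = b_in * (h_in - h_bed) if net_users_protected_in_bed else w_in_full
    w_out = b_out * (1.0 - h_in)

    total = w_in.sum() + w_out.sum()
    if total <= 0.0:
        raise ValidationError("all-zero exposure: distribution undefined")
    pi_indoor = float(w_in.sum() / total)
    pi_in_bed = float(w_bed.sum() / w_in_full.sum()) if w_in_full.sum() > 0 else 0.0
    hourly = pd.DataFrame(
        {"hour": t["hour"], "w_indoor": w_in, "w_outdoor": w_out, "w_in_bed": w_bed}
    )
    return ExposureDistribution(pi_indoor=pi_indoor, pi_in_bed=pi_in_bed, hourly=hourly)


def residual_outdoor_fraction(survey: SurveyData, screening_efficacy: float) -> float:
    """Outdoor share of the exposure that remains under house screening.

    Screening with protective efficacy ``s`` removes a fraction ``s`` of
    indoor exposure, so the remaining exposure splits as
    ``sum w_out / (sum w_out + (1 - s) * sum w_in)``. At ``s = 0`` this is
    the plain outdoor exposure proportion; at ``s = 1`` all remaining
    exposure is outdoors.
    """
    if not 0.0 <= screening_efficacy <= 1.0:
        raise ValidationError(
            f"screening_efficacy must be in [0, 1], got {screening_efficacy!r}"
        )
    dist = exposure_distribution(survey)
    w_in = dist.hourly["w_indoor"].sum()
    w_out = dist.hourly["w_outdoor"].sum()
    denom = w_out + (1.0 - screening_efficacy) * w_in
    if denom <= 0.0:
        raise ValidationError("no residual exposure under this screening efficacy")
    return float(w_out / denom)


def indoor_resting_fraction(
    indoor_fed_count: int, outdoor_fed_count: int, conf: float = 0.95
) -> ProportionEstimate:
    """Fraction of blood-fed mosquitoes collected resting indoors.

    A simple proportion of fed specimens from paired indoor/outdoor
    resting collections. This approximates the per-cycle indoor resting
    site usage rate without correcting for differential collection
    efficiency between locations; the method tag on the result records
    the approximation.
    """
    if indoor_fed_count < 0 or outdoor_fed_count < 0:
        raise ValidationError("resting counts must be non-negative")
    est = _wilson(indoor_fed_count, indoor_fed_count + outdoor_fed_count, conf)
    return ProportionEstimate(
        estimate=est.estimate,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        conf=est.conf,
        n=est.n,
        method="wilson;simple_proportion_uncorrected",
    )
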