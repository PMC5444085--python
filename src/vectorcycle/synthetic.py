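"""Synthetic entomological surveys and scenario ensembles.

Generates data with the statistical structure the indicator estimators
assume, so the whole pipeline is testable without field collections:

* hourly biting-rate curves as a mixture of two circular-normal (von
  Mises) peaks — an evening and a morning peak — discretised to hour
  bins, split indoors/outdoors so that the implied indoor exposure
  proportion equals the configured truth, with Poisson counting noise;
* human location schedules (go indoors for the evening, into bed, out of
  bed, leave the house in the morning) as step functions of hour;
* blood-meal host counts as multinomial draws with a true human blood
  index and livestock fraction;
* between-site ensembles of behaviour profiles: Beta-distributed
  behavioural fractions that can span essentially the whole (0, 1)
  range, and a log-normal indoor-resting rate that can span several
  hundred-fold between villages.

All randomness flows through one seeded NumPy generator; a fixed seed
gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from vectorcycle.errors import ValidationError
from vectorcycle.feeding_cycle import BehaviourProfile, _check_fraction
from vectorcycle.indicators import BloodMealCounts, SurveyData

HOURS = np.arange(24)


@dataclass(frozen=True)
class SynthConfig:
    """True parameters and sampling design for the synthetic generators.

    Schedule hours wrap overnight: people go indoors in the evening
    (``go_indoors_hour``), into bed (``bed_hour``), rise (``rise_hour``)
    and leave the house (``leave_house_hour``) the next morning. Biting
    peaks are von Mises means on the 24 h circle with concentrations
    ``kappa``; ``peak_weights`` mixes the two peaks. ``spread`` controls
    between-site heterogeneity of behavioural fractions (0 = all sites
    identical; larger values push mass toward the 0/1 extremes), and
    ``resting_log_sd`` the log-scale spread of the indoor-resting rate.
    """

    q_human: float = 0.5
    pi_indoor: float = 0.8
    pi_in_bed: float = 0.75
    f_livestock: float = 0.7
    r_indoor_rest: float = 0.5
    evening_peak_hour: float = 21.0
    morning_peak_hour: float = 5.0
    kappa_evening: float = 2.0
    kappa_morning: float = 2.0
    peak_weights: tuple[float, float] = (0.6, 0.4)
    go_indoors_hour: int = 20
    bed_hour: int = 22
    rise_hour: int = 5
    leave_house_hour: int = 6
    person_nights: int = 500
    bites_per_person_night: float = 2.0
    n_bloodmeals: int = 200
    spread: float = 0.8
    resting_median: float = 0.02
    resting_log_sd: float = 1.2
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_human", "pi_indoor", "pi_in_bed", "f_livestock", "r_indoor_rest"):
            object.__setattr__(self, name, _check_fraction(name, getattr(self, name)))
        w = self.peak_weights
        if len(w) != 2 or min(w) < 0 or sum(w) <= 0:
            raise ValidationError(f"peak_weights must be two non-negative weights, got {w!r}")
        for name in ("go_indoors_hour", "bed_hour", "rise_hour", "leave_house_hour"):
            h = int(getattr(self, name))
            if not 0 <= h < 24:
                raise ValidationError(f"{name} must be an hour in 0..23, got {h}")
            object.__setattr__(self, name, h)
        if not self._hours_ordered():
            raise ValidationError(
                "schedule must run go_indoors -> bed -> rise -> leave_house "
                "around the overnight wrap"
            )
        if self.spread < 0:
            raise ValidationError("spread must be non-negative")
        if self.resting_log_sd < 0 or self.resting_median <= 0:
            raise ValidationError("resting distribution parameters degenerate")

    def _hours_ordered(self) -> bool:
        # unwrap relative to go_indoors_hour: each event must follow the
        # previous one within a single night
        ref = self.go_indoors_hour
        seq = [
            (h - ref) % 24
            for h in (self.go_indoors_hour, self.bed_hour, self.rise_hour, self.leave_house_hour)
        ]
        return all(a <= b for a, b in zip(seq, seq[1:]))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def profile(self) -> BehaviourProfile:
        return BehaviourProfile(
            q_human=self.q_human,
            pi_indoor=self.pi_indoor,
            pi_in_bed=self.pi_in_bed,
            f_livestock=self.f_livestock,
            r_indoor_rest=self.r_indoor_rest,
        )


def _in_window(hour: np.ndarray, start: int, end: int) -> np.ndarray:
    """Indicator for the half-open overnight window [start, end)."""
    if start == end:
        return np.zeros_like(hour, dtype=float)
    if start < end:
        return ((hour >= start) & (hour < end)).astype(float)
    return ((hour >= start) | (hour < end)).astype(float)


def human_schedule(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Hourly fractions of humans indoors and in bed (step functions)."""
    h_in = _in_window(HOURS, config.go_indoors_hour, config.leave_house_hour)
    h_bed = _in_window(HOURS, config.bed_hour, config.rise_hour)
    return h_in, h_bed


def biting_curve(config: SynthConfig) -> np.ndarray:
    """Expected total biting activity per hour (normalised to sum to 1)."""
    theta = (HOURS + 0.5) * 2.0 * np.pi / 24.0
    w = np.asarray(config.peak_weights, float)
    w = w / w.sum()
    dens = np.zeros(24)
    for weight, mu_h, kappa in (
        (w[0], config.evening_peak_hour, config.kappa_evening),
        (w[1], config.morning_peak_hour, config.kappa_morning),
    ):
        mu = mu_h * 2.0 * np.pi / 24.0
        dens += weight * stats.vonmises.pdf(theta, kappa, loc=mu)
    return dens / dens.sum()


def gen_biting_survey(config: SynthConfig) -> SurveyData:
    """Generate a 24 h indoor/outdoor biting survey.

    The total attack curve follows the configured bimodal shape; the
    indoor/outdoor split of the biting rates is solved so that the
    exposure-weighted indoor proportion equals ``config.pi_indoor``
    exactly in the noiseless limit. Counts are Poisson around the
    expected person-night totals when ``config.noise`` is set.
    """
    h_in, h_bed = human_schedule(config)
    curve = biting_curve(config)
    x = float((curve * h_in).sum())
    y = float((curve * (1.0 - h_in)).sum())
    pi = config.pi_indoor
    # solve phi (indoor share of location-specific rates):
    # pi = phi*x / (phi*x + (1-phi)*y)
    if x <= 0.0 and pi > 0.0:
        raise ValidationError("no biting activity while humans are indoors")
    if y <= 0.0 and pi < 1.0:
        raise ValidationError("no biting activity while humans are outdoors")
    if pi in (0.0, 1.0):
        phi = pi
    else:
        phi = pi * y / (pi * y + (1.0 - pi) * x)

    scale = config.bites_per_person_night * config.person_nights
    mu_in = scale * curve * phi
    mu_out = scale * curve * (1.0 - phi)
    if config.noise:
        rng = config.rng()
        counts_in = rng.poisson(mu_in).astype(float)
        counts_out = rng.poisson(mu_out).astype(float)
    else:
        counts_in, counts_out = mu_in, mu_out

    table = pd.DataFrame(
        {
            "hour": HOURS,
            "bite_rate_indoor": counts_in / config.person_nights,
            "bite_rate_outdoor": counts_out / config.person_nights,
            "frac_humans_indoor": h_in,
            "frac_humans_in_bed": h_bed,
        }
    )
    return SurveyData(table)


def gen_bloodmeals(config: SynthConfig) -> BloodMealCounts:
    """Multinomial blood-meal host draws with the configured truth.

    Hosts are drawn as human with probability ``q_human``, livestock
    (cattle) with ``(1 - q_human) * f_livestock`` and wild/other hosts
    with the remainder.
    """
    n = int(config.n_bloodmeals)
    if n <= 0:
        raise ValidationError(f"n_bloodmeals must be positive, got {n}")
    p = np.array(
        [
            config.q_human,
            (1.0 - config.q_human) * config.f_livestock,
            (1.0 - config.q_human) * (1.0 - config.f_livestock),
        ]
    )
    draws = config.rng().multinomial(n, p)
    return BloodMealCounts(
        counts={"human": int(draws[0]), "cattle": int(draws[1]), "other": int(draws[2])}
    )


def gen_site_ensemble(config: SynthConfig, n_sites: int) -> list[BehaviourProfile]:
    """Draw between-site heterogeneity in behavioural fractions.

    Behavioural fractions follow Beta distributions centred on the
    configured truths with concentration ``2 / spread`` — at large spread
    the draws cover essentially the full (0, 1) range, as observed between
    trap locations within single villages. The indoor-resting rate is
    log-normal (median ``resting_median``, log-sd ``resting_log_sd``),
    capable of spanning several-hundred-fold ranges between villages,
    truncated at 1. ``spread == 0`` returns identical sites.
    """
    if n_sites < 1:
        raise ValidationError(f"n_sites must be >= 1, got {n_sites}")
    rng = config.rng()
    profiles: list[BehaviourProfile] = []

    def draw_frac(mean: float) -> np.ndarray:
        if config.spread == 0.0:
            return np.full(n_sites, mean)
        conc = 2.0 / config.spread
        a = max(mean * conc, 1e-6)
        b = max((1.0 - mean) * conc, 1e-6)
        return rng.beta(a, b, size=n_sites)

    q = draw_frac(config.q_human)
    pi = draw_frac(config.pi_indoor)
    pb = draw_frac(config.pi_in_bed)
    fl = draw_frac(config.f_livestock)
    if config.resting_log_sd == 0.0:
        rest = np.full(n_sites, config.resting_median)
    else:
        rest = np.minimum(
            rng.lognormal(np.log(config.resting_median), config.resting_log_sd, n_sites),
            1.0,
        )
    for i in range(n_sites):
        profiles.append(
            BehaviourProfile(
                q_human=q[i],
                pi_indoor=pi[i],
                pi_in_bed=pb[i],
                f_livestock=fl[i],
                r_indoor_rest=rest[i],
            )
        )
    return profiles


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
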