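"""Independent oracles for the closed-form models.

These re-derive expected values by brute force — a stochastic replay of
the per-attempt rules for the feeding cycle, and the textbook closed-form
Wilson interval — deliberately sharing no code with the library paths
they check.
"""

from __future__ import annotations

import math

import numpy as np

from vectorcycle.compartments import BLOOD_COMPARTMENTS, Compartment
from vectorcycle.feeding_cycle import BehaviourProfile, Intervention, InterventionKind


def simulate_cycle(
    profile: BehaviourProfile,
    interventions,
    n: int,
    seed: int,
    max_attempts: int = 10_000,
):
    """Monte-Carlo replay of the attempt rules for ``n`` mosquitoes.

    Each replicate repeatedly draws a compartment from the baseline
    weights, walks the intervention stack in order (covered -> pre-kill /
    block / pass), and is absorbed on death or a successful feed; fed
    replicates then face the post-bite hazards. Returns empirical fate
    probabilities plus the mean number of attempts.
    """
    rng = np.random.default_rng(seed)
    weights = profile.attempt_weights()
    comps = list(BLOOD_COMPARTMENTS)
    p = np.array([weights[j] for j in comps])

    fed_in = np.full(n, -1, dtype=int)  # compartment index, -1 = died pre-feed
    active = np.ones(n, dtype=bool)
    attempts = np.zeros(n, dtype=int)
    for _ in range(max_attempts):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        attempts[idx] += 1
        drawn = rng.choice(len(comps), size=idx.size, p=p)
        resolved_fed = np.ones(idx.size, dtype=bool)  # feeds unless killed/blocked
        dead = np.zeros(idx.size, dtype=bool)
        blocked = np.zeros(idx.size, dtype=bool)
        undecided = np.ones(idx.size, dtype=bool)
        for iv in interventions:
            t_idx = [k for k, c in enumerate(comps) if c in iv.blood_targets]
            hit = undecided & np.isin(drawn, t_idx)
            if not hit.any():
                continue
            met = hit & (rng.random(idx.size) < iv.coverage)
            r = rng.random(idx.size)
            die = met & (r < iv.pre_kill)
            blk = met & ~die & (r < iv.pre_kill + iv.block)
            dead |= die
            blocked |= blk
            undecided &= ~(die | blk)
        resolved_fed = ~(dead | blocked)
        # record fates
        gd = idx[dead]
        active[gd] = False
        fed_in[gd] = -1
        gf = idx[resolved_fed]
        active[gf] = False
        fed_in[gf] = drawn[resolved_fed]
        # blocked replicates stay active for another attempt
    if active.any():
        raise RuntimeError("simulation did not absorb; near-total blockade?")

    fed_mask = fed_in >= 0
    p_pre_death = float((~fed_mask).mean())
    p_fed = {
        c: float((fed_in == k).mean()) for k, c in enumerate(comps)
    }

    # post-bite hazards on fed replicates
    post_dead = np.zeros(n, dtype=bool)
    for iv in interventions:
        if iv.post_kill <= 0.0:
            continue
        if iv.kind is InterventionKind.SUGAR_BAIT:
            hazard = profile.sugar_rate * iv.coverage * iv.post_kill
            post_dead |= fed_mask & (rng.random(n) < hazard)
        elif iv.kind is InterventionKind.SWARM_SPRAY:
            post_dead |= fed_mask & (rng.random(n) < iv.coverage * iv.post_kill)
        else:
            factor = profile.r_indoor_rest if iv.kind is InterventionKind.IRS else 1.0
            t_idx = [k for k, c in enumerate(comps) if c in iv.blood_targets]
            in_target = fed_mask & np.isin(fed_in, t_idx)
            hazard = factor * iv.coverage * iv.post_kill
            post_dead |= in_target & (rng.random(n) < hazard)
    n_fed = int(fed_mask.sum())
    p_post_death = float(post_dead[fed_mask].mean()) if n_fed else 0.0
    p_survival = float((fed_mask & ~post_dead).mean())

    return {
        "p_pre_death": p_pre_death,
        "p_fed": p_fed,
        "p_post_death": p_post_death,
        "p_cycle_survival": p_survival,
        "mean_attempts": float(attempts.mean()),
        "n": n,
    }


def mc_se(p: float, n: int) -> float:
    """Binomial standard error, floored to keep 3-SE bands meaningful at
    the 0/1 boundary."""
    return max(math.sqrt(p * (1.0 - p) / n), 1.0 / n)


def wilson_interval(k: float, n: float, conf: float) -> tuple[float, float]:
    """Closed-form Wilson score interval, written from the formula."""
    from scipy.stats import norm

    z = norm.ppf(1.0 - (1.0 - conf) / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    return centre - half, centre + half
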