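"""Synthetic observers: response tables with known, recoverable structure.

The generator produces long-format trial tables (participant, condition,
trial, actual heading ``ah_deg``, perceived heading ``ph_deg``) whose
statistical structure matches what the downstream analyses test for:

* linear center bias — compression of responses toward 0° with slope ``slope_s``;
* central tendency — optional attraction toward the block's distribution
  mean with weight ``ct_weight`` (negative values give repulsion);
* a constant response shift ``shift_delta``;
* serial dependence — an influence of the previous trial's heading
  whose measured residual-regression slope s′ equals ``sd_coef``
  (negative = repulsion from the previous heading);
* homoscedastic Gaussian response noise with SD ``noise_sigma``.

Generative model for trial i of a block with distribution mean m::

    PH_i = shift_delta
           + slope_s * ((1 - ct_weight) * AH_i + ct_weight * m)
           + 2 * sd_coef * (AH_{i-1} - m)         # 0 on the first trial
           + Normal(0, noise_sigma^2)

Each analysis-stage parameter maps one-to-one onto a generator
parameter, so the whole pipeline supports parameter recovery. The
serial term uses the centered previous heading, with a factor 2, so
that the downstream estimate is consistent: the analysis regresses the
residual heading error on the relative heading RH = AH_prev − AH_cur,
and only the AH_prev half of RH carries signal
(Var(AH_prev)/Var(RH) = 1/2 on a shuffled schedule). A naive
``sd_coef·RH`` term would be recovered as sd_coef/2 and would bias the
fitted center-bias slope by −sd_coef; the centered form keeps the
center-bias slope unbiased and makes the group-level s′ converge to
``sd_coef``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    HeadingDistribution,
    TrialSchedule,
    distribution_mean,
    generate_schedule,
    make_distribution,
)

__all__ = ["ObserverParams", "COLUMNS", "simulate_block", "simulate_cohort"]

#: canonical ResponseTable column order (also the CSV header)
COLUMNS = ("participant", "condition", "trial", "ah_deg", "ph_deg")


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic observer.

    Parameters
    ----------
    slope_s
        Descriptive compression slope toward 0°; 1 is veridical, <1 is
        center bias.
    shift_delta
        Constant response shift in degrees.
    ct_weight
        Attraction weight toward the block's distribution mean, in
        [0, 1] for attraction (negative values allowed for repulsion).
    sd_coef
        Serial-dependence coefficient, on the scale of the measured
        group-level slope s′ (RHE on RH); negative = repulsive.
    noise_sigma
        SD of additive Gaussian response noise, degrees.
    """

    slope_s: float = 1.0
    shift_delta: float = 0.0
    ct_weight: float = 0.0
    sd_coef: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.ct_weight > 1:
            raise ValueError("ct_weight must be <= 1")


def _block_responses(
    ah: np.ndarray, dist_mean: float, params: ObserverParams, rng: np.random.Generator
) -> np.ndarray:
    serial = np.zeros_like(ah)
    serial[1:] = 2.0 * params.sd_coef * (ah[:-1] - dist_mean)  # first trial: no predecessor
    ph = (
        params.shift_delta
        + params.slope_s
        * ((1.0 - params.ct_weight) * ah + params.ct_weight * dist_mean)
        + serial
    )
    if params.noise_sigma > 0:
        ph = ph + rng.normal(0.0, params.noise_sigma, size=ah.shape)
    return ph


def simulate_block(
    schedule: TrialSchedule,
    params: ObserverParams,
    seed: int,
    participant: str = "p01",
) -> pd.DataFrame:
    """Simulate one participant running one block.

    Returns a ResponseTable (columns ``participant, condition, trial,
    ah_deg, ph_deg``) with 1-based trial indices in schedule order.
    """
    rng = np.random.default_rng(seed)
    ah = np.asarray(schedule.order, dtype=float)
    ph = _block_responses(
        ah, distribution_mean(schedule.distribution), params, rng
    )
    return pd.DataFrame(
        {
            "participant": participant,
            "condition": schedule.distribution.name,
            "trial": np.arange(1, len(ah) + 1),
            "ah_deg": ah,
            "ph_deg": ph,
        }
    )


def simulate_cohort(
    design: Sequence[str | HeadingDistribution],
    n_participants: int,
    params: ObserverParams | Mapping[str, ObserverParams],
    seed: int,
    slope_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate a cohort of participants, each running every block.

    Parameters
    ----------
    design
        Block distributions, as preset names or ``HeadingDistribution``
        objects; every participant runs all of them (own random order
        per participant and block).
    n_participants
        Cohort size.
    params
        One ``ObserverParams`` for everybody, or a mapping from
        condition (distribution name) to per-condition params.
    seed
        Master seed; per-participant/block streams are spawned from it.
    slope_sd
        Optional between-participant SD of ``slope_s`` (Gaussian around
        the supplied value, truncated at 0).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    dists = [
        d if isinstance(d, HeadingDistribution) else make_distribution(d)
        for d in design
    ]
    if isinstance(params, Mapping):
        per_cond = {d.name: params[d.name] for d in dists}
    else:
        per_cond = {d.name: params for d in dists}

    master = np.random.SeedSequence(seed)
    participant_seqs = master.spawn(n_participants)
    slope_rng = np.random.default_rng(master.spawn(1)[0])

    frames = []
    width = len(str(n_participants))
    for i, pseq in enumerate(participant_seqs):
        pid = f"p{i + 1:0{width}d}"
        # one slope offset per participant, shared across their blocks
        slope_offset = slope_rng.normal(0.0, slope_sd) if slope_sd > 0 else 0.0
        block_seqs = pseq.spawn(2 * len(dists))
        for j, dist in enumerate(dists):
            p = per_cond[dist.name]
            if slope_sd > 0:
                p = replace(p, slope_s=max(0.0, p.slope_s + slope_offset))
            sched_seed = int(block_seqs[2 * j].generate_state(1)[0] % (2**31))
            noise_seed = int(block_seqs[2 * j + 1].generate_state(1)[0] % (2**31))
            schedule = generate_schedule(dist, sched_seed)
            frames.append(simulate_block(schedule, p, noise_seed, participant=pid))
    table = pd.concat(frames, ignore_index=True)
    return table[list(COLUMNS)]
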