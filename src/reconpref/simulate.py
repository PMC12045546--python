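"""End-to-end simulation of the interview study.

For each synthetic participant this runs, in the interview's order: card
ranking without death, VAS without death, card ranking and VAS with the
death card added, and the two-stage chained standard gamble.  Output is a
set of long-format tables mirroring what an interviewer's data capture
would produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .cohort import (
    generate_latent_profiles,
    participant_stream,
    profiles_to_frame,
    sample_covariates,
)
from .config import GeneratorConfig
from .gamble import elicit_participant
from .instruments import rank_cards, vas_rate
from .states import build_deck


@dataclass
class SimulatedStudy:
    """All tables produced by one simulated interview study."""

    config: GeneratorConfig
    covariates: pd.DataFrame     # one row per participant
    latent: pd.DataFrame         # participant_id, state_id, latent_utility
    elicitation: pd.DataFrame    # participant_id, state_id, p1, p2, utility, degenerate
    rankings: pd.DataFrame       # participant_id, state_id, include_death, rank
    ratings: pd.DataFrame        # participant_id, state_id, include_death, rating


def simulate_study(
    config: Optional[GeneratorConfig] = None, seed: Optional[int] = None
) -> SimulatedStudy:
    """Simulate covariates, latent profiles, and all three instruments.

    ``seed`` overrides ``config.rng_seed`` when given.  Every participant
    draws from private streams, so results are reproducible and stable
    under changes of cohort size.
    """
    config = (config or GeneratorConfig()).validate()
    if seed is not None:
        config = config.replace(rng_seed=int(seed) % 2**31)
    covariates = sample_covariates(config)
    profiles = generate_latent_profiles(covariates, config)

    rank_rows, vas_rows, util_rows = [], [], []
    for (_, cov_row), profile in zip(covariates.iterrows(), profiles):
        idx = int(str(profile.participant_id).lstrip("P"))
        deck = build_deck(str(cov_row["bmi_category"]), str(cov_row["laterality"]),
                          include_death=True)
        gamble_rng = participant_stream(config.rng_seed, idx, 2)
        instrument_rng = participant_stream(config.rng_seed, idx, 3)

        for include_death in (False, True):
            rec = rank_cards(profile, deck, include_death, rng=instrument_rng)
            rank_rows += [
                {"participant_id": profile.participant_id, "state_id": sid,
                 "include_death": include_death, "rank": r}
                for sid, r in rec.rank.items()
            ]
            vas = vas_rate(profile, deck, include_death,
                           rounding=config.vas_rounding, rng=instrument_rng)
            vas_rows += [
                {"participant_id": profile.participant_id, "state_id": sid,
                 "include_death": include_death, "rating": r}
                for sid, r in vas.rating.items()
            ]

        result = elicit_participant(profile, deck, step=config.sg_step, rng=gamble_rng)
        util_rows += [
            {"participant_id": rec.participant_id, "state_id": rec.state_id,
             "p1": rec.p1, "p2": rec.p2, "utility": rec.utility,
             "degenerate": rec.degenerate}
            for rec in result.records
        ]

    return SimulatedStudy(
        config=config,
        covariates=covariates,
        latent=profiles_to_frame(profiles),
        elicitation=pd.DataFrame(util_rows),
        rankings=pd.DataFrame(rank_rows),
        ratings=pd.DataFrame(vas_rows),
    )
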