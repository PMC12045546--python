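"""Non-gamble preference instruments: card ranking and the visual analog scale.

Both instruments read the respondent's latent utilities, optionally
perturbed by rating noise.  The VAS reproduces the anchoring behaviour
seen in interviews: respondents place their most preferred card at 100
and least preferred at 0, so ratings are a min-max rescaling over the
presented card set.  When the death card is added, the rescaling set
includes death, which compresses the reconstruction states toward 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .cohort import LatentProfile
from .config import VAS_GRIDS
from .states import HealthState

#: within-modality qualities flagged when they appear in the top 3
_LOW_QUALITIES = ("fair", "poor")


@dataclass
class RankingRecord:
    """Ranks per card, 1 = most preferred; midranks used for ties."""

    participant_id: str
    include_death: bool
    rank: dict[str, float]


@dataclass
class VasRecord:
    """Feeling-thermometer ratings per card on the 0-100 scale."""

    participant_id: str
    include_death: bool
    rating: dict[str, float]


def _perceived(profile, deck, rng) -> np.ndarray:
    values = np.array([profile.latent_utility[s.state_id] for s in deck], dtype=float)
    if rng is not None and profile.vas_noise_sd > 0:
        values = values + rng.normal(0.0, profile.vas_noise_sd / 100.0, size=len(deck))
    return values


def _midranks(values: np.ndarray, tie_eps: float) -> np.ndarray:
    """Descending ranks with midranks for values closer than ``tie_eps``.

    Ties are chained: consecutive sorted values with gaps <= tie_eps join
    one cluster, and every member receives the mean of the cluster's
    positions.
    """
    order = np.argsort(-values, kind="stable")
    sorted_vals = values[order]
    ranks_sorted = np.empty(len(values), dtype=float)
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or sorted_vals[i - 1] - sorted_vals[i] > tie_eps:
            ranks_sorted[start:i] = (start + 1 + i) / 2.0
            start = i
    ranks = np.empty(len(values), dtype=float)
    ranks[order] = ranks_sorted
    return ranks


def rank_cards(
    profile: LatentProfile,
    deck: list[HealthState],
    include_death: bool = False,
    rng: Optional[np.random.Generator] = None,
    tie_eps: float = 1e-9,
) -> RankingRecord:
    """Rank the deck from most (1) to least preferred (9, or 10 with death).

    Ranks follow the descending order of the latent utilities perturbed by
    rating noise (sd ``vas_noise_sd``/100 when an rng is supplied); states
    within ``tie_eps`` of each other share a midrank.  Deterministic when
    no rng is given.
    """
    presented = [s for s in deck if include_death or s.modality != "death"]
    values = _perceived(profile, presented, rng)
    ranks = _midranks(values, tie_eps)
    return RankingRecord(
        profile.participant_id,
        include_death,
        {s.state_id: float(r) for s, r in zip(presented, ranks)},
    )


def vas_rate(
    profile: LatentProfile,
    deck: list[HealthState],
    include_death: bool = False,
    rounding: float = 2.5,
    rng: Optional[np.random.Generator] = None,
    anchor: bool = True,
) -> VasRecord:
    """Rate the deck on the 0-100 feeling thermometer.

    With ``anchor=True`` (the interview behaviour) the noisy latent values
    are min-max rescaled over the presented card set, so the best card sits
    at exactly 100 and the worst at exactly 0; if all values coincide every
    card is returned as 50.  ``anchor=False`` returns the raw thermometer
    reading 100 * latent, clipped to [0, 100], without re-anchoring —
    useful when ratings must stay comparable across respondents.  Ratings
    are snapped to the ``rounding`` grid (0 disables snapping).
    """
    if rounding not in VAS_GRIDS:
        raise ValueError(f"invalid rounding grid {rounding}; expected one of {VAS_GRIDS}")
    presented = [s for s in deck if include_death or s.modality != "death"]
    values = _perceived(profile, presented, rng)
    if anchor:
        lo, hi = values.min(), values.max()
        if hi - lo < 1e-12:
            ratings = np.full(len(values), 50.0)
        else:
            ratings = (values - lo) / (hi - lo) * 100.0
    else:
        ratings = np.clip(values * 100.0, 0.0, 100.0)
    if rounding > 0:
        ratings = np.round(ratings / rounding) * rounding
    ratings = np.clip(ratings, 0.0, 100.0)
    return VasRecord(
        profile.participant_id,
        include_death,
        {s.state_id: float(r) for s, r in zip(presented, ratings)},
    )


def flag_unexpected(
    record: RankingRecord, deck: list[HealthState]
) -> tuple[bool, list[str]]:
    """Flag rankings inconsistent with the surgeon-rated quality ordering.

    A ranking is "unexpected" when a fair or poor outcome sits in the top
    3 or an excellent outcome sits in the bottom 3 of the 9 non-death
    cards.  With-death records are re-ranked over the non-death subset
    before the rule is applied.
    """
    non_death = [s for s in deck if s.modality != "death" and s.state_id in record.rank]
    raw = np.array([record.rank[s.state_id] for s in non_death], dtype=float)
    ranks = rankdata(raw, method="average") if record.include_death else raw
    n = len(non_death)
    reasons = []
    for s, r in zip(non_death, ranks):
        if s.quality in _LOW_QUALITIES and r <= 3:
            reasons.append(f"{s.state_id} ranked {r:g} (top 3)")
        if s.quality == "excellent" and r >= n - 2:
            reasons.append(f"{s.state_id} ranked {r:g} (bottom 3)")
    return bool(reasons), reasons
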