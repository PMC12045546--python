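"""Standard-gamble titration and chained-gamble utility composition.

The interview offers a choice between the certainty of an intermediate
outcome and a lottery giving the respondent's best outcome with
probability ``p`` and the worst with ``1 - p``.  Starting from p = 1, the
interviewer lowers p in fixed decrements until the certainty is first
chosen; the indifference probability is taken as the midpoint of the
bracketing interval.

Chaining: stage 1 titrates each intermediate state against the
respondent's (best, worst) pair giving P1_i; stage 2 titrates the worst
state against (best, death) giving P2.  On the death-anchored scale with
u(best) = 1 and u(death) = 0,

    u(state_i) = P1_i + (1 - P1_i) * P2

which is the two-step composition u = P1*u(best) + (1 - P1)*u(worst) with
u(worst) = P2.

The simulated respondent is a random-utility agent: it compares
w(p)*u(best) + (1 - w(p))*u(worst) with u(certain), where w is a
probability-weighting function (identity for weighting_gamma = 1), and
with positive ``choice_noise`` chooses the gamble with logistic
probability in the expected-utility difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cohort import LatentProfile
from .states import HealthState

GAMBLE = "gamble"
CERTAINTY = "certainty"


@dataclass(frozen=True)
class GambleOffer:
    """One lottery offer: certainty of one state vs a best/worst gamble."""

    certain_state: str
    best_state: str
    worst_state: str
    p_best: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_best <= 1.0:
            raise ValueError(f"p_best={self.p_best} outside [0, 1]")
        if self.certain_state in (self.best_state, self.worst_state):
            raise ValueError(
                f"certain state {self.certain_state!r} cannot also be a gamble arm"
            )


@dataclass
class TitrationTrace:
    """Offered probabilities, choices, and the bracketed indifference point."""

    state_id: str
    offers: list[tuple[float, str]]
    p_indifference: float
    p_low: float
    p_high: float
    degenerate: Optional[str] = None  # None | 'high' | 'low'


@dataclass
class UtilityRecord:
    """Composed chained-gamble utility for one participant/state."""

    participant_id: str
    state_id: str
    p1: float
    p2: float
    utility: float
    degenerate: bool = False


@dataclass
class ElicitationResult:
    records: list[UtilityRecord]
    stage1_traces: dict[str, TitrationTrace] = field(default_factory=dict)
    anchor_trace: Optional[TitrationTrace] = None


def weight_probability(p: float, gamma: float) -> float:
    """Inverse-S probability weighting w(p) = p^g / (p^g + (1-p)^g)^(1/g).

    Identity for gamma = 1 (expected-utility respondent).
    """
    if gamma == 1.0:
        return p
    if p in (0.0, 1.0):
        return p
    num = p**gamma
    return num / (num + (1.0 - p) ** gamma) ** (1.0 / gamma)


def respond(
    offer: GambleOffer,
    profile: LatentProfile,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """One choice between the certainty and the gamble.

    Noiseless respondents take the gamble iff its (weighted) expected
    utility strictly exceeds the certain state's utility; exact
    indifference resolves to the certainty.  With ``choice_noise`` > 0 the
    gamble is chosen with logistic probability in the utility difference,
    which requires an ``rng``.
    """
    lat = profile.latent_utility
    for sid in (offer.certain_state, offer.best_state, offer.worst_state):
        if sid not in lat:
            raise KeyError(f"state {sid!r} not in profile {profile.participant_id!r}")
    w = weight_probability(offer.p_best, profile.weighting_gamma)
    diff = w * lat[offer.best_state] + (1.0 - w) * lat[offer.worst_state] - lat[
        offer.certain_state
    ]
    if profile.choice_noise == 0.0:
        return GAMBLE if diff > 0.0 else CERTAINTY
    if rng is None:
        raise ValueError("stochastic respondent (choice_noise > 0) needs an rng")
    p_gamble = 1.0 / (1.0 + math.exp(-diff / profile.choice_noise))
    return GAMBLE if rng.random() < p_gamble else CERTAINTY


def titrate(
    profile: LatentProfile,
    certain_state: str,
    best_state: str,
    worst_state: str,
    step: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> TitrationTrace:
    """Fixed-decrement titration of one certainty against a gamble.

    Offers p = 1, 1-step, 1-2*step, ... and stops at the first certainty
    choice.  The indifference probability is the midpoint of (first
    certainty p, last gamble p).  Boundary behaviour: certainty at the very
    first offer yields 1 - step/2 flagged 'high'; never switching by p = 0
    yields step/2 flagged 'low'.
    """
    if not 0.0 < step <= 0.25:
        raise ValueError(f"step={step} outside (0, 0.25]")
    offers: list[tuple[float, str]] = []
    n_steps = math.ceil(round(1.0 / step, 9))
    p_cert = None
    p_last_gamble = None
    for k in range(n_steps + 1):
        p = max(0.0, 1.0 - k * step)
        offer = GambleOffer(certain_state, best_state, worst_state, p)
        choice = respond(offer, profile, rng)
        offers.append((p, choice))
        if choice == CERTAINTY:
            p_cert = p
            break
        p_last_gamble = p
    if p_cert is None:  # gamble all the way down to p = 0
        trace = TitrationTrace(certain_state, offers, step / 2.0, 0.0, step, "low")
    elif p_last_gamble is None:  # certainty at the very first offer
        trace = TitrationTrace(
            certain_state, offers, 1.0 - step / 2.0, 1.0 - step, 1.0, "high"
        )
    else:
        trace = TitrationTrace(
            certain_state,
            offers,
            (p_cert + p_last_gamble) / 2.0,
            p_cert,
            p_last_gamble,
        )
    return trace


def chain_utility(p1, p2):
    """Compose the chained-gamble utility u = p1 + (1 - p1) * p2.

    Accepts scalars or arrays in [0, 1]; p1 is the stage-1 indifference
    probability against the (best, worst) pair and p2 anchors the worst
    state against death.  The result is monotone in both arguments and
    spans [p2, 1] as p1 runs over [0, 1].
    """
    a1 = np.asarray(p1, dtype=float)
    a2 = np.asarray(p2, dtype=float)
    if np.any((a1 < 0) | (a1 > 1)) or np.any((a2 < 0) | (a2 > 1)):
        raise ValueError("chain_utility arguments must lie in [0, 1]")
    out = a1 + (1.0 - a1) * a2
    return float(out) if out.ndim == 0 else out


def elicit_participant(
    profile: LatentProfile,
    deck: list[HealthState],
    step: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> ElicitationResult:
    """Run the full two-stage chained standard gamble for one respondent.

    The most and least preferred non-death states are identified from the
    noiseless latent utilities (ties broken by deck order).  Each of the
    intermediate states is titrated against (best, worst) giving P1_i; the
    worst state is titrated against (best, death) giving P2; utilities are
    composed with :func:`chain_utility`.  The best state gets utility 1.0
    and the worst gets P2.
    """
    death = [s for s in deck if s.modality == "death"]
    if not death:
        raise ValueError("deck has no death state; the chain anchor is undefined")
    non_death = [s for s in deck if s.modality != "death"]
    if len(non_death) < 3:
        raise ValueError("need at least 3 non-death states to run the chained gamble")
    lat = profile.latent_utility
    best = max(non_death, key=lambda s: lat[s.state_id])  # first max in deck order
    rest = [s for s in non_death if s is not best]
    worst = min(rest, key=lambda s: lat[s.state_id])  # first min in deck order
    intermediates = [s for s in rest if s is not worst]

    anchor = titrate(profile, worst.state_id, best.state_id, "death", step, rng)
    p2 = anchor.p_indifference

    records = [
        UtilityRecord(profile.participant_id, best.state_id, 1.0, p2, 1.0),
        UtilityRecord(
            profile.participant_id, worst.state_id, 0.0, p2, p2,
            degenerate=anchor.degenerate is not None,
        ),
    ]
    traces: dict[str, TitrationTrace] = {}
    for s in intermediates:
        tr = titrate(profile, s.state_id, best.state_id, worst.state_id, step, rng)
        traces[s.state_id] = tr
        records.append(
            UtilityRecord(
                profile.participant_id,
                s.state_id,
                tr.p_indifference,
                p2,
                chain_utility(tr.p_indifference, p2),
                degenerate=tr.degenerate is not None,
            )
        )
    order = {s.state_id: i for i, s in enumerate(deck)}
    records.sort(key=lambda r: order[r.state_id])
    return ElicitationResult(records, traces, anchor)
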