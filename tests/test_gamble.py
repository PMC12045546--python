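import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reconpref import (
    GambleOffer,
    LatentProfile,
    build_deck,
    chain_utility,
    elicit_participant,
    respond,
    titrate,
)
from reconpref.config import default_base_utilities
from reconpref.gamble import weight_probability

from conftest import make_profile


def _triple(u_c, u_b=1.0, u_w=0.0, **kw):
    return make_profile(
        {"implant_good": u_c, "implant_excellent": u_b, "implant_poor": u_w}, **kw
    )


# --------------------------------------------------------------------------- #
# respond
# --------------------------------------------------------------------------- #
class TestRespond:
    def test_sure_gamble_taken_when_best_dominates(self):
        offer = GambleOffer("implant_good", "implant_excellent", "implant_poor", 1.0)
        assert respond(offer, _triple(0.95)) == "gamble"

    def test_certainty_taken_when_expected_utility_lower(self):
        offer = GambleOffer("implant_good", "implant_excellent", "implant_poor", 0.90)
        assert respond(offer, _triple(0.95)) == "certainty"

    def test_exact_indifference_resolves_to_certainty(self):
        offer = GambleOffer("implant_good", "implant_excellent", "implant_poor", 0.95)
        assert respond(offer, _triple(0.95)) == "certainty"

    def test_unknown_state_rejected(self):
        offer = GambleOffer("tissue_good", "implant_excellent", "implant_poor", 0.5)
        with pytest.raises(KeyError, match="tissue_good"):
            respond(offer, _triple(0.95))

    def test_stochastic_choice_needs_rng(self):
        offer = GambleOffer("implant_good", "implant_excellent", "implant_poor", 1.0)
        with pytest.raises(ValueError, match="rng"):
            respond(offer, _triple(0.95, choice_noise=0.1))

    def test_noise_to_zero_limit_recovers_deterministic_rule(self, rng):
        # P(gamble) under shrinking temperature converges to the 0/1 rule
        offer = GambleOffer("implant_good", "implant_excellent", "implant_poor", 0.97)
        agreement = []
        for tau in (0.1, 0.01, 0.001):
            profile = _triple(0.95, choice_noise=tau)
            picks = [respond(offer, profile, rng) for _ in range(1000)]
            agreement.append(np.mean([c == "gamble" for c in picks]))
        assert agreement[0] < agreement[-1]
        assert agreement[-1] > 0.99  # deterministic rule says gamble (0.97 > 0.95)

    def test_probability_weighting_distorts_choice(self):
        # gamma < 1 underweights a large p, flipping a near-indifferent choice
        offer = GambleOffer("implant_good", "implant_excellent", "implant_poor", 0.96)
        assert respond(offer, _triple(0.95)) == "gamble"
        assert respond(offer, _triple(0.95, weighting_gamma=0.5)) == "certainty"

    def test_weighting_function_anchors_and_identity(self):
        assert weight_probability(0.0, 0.6) == 0.0
        assert weight_probability(1.0, 0.6) == 1.0
        assert weight_probability(0.37, 1.0) == 0.37
        ps = np.linspace(0, 1, 21)
        ws = [weight_probability(p, 0.6) for p in ps]
        assert all(b >= a for a, b in zip(ws, ws[1:]))


# --------------------------------------------------------------------------- #
# titrate
# --------------------------------------------------------------------------- #
def _oracle_midpoint(v: float, step: float) -> float:
    """Independent hand-computation of the titration midpoint.

    The respondent gambles while p > v, so the first certainty choice is at
    the largest grid value <= v and the bracket spans one step.
    """
    grid = [max(0.0, 1.0 - k * step) for k in range(math.ceil(round(1 / step, 9)) + 1)]
    for prev, p in zip(grid, grid[1:]):
        if p <= v:
            return (prev + p) / 2.0
    return step / 2.0


class TestTitrate:
    def test_hand_trace_relative_utility_093(self):
        trace = titrate(_triple(0.93), "implant_good", "implant_excellent",
                        "implant_poor", step=0.05)
        assert [c for _, c in trace.offers] == ["gamble", "gamble", "certainty"]
        assert trace.p_indifference == pytest.approx(0.925)
        assert trace.degenerate is None

    def test_hand_trace_near_one(self):
        trace = titrate(_triple(0.999), "implant_good", "implant_excellent",
                        "implant_poor", step=0.05)
        assert trace.p_indifference == pytest.approx(0.975)

    def test_certainty_at_first_offer_flagged_high(self):
        # u(certain) >= u(best): the gamble is never attractive
        trace = titrate(_triple(1.0, u_b=0.9), "implant_good", "implant_excellent",
                        "implant_poor", step=0.05)
        assert trace.degenerate == "high"
        assert trace.p_indifference == pytest.approx(0.975)
        assert trace.p_low <= trace.p_indifference <= trace.p_high

    def test_never_switching_flagged_low(self):
        # u(certain) <= u(worst): the certainty is never attractive
        trace = titrate(_triple(0.1, u_w=0.2), "implant_good", "implant_excellent",
                        "implant_poor", step=0.05)
        assert trace.degenerate == "low"
        assert trace.p_indifference == pytest.approx(0.025)

    @pytest.mark.parametrize("step", [0.3, 0.0, -0.05])
    def test_invalid_step_rejected(self, step):
        with pytest.raises(ValueError, match="step"):
            titrate(_triple(0.5), "implant_good", "implant_excellent",
                    "implant_poor", step=step)

    @pytest.mark.parametrize("step", [0.05, 0.1, 0.25])
    def test_midpoint_matches_oracle_on_grid_of_utilities(self, step):
        for v in np.linspace(0.013, 0.987, 41):
            trace = titrate(_triple(v), "implant_good", "implant_excellent",
                            "implant_poor", step=step)
            assert trace.p_indifference == pytest.approx(_oracle_midpoint(v, step),
                                                         abs=1e-9)
            assert abs(trace.p_indifference - v) <= step / 2 + 1e-9

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        v=st.floats(0.002, 0.998),
        step=st.sampled_from([0.02, 0.05, 0.1, 0.25]),
    )
    def test_indifference_within_half_step_of_truth(self, v, step):
        trace = titrate(_triple(v), "implant_good", "implant_excellent",
                        "implant_poor", step=step)
        if trace.degenerate is None:
            assert abs(trace.p_indifference - v) <= step / 2 + 1e-9

    def test_offers_strictly_decrease_with_single_switch(self):
        trace = titrate(_triple(0.61), "implant_good", "implant_excellent",
                        "implant_poor", step=0.05)
        ps = [p for p, _ in trace.offers]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        choices = [c for _, c in trace.offers]
        assert choices[-1] == "certainty"
        assert all(c == "gamble" for c in choices[:-1])


# --------------------------------------------------------------------------- #
# chain_utility
# --------------------------------------------------------------------------- #
class TestChainUtility:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [(1.0, 0.3, 1.0), (0.0, 0.86, 0.86), (0.95, 0.80, 0.99)],
    )
    def test_printed_formula_values(self, p1, p2, expected):
        assert chain_utility(p1, p2) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p1,p2", [(-0.1, 0.5), (0.5, 1.2), (2.0, 0.0)])
    def test_out_of_range_rejected(self, p1, p2):
        with pytest.raises(ValueError):
            chain_utility(p1, p2)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(p1=st.floats(0, 1), p2=st.floats(0, 1), d=st.floats(0, 1))
    def test_monotone_and_bounded(self, p1, p2, d):
        u = chain_utility(p1, p2)
        assert p2 - 1e-12 <= u <= 1 + 1e-12
        p1b = p1 + (1 - p1) * d  # any larger p1
        assert chain_utility(p1b, p2) >= u - 1e-12
        p2b = p2 + (1 - p2) * d
        assert chain_utility(p1, p2b) >= u - 1e-12


# --------------------------------------------------------------------------- #
# elicit_participant
# --------------------------------------------------------------------------- #
class TestElicitParticipant:
    def test_requires_death_card(self, base_profile, deck9):
        with pytest.raises(ValueError, match="death"):
            elicit_participant(base_profile, deck9)

    @pytest.mark.parametrize("step,tol", [(0.05, 0.05), (0.01, 0.01), (0.002, 0.002)])
    def test_composed_utilities_converge_to_rescaled_latents(
        self, base_profile, deck10, step, tol
    ):
        result = elicit_participant(base_profile, deck10, step=step)
        u_best = max(base_profile.latent_utility[s.state_id] for s in deck10)
        errs = [
            abs(r.utility - base_profile.latent_utility[r.state_id] / u_best)
            for r in result.records
        ]
        assert max(errs) <= tol

    def test_error_shrinks_with_step(self, base_profile, deck10):
        def max_err(step):
            result = elicit_participant(base_profile, deck10, step=step)
            u_best = max(base_profile.latent_utility[s.state_id] for s in deck10)
            return max(
                abs(r.utility - base_profile.latent_utility[r.state_id] / u_best)
                for r in result.records
            )

        assert max_err(0.002) < max_err(0.05)

    def test_all_equal_profile_everything_degenerate(self, deck10):
        profile = make_profile({s.state_id: 0.9 for s in deck10 if s.modality != "death"})
        result = elicit_participant(profile, deck10, step=0.05)
        assert all(r.degenerate for r in result.records[1:])
        assert all(0.0 <= r.utility <= 1.0 for r in result.records)
        assert result.anchor_trace.degenerate == "high"
        assert all(t.degenerate is not None for t in result.stage1_traces.values())

    def test_structure_and_bounds(self, base_profile, deck10):
        result = elicit_participant(base_profile, deck10, step=0.05)
        assert len(result.records) == 9
        by_state = {r.state_id: r for r in result.records}
        assert by_state["implant_excellent"].utility == 1.0  # most preferred
        assert by_state["none"].utility == by_state["none"].p2  # least preferred
        p2 = result.anchor_trace.p_indifference
        for r in result.records:
            assert 0.0 <= r.utility <= 1.0
            assert r.utility >= p2 - 1e-12
            assert r.utility == pytest.approx(r.p1 + (1 - r.p1) * r.p2, abs=1e-12)

    def test_chained_equals_two_step_composition(self, base_profile, deck10):
        # u = P1*u(best) + (1-P1)*u(worst) with u(best)=1, u(worst)=P2
        result = elicit_participant(base_profile, deck10, step=0.05)
        for r in result.records:
            assert r.utility == pytest.approx(r.p1 * 1.0 + (1 - r.p1) * r.p2, abs=1e-12)

    def test_cohort_sweep_respects_scale_contract(self):
        from reconpref import GeneratorConfig, generate_latent_profiles, sample_covariates
        from reconpref.cohort import participant_stream

        config = GeneratorConfig(n_participants=40, rng_seed=6)
        profiles = generate_latent_profiles(sample_covariates(config), config)
        deck = build_deck("normal", "unilateral", include_death=True)
        for i, profile in enumerate(profiles, start=1):
            rng = participant_stream(config.rng_seed, i, 2)
            result = elicit_participant(profile, deck, step=0.05, rng=rng)
            for r in result.records:
                assert 0.0 <= r.utility <= 1.0
                assert r.utility >= r.p2 - 1e-12
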