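"""Validation experiments for the elicitation machinery and the analysis.

These are the package's own checks that the simulated instruments measure
what they claim: titration error sweeps against the known relative
utility, chained-vs-direct gamble agreement, zero-noise instrument
concordance, the behaviour of the p < 0.2 univariate screen under the
null, and the backward-AIC recovery of the generating covariate effects.
They are exercised by the test suite and by ``scripts/acceptance.py``.

The coefficient-recovery experiment regresses *unanchored* thermometer
ratings: respondent re-anchoring (best card to 100, worst to 0) is a
per-participant monotone transformation that destroys cross-respondent
comparability of VAS points, so generating effects are only identified on
the unanchored scale.  Its config also lowers the base utilities to keep
latent values away from the [0, 1] clip.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (
    LatentProfile,
    generate_latent_profiles,
    participant_stream,
    sample_covariates,
)
from .config import GeneratorConfig, default_base_utilities
from .gamble import chain_utility, elicit_participant, titrate
from .instruments import rank_cards, vas_rate
from .states import build_deck
from .stats import backward_aic, rank_utility_correlation, univariate_screen
from .study import GROUPS, default_candidate_frame, group_scores

_DECK9 = build_deck("normal", "unilateral", include_death=False)
_DECK10 = build_deck("normal", "unilateral", include_death=True)
_STATE_IDS9 = [s.state_id for s in _DECK9]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(int(seed) % 2**31).generate_state(n) % 2**31


# --------------------------------------------------------------------------- #
# titration accuracy
# --------------------------------------------------------------------------- #
def titration_error_sweep(
    n_profiles: int = 1000, step: float = 0.05, seed: int = 0
) -> dict:
    """Titrate random noiseless (certain, best, worst) triples.

    Returns the maximum absolute error of the elicited indifference
    probability against the true relative utility
    v = (u_c - u_w)/(u_b - u_w), over non-degenerate traces.
    """
    rng = np.random.default_rng(int(seed) % 2**31)
    errors = []
    n_degenerate = 0
    for _ in range(n_profiles):
        while True:
            u = np.sort(rng.uniform(0.02, 0.999, size=3))
            if np.min(np.diff(u)) > 1e-6:
                break
        u_w, u_c, u_b = u
        profile = LatentProfile(
            "sweep",
            {"implant_good": u_c, "implant_excellent": u_b, "implant_poor": u_w},
        )
        trace = titrate(profile, "implant_good", "implant_excellent", "implant_poor",
                        step=step)
        if trace.degenerate is not None:
            n_degenerate += 1
            continue
        v = (u_c - u_w) / (u_b - u_w)
        errors.append(abs(trace.p_indifference - v))
    return {
        "max_abs_error": float(np.max(errors)),
        "mean_abs_error": float(np.mean(errors)),
        "n": len(errors),
        "n_degenerate": n_degenerate,
    }


def _cohort_like_profile(rng: np.random.Generator) -> LatentProfile:
    """A noiseless profile jittered around the default base utilities."""
    base = default_base_utilities()
    while True:
        lat = {sid: float(np.clip(u + rng.uniform(-0.02, 0.02), 0.01, 0.999))
               for sid, u in base.items()}
        vals = np.sort(list(lat.values()))
        if np.min(np.diff(vals)) > 1e-6:
            return LatentProfile("sweep", lat)


def chained_vs_direct_gap(
    n_profiles: int = 500, step: float = 0.05, seed: int = 0
) -> dict:
    """Chained two-stage utilities vs a single direct (best, death) titration.

    Profiles are noiseless expected-utility respondents jittered around the
    cohort's base utilities (the instrument's operating range).  Returns
    the maximum absolute gap over all states and profiles.
    """
    rng = np.random.default_rng(int(seed) % 2**31)
    gaps = []
    for _ in range(n_profiles):
        profile = _cohort_like_profile(rng)
        result = elicit_participant(profile, _DECK10, step=step)
        lat = profile.latent_utility
        best = max(_STATE_IDS9, key=lambda s: lat[s])
        for rec in result.records:
            if rec.state_id == best:
                continue
            direct = titrate(profile, rec.state_id, best, "death", step=step)
            gaps.append(abs(rec.utility - direct.p_indifference))
    return {"max_abs_gap": float(np.max(gaps)), "n": n_profiles,
            "n_comparisons": len(gaps)}


# --------------------------------------------------------------------------- #
# instrument concordance
# --------------------------------------------------------------------------- #
def zero_noise_concordance(
    n_participants: int = 50, step: float = 0.01, seed: int = 0
) -> dict:
    """Per-participant Spearman correlations between instruments, no noise.

    Ranks against VAS should be exactly -1 (opposite orientations of the
    same ordering); VAS against chained utilities should be near 1, limited
    only by titration quantisation.  "Zero noise" switches off rating and
    choice noise and the behavioural perturbations: in particular the
    equipoise compression creates near-ties narrower than any finite
    titration step can resolve, so it is a deliberate departure from
    concordance, not noise the gamble should see through.  The sweep uses
    the clip-free base utilities of :func:`recovery_config`: with the
    ceiling-hugging default bases, covariate effects saturate several
    states at latent 1.0, and exact ties are rated identically by the VAS
    but resolved degenerately (1 vs 1 - step/2 of the way to P2) by the
    gamble, which is a property of ties, not of the instruments' agreement.
    """
    config = recovery_config(n_participants).replace(
        rng_seed=int(seed) % 2**31,
        latent_noise_sd=0.0, vas_noise_sd=0.0, choice_noise=0.0,
        vas_rounding=0.0, sg_step=step,
    )
    cov = sample_covariates(config)
    profiles = generate_latent_profiles(cov, config)
    rho_rank_vas, rho_vas_util = [], []
    n_below_resolution = 0
    for profile in profiles:
        ranks = rank_cards(profile, _DECK9, include_death=False)
        vas = vas_rate(profile, _DECK9, include_death=False, rounding=0.0)
        r_vec = [ranks.rank[s] for s in _STATE_IDS9]
        v_vec = [vas.rating[s] for s in _STATE_IDS9]
        rho_rank_vas.append(rank_utility_correlation(r_vec, v_vec).statistic)
        # A gamble titrated in decrements of `step` cannot order states whose
        # relative utilities differ by less than the step; the utility
        # concordance is only defined for respondents whose preferences are
        # separated beyond that resolution.
        lat = np.sort([profile.latent_utility[s] for s in _STATE_IDS9])
        v_gap = np.min(np.diff(lat)) / (lat[-1] - lat[0])
        if v_gap <= step:
            n_below_resolution += 1
            continue
        result = elicit_participant(profile, _DECK10, step=step)
        util = {r.state_id: r.utility for r in result.records}
        u_vec = [util[s] for s in _STATE_IDS9]
        rho_vas_util.append(rank_utility_correlation(v_vec, u_vec).statistic)
    return {
        "rho_rank_vas_min": float(np.min(rho_rank_vas)),
        "rho_rank_vas_max": float(np.max(rho_rank_vas)),
        "rho_vas_utility_min": float(np.min(rho_vas_util)),
        "n": n_participants,
        "n_below_resolution": n_below_resolution,
    }


# --------------------------------------------------------------------------- #
# screen null behaviour
# --------------------------------------------------------------------------- #
def null_screen_retention(n_reps: int = 1000, n: int = 500, seed: int = 0) -> dict:
    """Retention rate of a pure-noise covariate under the p < 0.2 screen."""
    rng = np.random.default_rng(int(seed) % 2**31)
    kept = 0
    for _ in range(n_reps):
        y = rng.normal(size=n)
        x = pd.DataFrame({"x": rng.normal(size=n)})
        if univariate_screen(y, x, alpha=0.2).retained:
            kept += 1
    return {"retention_rate": kept / n_reps, "n_reps": n_reps, "n": n}


# --------------------------------------------------------------------------- #
# coefficient recovery
# --------------------------------------------------------------------------- #
def recovery_config(n_participants: int = 2000) -> GeneratorConfig:
    """Generator config for the effect-recovery experiment.

    Uses the study's generating covariate effects but lowers the base
    utilities (more headroom before the [0, 1] clip) and switches off the
    equipoise/unexpected behavioural perturbations, which are deliberate
    nonlinearities orthogonal to the linear effect structure under test.
    """
    bases = {
        "implant_excellent": 0.70, "implant_good": 0.64,
        "implant_fair": 0.58, "implant_poor": 0.52,
        "tissue_excellent": 0.68, "tissue_good": 0.62,
        "tissue_fair": 0.56, "tissue_poor": 0.50,
        "none": 0.35,
    }
    return GeneratorConfig(n_participants=n_participants).replace(
        base_utilities=bases,
        latent_noise_sd=0.05,
        vas_noise_sd=5.0,
        unexpected_rank_fraction=0.0,
        equipoise_fraction=0.0,
    )


def implied_group_slopes(config: GeneratorConfig) -> dict[tuple[str, str], float]:
    """Generating slope of each regression term on each option-group score.

    A group score averages its states, and states receive different effect
    sums (e.g. 'any' + 'implant' both hit an implant state), so the implied
    slope for (group, term) is the mean per-state effect over the group.
    """
    group_states = {
        "any": [s for s in _STATE_IDS9 if s != "none"],
        "implant": [s for s in _STATE_IDS9 if s.startswith("implant_")],
        "tissue": [s for s in _STATE_IDS9 if s.startswith("tissue_")],
        "none": ["none"],
    }
    slopes: dict[tuple[str, str], float] = {}
    for eff in config.effects:
        term = eff.level if eff.level is not None else eff.covariate
        if eff.group == "any":
            targets = group_states["any"]
        elif eff.group in ("implant", "tissue", "none"):
            targets = group_states[eff.group]
        else:
            targets = [eff.group]
        for gname, states in group_states.items():
            hit = sum(1 for s in states if s in targets)
            if hit:
                key = (gname, term)
                slopes[key] = slopes.get(key, 0.0) + eff.per_point * hit / len(states)
    return {k: v for k, v in slopes.items() if v != 0.0}


_TERM_BLOCK = {"overweight": "bmi_category", "obese": "bmi_category"}


def coefficient_recovery_experiment(
    n_reps: int = 200,
    n: int = 2000,
    seed: int = 0,
    config: Optional[GeneratorConfig] = None,
) -> dict:
    """Backward-AIC recovery of the generating effects from unanchored VAS.

    For each replicate: draw a cohort, build latent profiles, rate all nine
    cards on the unanchored thermometer, average per option group, then run
    the univariate screen and backward-AIC selection per group.  Reports,
    per nonzero generating (group, term) slope, how often the term is
    retained and how often its Wald 95% CI covers the implied slope.
    """
    base_config = config if config is not None else recovery_config(n)
    slopes = implied_group_slopes(base_config)
    retained_counts = {k: 0 for k in slopes}
    covered_counts = {k: 0 for k in slopes}
    fitted_counts = {k: 0 for k in slopes}
    coef_sums = {k: 0.0 for k in slopes}

    for child in _child_seeds(seed, n_reps):
        cfg = base_config.replace(rng_seed=int(child))
        cov = sample_covariates(cfg)
        profiles = generate_latent_profiles(cov, cfg)
        rows = {}
        for profile in profiles:
            idx = int(profile.participant_id.lstrip("P"))
            rng = participant_stream(cfg.rng_seed, idx, 3)
            vas = vas_rate(profile, _DECK9, include_death=False,
                           rounding=cfg.vas_rounding, rng=rng, anchor=False)
            rows[profile.participant_id] = vas.rating
        wide = pd.DataFrame.from_dict(rows, orient="index")
        wide.index.name = "participant_id"
        cand = default_candidate_frame(cov).set_axis(cov["participant_id"], axis=0)
        for group in GROUPS:
            terms_here = [k for k in slopes if k[0] == group]
            if not terms_here:
                continue
            y = group_scores(wide, group).reindex(cand.index)
            screen = univariate_screen(y, cand, alpha=0.2)
            model = (backward_aic(y, cand, screen.retained, outcome_name=group)
                     if screen.retained else None)
            for key in terms_here:
                _, term = key
                fitted_counts[key] += 1
                if model is None:
                    continue
                block = _TERM_BLOCK.get(term, term)
                if block in model.retained and term in model.terms.index:
                    retained_counts[key] += 1
                    row = model.terms.loc[term]
                    coef_sums[key] += float(row["coef"])
                    if row["ci_low"] <= slopes[key] <= row["ci_high"]:
                        covered_counts[key] += 1

    retention = {f"{g}:{t}": retained_counts[(g, t)] / max(fitted_counts[(g, t)], 1)
                 for (g, t) in slopes}
    total_ret = sum(retained_counts.values())
    coverage = (sum(covered_counts.values()) / total_ret) if total_ret else float("nan")
    mean_coefs = {
        f"{g}:{t}": coef_sums[(g, t)] / retained_counts[(g, t)]
        for (g, t) in slopes if retained_counts[(g, t)]
    }
    return {
        "retention": retention,
        "min_retention": min(retention.values()),
        "ci_coverage": coverage,
        "implied_slopes": {f"{g}:{t}": v for (g, t), v in slopes.items()},
        "mean_coefficients": mean_coefs,
        "n_reps": n_reps,
        "n": n,
    }
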