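"""Synthetic cohort: participant covariates and latent utility profiles.

Each participant owns private random streams derived from
``(rng_seed, participant_index, stage)``, so a cohort is bit-reproducible
and stable under subsetting or reordering.  Continuous covariates are
clipped normals whose pre-clip mean is calibrated so the clipped draw is
unbiased for the configured mean; categoricals are drawn from the
configured probabilities.

Latent utilities are built per state as

    base(modality, quality) + sum(effects) / 100 + noise,     clipped to [0, 1]

with two optional behavioural perturbations observed in the interview
data: "unexpected" preference orderings (an excellent card swapped with a
fair or poor card of the same modality) and equipoise (all non-excellent
cards compressed toward a common value).  Death always has latent utility
exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .config import ContinuousSpec, GeneratorConfig
from .states import RECON_MODALITIES, reconstruction_states

_CONTINUOUS_ORDER = (
    "age",
    "asir_total",
    "asir_behavior",
    "asir_self_evaluation",
    "asir_control",
    "breastq_breast",
    "breastq_outcome",
)
_CATEGORICAL_ORDER = (
    "race",
    "ethnicity",
    "married",
    "education",
    "indication",
    "laterality",
    "bmi_category",
    "timing",
)

_STATE_IDS = tuple(s.state_id for s in reconstruction_states()) + ("none",)


@dataclass
class LatentProfile:
    """A respondent's true (latent) evaluation of every card plus noise knobs."""

    participant_id: str
    latent_utility: dict[str, float]
    choice_noise: float = 0.0
    weighting_gamma: float = 1.0
    vas_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.latent_utility = dict(self.latent_utility)
        self.latent_utility.setdefault("death", 0.0)
        if self.latent_utility["death"] != 0.0:
            raise ValueError("latent utility of death must be exactly 0")
        for sid, u in self.latent_utility.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"latent utility of {sid!r} = {u} outside [0, 1]")


def participant_stream(seed: int, index: int, stage: int) -> np.random.Generator:
    """Private RNG stream for one participant and pipeline stage.

    Stages: 0 covariates, 1 latent profile, 2 gamble choices, 3 instruments.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed) % 2**31, index, stage)))


# --------------------------------------------------------------------------- #
# covariates
# --------------------------------------------------------------------------- #
def _censored_mean(mu: float, spec: ContinuousSpec) -> float:
    """Mean of clip(N(mu, sd), lo, hi)."""
    a = (spec.lo - mu) / spec.sd
    b = (spec.hi - mu) / spec.sd
    return (
        spec.lo * norm.cdf(a)
        + spec.hi * norm.sf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        + spec.sd * (norm.pdf(a) - norm.pdf(b))
    )


def _calibrated_mu(spec: ContinuousSpec) -> float:
    """Pre-clip mean whose clipped draw has expectation ``spec.mean``."""
    if spec.sd == 0 or not spec.calibrate_mean:
        return spec.mean
    if spec.mean <= spec.lo or spec.mean >= spec.hi:
        return spec.mean
    lo, hi = spec.mean - 10 * spec.sd, spec.mean + 10 * spec.sd
    return brentq(lambda m: _censored_mean(m, spec) - spec.mean, lo, hi, xtol=1e-10)


def _draw_continuous(rng: np.random.Generator, spec: ContinuousSpec, mu: float) -> float:
    if spec.sd == 0:
        rng.normal()  # keep the stream layout fixed
        return spec.mean
    return float(np.clip(mu + spec.sd * rng.normal(), spec.lo, spec.hi))


def _draw_categorical(u: float, probs: dict[str, float]) -> str:
    levels = list(probs)
    cum = np.cumsum([probs[k] for k in levels])
    return levels[int(np.searchsorted(cum, u, side="right").clip(0, len(levels) - 1))]


def sample_covariates(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the participant covariate table.

    Returns a DataFrame with one row per participant, indexed 0..n-1, with a
    ``participant_id`` column ("P0001", ...) plus the continuous scores and
    categorical characteristics named in the config.
    """
    config.validate()
    mus = {name: _calibrated_mu(spec) for name, spec in config.continuous.items()}
    rows = []
    for i in range(1, config.n_participants + 1):
        rng = participant_stream(config.rng_seed, i, 0)
        row: dict[str, object] = {"participant_id": f"P{i:04d}"}
        z_draws = {name: _draw_continuous(rng, config.continuous[name], mus[name])
                   for name in _CONTINUOUS_ORDER if name in config.continuous}
        row.update(z_draws)
        u = rng.random(len(_CATEGORICAL_ORDER))
        for j, name in enumerate(_CATEGORICAL_ORDER):
            if name in config.categorical:
                row[name] = _draw_categorical(u[j], config.categorical[name])
        rows.append(row)
    df = pd.DataFrame(rows)
    for name in config.categorical:
        if name in df.columns:
            df[name] = pd.Categorical(df[name], categories=list(config.categorical[name]))
    return df


# --------------------------------------------------------------------------- #
# latent profiles
# --------------------------------------------------------------------------- #
def _effect_delta(row: pd.Series, config: GeneratorConfig) -> dict[str, float]:
    """Summed covariate effects per state, on the 0-1 latent scale."""
    delta = {sid: 0.0 for sid in _STATE_IDS}
    for eff in config.effects:
        if eff.covariate in config.continuous:
            z = float(row[eff.covariate]) - config.continuous[eff.covariate].mean
        else:
            z = 1.0 if row[eff.covariate] == eff.level else 0.0
        if z == 0.0:
            continue
        shift = eff.per_point * z / 100.0
        if eff.group == "any":
            targets = [s for s in _STATE_IDS if s != "none"]
        elif eff.group in RECON_MODALITIES:
            targets = [s for s in _STATE_IDS if s.startswith(eff.group + "_")]
        elif eff.group == "none":
            targets = ["none"]
        else:  # explicit state id
            targets = [eff.group]
        for sid in targets:
            delta[sid] += shift
    return delta


def generate_latent_profiles(
    covariates: pd.DataFrame, config: GeneratorConfig
) -> list[LatentProfile]:
    """Build one latent utility profile per covariate row.

    The participant's RNG stream index is parsed from ``participant_id``,
    so profiles do not depend on the order or subset of rows passed in.
    """
    config.validate()
    if len(covariates) == 0:
        raise ValueError("covariates table is empty")
    profiles = []
    for _, row in covariates.iterrows():
        idx = int(str(row["participant_id"]).lstrip("P"))
        rng = participant_stream(config.rng_seed, idx, 1)
        eps = rng.normal(0.0, config.latent_noise_sd or 0.0, size=len(_STATE_IDS))
        u_unexpected = rng.random()
        swap_modality = RECON_MODALITIES[int(rng.random() < 0.5)]
        swap_partner = "fair" if rng.random() < 0.5 else "poor"
        u_equipoise = rng.random()

        delta = _effect_delta(row, config)
        lat = {
            sid: float(np.clip(config.base_utilities[sid] + delta[sid] + e, 0.0, 1.0))
            for sid, e in zip(_STATE_IDS, eps)
        }
        if u_unexpected < config.unexpected_rank_fraction:
            a, b = f"{swap_modality}_excellent", f"{swap_modality}_{swap_partner}"
            lat[a], lat[b] = lat[b], lat[a]
        if u_equipoise < config.equipoise_fraction:
            pool = [s for s in _STATE_IDS if not s.endswith("excellent")]
            centre = float(np.mean([lat[s] for s in pool]))
            keep = 1.0 - config.equipoise_strength
            for s in pool:
                lat[s] = centre + keep * (lat[s] - centre)
        lat["death"] = 0.0
        profiles.append(
            LatentProfile(
                participant_id=str(row["participant_id"]),
                latent_utility=lat,
                choice_noise=config.choice_noise,
                weighting_gamma=config.weighting_gamma,
                vas_noise_sd=config.vas_noise_sd,
            )
        )
    return profiles


def profiles_to_frame(profiles: list[LatentProfile]) -> pd.DataFrame:
    """Long-format table (participant_id, state_id, latent_utility)."""
    records = [
        {"participant_id": p.participant_id, "state_id": sid, "latent_utility": u}
        for p in profiles
        for sid, u in p.latent_utility.items()
    ]
    return pd.DataFrame(records)
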