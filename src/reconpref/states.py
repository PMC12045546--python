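"""Health-state cards.

A respondent evaluates nine post-mastectomy outcomes: four qualities
(excellent, good, fair, poor) of implant-based reconstruction, four of
tissue-based (autologous) reconstruction, and one no-reconstruction state.
For the instruments that need a bottom anchor, a tenth "death" card is
appended.  The deck is case-matched to the respondent's BMI category and
reconstruction laterality in the interview protocol; here those inputs
select nothing visual but are validated so that configuration errors
surface early.
"""

from __future__ import annotations

from dataclasses import dataclass

MODALITIES = ("implant", "tissue", "none", "death")
QUALITIES = ("excellent", "good", "fair", "poor", "not_applicable")
RECON_MODALITIES = ("implant", "tissue")
RECON_QUALITIES = ("excellent", "good", "fair", "poor")
BMI_CATEGORIES = ("normal", "overweight", "obese")
LATERALITIES = ("unilateral", "bilateral")


@dataclass(frozen=True)
class HealthState:
    """One outcome card: a reconstruction modality at a given quality."""

    state_id: str
    modality: str
    quality: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.quality not in QUALITIES:
            raise ValueError(f"unknown quality {self.quality!r}")
        if self.modality in ("none", "death") and self.quality != "not_applicable":
            raise ValueError(
                f"modality {self.modality!r} requires quality 'not_applicable', "
                f"got {self.quality!r}"
            )
        if self.modality in RECON_MODALITIES and self.quality == "not_applicable":
            raise ValueError(f"reconstruction state {self.state_id!r} needs a quality")


DEATH = HealthState("death", "death", "not_applicable")
NO_RECONSTRUCTION = HealthState("none", "none", "not_applicable")


def reconstruction_states() -> tuple[HealthState, ...]:
    """The eight reconstruction cards, implant qualities first."""
    return tuple(
        HealthState(f"{modality}_{quality}", modality, quality)
        for modality in RECON_MODALITIES
        for quality in RECON_QUALITIES
    )


def build_deck(
    bmi_category: str, laterality: str, include_death: bool = False
) -> list[HealthState]:
    """Assemble the ordered card deck for one respondent.

    Parameters
    ----------
    bmi_category : {'normal', 'overweight', 'obese'}
        Weight category the photographic cards are case-matched to.
    laterality : {'unilateral', 'bilateral'}
        Reconstruction plan the cards are case-matched to.
    include_death : bool
        Append the death card (used by the with-death ranking/VAS pass and
        required by the chained standard gamble).

    Returns
    -------
    list of :class:`HealthState`
        Nine states (4 implant, 4 tissue, 1 none), death last if requested.
    """
    if bmi_category not in BMI_CATEGORIES:
        raise ValueError(
            f"invalid bmi_category {bmi_category!r}; expected one of {BMI_CATEGORIES}"
        )
    if laterality not in LATERALITIES:
        raise ValueError(
            f"invalid laterality {laterality!r}; expected one of {LATERALITIES}"
        )
    deck = list(reconstruction_states()) + [NO_RECONSTRUCTION]
    if include_death:
        deck.append(DEATH)
    return deck


def state_ids(deck: list[HealthState]) -> list[str]:
    return [s.state_id for s in deck]


def state_group(state: HealthState) -> str:
    """Option group an outcome belongs to ('implant', 'tissue', 'none', 'death')."""
    return state.modality
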