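"""Words-of-interest scoring: thresholded flagging, category percentages, and
the ranked per-participant issue profile.

A word is "of interest" for a participant when its standardised latency lies
strictly above the chosen z cut-off; the study swept cut-offs 0.5, 1.0, 1.5
and 2.0 and settled on 1.5 for the daily-life rounds, while stressing the
choice is the therapist's to make. The percentage of interest divides the
flagged count by the designed word-list size of that (section, category) —
not the post-filter observed words — so percentages stay comparable across
participants with different outlier counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .cohort_model import (
    DAILY_LIFE_SECTIONS,
    Category,
    FlaggedWord,
    InterestProfile,
    ParticipantMeta,
    Section,
    ValidationError,
    WordList,
)

__all__ = [
    "THRESHOLD_SWEEP",
    "ScoringConfig",
    "flag_words_of_interest",
    "percentage_of_interest",
    "build_interest_profile",
    "cohort_percentage_table",
    "score_cohort",
]

#: The four swept cut-offs.
THRESHOLD_SWEEP: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)


@dataclass
class ScoringConfig:
    """Scoring knobs.

    z_threshold
        Strict cut-off on the standardised latency; default 1.5. Arbitrary by
        design — exposed so a practitioner can set it.
    sections_in_scope
        Sections whose flagged words populate the ranked profile and the
        headline issue count; defaults to the five daily-life domains.
    headline_related_only
        Count only related-category flags in the headline number instead of
        all words of the in-scope sections.
    """

    z_threshold: float = 1.5
    supported_thresholds: tuple[float, ...] = THRESHOLD_SWEEP
    sections_in_scope: tuple[Section, ...] = DAILY_LIFE_SECTIONS
    headline_related_only: bool = False

    def __post_init__(self) -> None:
        if not self.z_threshold > 0:
            raise ValidationError(
                f"z_threshold must be positive, got {self.z_threshold}"
            )
        self.sections_in_scope = tuple(Section(s) for s in self.sections_in_scope)


def flag_words_of_interest(
    z_scores: pd.DataFrame, config: ScoringConfig
) -> list[FlaggedWord]:
    """Return one participant's words with z strictly above the cut-off.

    Sorted z-descending; ties broken by word text ascending so reports are
    bit-for-bit reproducible.
    """
    if z_scores.empty:
        return []
    pids = z_scores["participant_id"].unique()
    if len(pids) > 1:
        raise ValidationError(
            f"z-scores mix {len(pids)} participants; flag one at a time"
        )
    hits = z_scores.loc[z_scores["z"] > config.z_threshold]
    hits = hits.sort_values(
        ["z", "word"], ascending=[False, True], kind="mergesort"
    )
    return [
        FlaggedWord(
            word=r.word,
            section=Section(r.section),
            category=Category(r.category),
            z=float(r.z),
        )
        for r in hits.itertuples(index=False)
    ]


def percentage_of_interest(
    flagged: Iterable[FlaggedWord],
    word_list: WordList,
    section: Section,
    category: Category,
) -> float:
    """Percentage of the (section, category) inventory that was flagged.

    The denominator is the configured word list, so a word removed by the
    slow-latency filter still counts in it.
    """
    section, category = Section(section), Category(category)
    denominator = len(word_list.words_in(section, category))
    if denominator == 0:
        raise ValidationError(
            f"word list has no words in ({section.value}, {category.value}); "
            "percentage undefined"
        )
    n = sum(
        1
        for fw in flagged
        if fw.section is section and fw.category is category
    )
    return 100.0 * n / denominator


def build_interest_profile(
    participant: ParticipantMeta,
    z_scores: pd.DataFrame,
    word_list: WordList,
    config: Optional[ScoringConfig] = None,
) -> InterestProfile:
    """Assemble one participant's issue profile.

    Flags are computed over every section present, percentages cover all
    (section, category) cells of the word list, and the ranked
    ``flagged_words`` list is restricted to the sections in scope (the five
    daily-life domains by default), whose count is the headline "issues"
    number.
    """
    config = config or ScoringConfig()
    sub = z_scores.loc[z_scores["participant_id"] == participant.participant_id]
    all_flagged = flag_words_of_interest(sub, config)
    percentages = {
        (section, category): percentage_of_interest(
            all_flagged, word_list, section, category
        )
        for section in word_list.sections()
        for category in word_list.categories_in(section)
    }
    in_scope = [
        fw
        for fw in all_flagged
        if fw.section in config.sections_in_scope
        and (not config.headline_related_only or fw.category is Category.RELATED)
    ]
    return InterestProfile(
        participant_id=participant.participant_id,
        z_threshold=config.z_threshold,
        flagged_words=in_scope,
        category_percentages=percentages,
    )


def cohort_percentage_table(
    profiles: Iterable[InterestProfile],
) -> pd.DataFrame:
    """Long table participant x section x category -> percentage."""
    rows = [
        (p.participant_id, s.value, c.value, pct)
        for p in profiles
        for (s, c), pct in sorted(
            p.category_percentages.items(),
            key=lambda kv: (kv[0][0].value, kv[0][1].value),
        )
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "section", "category", "percentage"]
    )


def score_cohort(
    z_scores: pd.DataFrame,
    participants: Iterable[ParticipantMeta],
    word_list: WordList,
    config: Optional[ScoringConfig] = None,
) -> tuple[dict[str, InterestProfile], pd.DataFrame]:
    """Score every participant; return profiles and the cohort percentage table.

    Profiles are produced for all participants — including those excluded
    from group analyses — since the individual report is the instrument's
    point.
    """
    config = config or ScoringConfig()
    profiles: dict[str, InterestProfile] = {}
    for participant in participants:
        profiles[participant.participant_id] = build_interest_profile(
            participant, z_scores, word_list, config
        )
    return profiles, cohort_percentage_table(profiles.values())
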