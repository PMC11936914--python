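"""Synthetic emotional-Stroop cohorts with known ground truth.

The study's participant data are personal medical data and are not shared, so
this module generates trial-level datasets with the statistical structure the
analysis assumes: per-participant baseline latency heterogeneity, each word
shown once in red and once in blue, a linear valence x diagnosis effect on
emotion-word latencies, planted high-latency "issue" words for ADHD
participants, ex-Gaussian trial noise (the standard right-skewed
reaction-time model, mean mu + tau), and occasional extreme latencies that
exercise both outlier rules.

Ground truth (planted words, generating coefficients, per-word expected
latencies, injected contamination) is emitted alongside the dataset and is
never consumed by the pipeline under test.

A single global seed drives a hierarchy of per-participant substreams, so a
cohort can be extended with more participants without reshuffling the
existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort_model import (
    DAILY_LIFE_SECTIONS,
    RATED_EMOTION_CATEGORIES,
    Category,
    Diagnosis,
    ParticipantMeta,
    Section,
    ValidationError,
    WordList,
    WordStimulus,
    rescale_valence,
)

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "CohortData",
    "build_word_list",
    "generate_valence_ratings",
    "generate_cohort",
]


@dataclass
class CohortConfig:
    """Generating parameters of the synthetic population.

    Latency model (ms), per participant p, word w::

        E[latency] = mu_ms + baseline_p + section_offset
                     + related_shift_ms * [ADHD and related-category]
                     + b_valence*v + b_diagnosis*d + b_interaction*v*d
                       (rated emotion words; v = the participant's rating)
                     + planted shift (issue words)

    with baseline_p ~ N(0, baseline_sd_ms) and per-trial ex-Gaussian noise
    N(0, sigma_ms) + Exp(tau_ms). The valence-model defaults are the study's
    reported regression coefficients; the planted shift is expressed in
    within-participant word-mean SDs, i.e. sqrt((sigma^2 + tau^2)/2).
    Contamination replaces a trial's latency with a uniform draw from
    4000-8000 ms (slow) or 10-90 ms (fast) at the configured rates.
    """

    n_adhd: int = 60
    n_control: int = 60
    n_excluded_suspected: int = 0
    words_per_domain: int = 10
    emotion_words_per_class: int = 8
    personality_words_per_category: int = 10
    mu_ms: float = 500.0
    sigma_ms: float = 60.0
    tau_ms: float = 100.0
    baseline_sd_ms: float = 80.0
    b_valence: float = 2.68
    b_diagnosis: float = 20.89
    b_interaction: float = -8.36
    related_shift_ms: float = 25.0
    planted_issues_per_adhd: int = 3
    planted_shift_sd: float = 3.0
    plant_in_controls: bool = False
    slow_contamination_rate: float = 0.002
    fast_contamination_rate: float = 0.0005
    rating_noise_sd: float = 0.5
    screener_mean_adhd: float = 14.0
    screener_mean_control: float = 8.0
    screener_sd: float = 3.0
    section_offsets: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adhd + self.n_control + self.n_excluded_suspected <= 0:
            raise ValidationError("cohort must contain at least one participant")
        if min(self.n_adhd, self.n_control, self.n_excluded_suspected) < 0:
            raise ValidationError("participant counts must be >= 0")
        if self.words_per_domain < 3:
            raise ValidationError(
                "words_per_domain must be >= 3 (each domain needs related, "
                "unrelated and distraction words)"
            )
        if self.emotion_words_per_class < 1 or self.personality_words_per_category < 1:
            raise ValidationError("word counts per category must be >= 1")
        for name in (
            "sigma_ms",
            "tau_ms",
            "baseline_sd_ms",
            "rating_noise_sd",
            "screener_sd",
            "slow_contamination_rate",
            "fast_contamination_rate",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.planted_issues_per_adhd < 0:
            raise ValidationError("planted_issues_per_adhd must be >= 0")

    @property
    def daily_life_inventory_size(self) -> int:
        return self.words_per_domain * len(DAILY_LIFE_SECTIONS)

    @property
    def within_participant_sd(self) -> float:
        """SD of a word-mean latency around its expectation (two trials)."""
        return float(np.sqrt((self.sigma_ms**2 + self.tau_ms**2) / 2.0))

    @property
    def planted_shift_ms(self) -> float:
        return self.planted_shift_sd * self.within_participant_sd


@dataclass
class SyntheticTruth:
    """Generator ground truth, segregated from the data under test."""

    planted_words: dict[str, list[str]]
    coefficients: dict[str, float]
    expected_latency: pd.DataFrame
    contaminated_trials: pd.DataFrame
    n_slow_injected: int = 0
    n_fast_injected: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "coefficients": self.coefficients,
            "planted_words": {k: list(v) for k, v in self.planted_words.items()},
            "n_slow_injected": self.n_slow_injected,
            "n_fast_injected": self.n_fast_injected,
            "contaminated_trials": self.contaminated_trials.to_dict("records"),
        }


@dataclass
class CohortData:
    trials: pd.DataFrame
    participants: list[ParticipantMeta]
    word_list: WordList
    truth: SyntheticTruth


def _spread(lo: float, hi: float, n: int) -> np.ndarray:
    if n == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, n)


def build_word_list(config: Optional[CohortConfig] = None) -> WordList:
    """Placeholder stimulus inventory with the study's structure.

    Synthetic tokens stand in for the (Dutch) stimulus words, which are not
    reproduced here; counts per category are configurable. Emotion-section
    words carry 1-7 norm valences spread over class-typical bands (negative
    1.0-2.5, neutral and distraction 3.5-4.5, positive 5.5-7.0); the
    words_per_domain inventory of each daily-life domain is split into
    related / unrelated / distraction words.
    """
    config = config or CohortConfig()
    words: list[WordStimulus] = []
    n = config.personality_words_per_category
    for cat, stem in (
        (Category.RELATED, "adhd_trait"),
        (Category.UNRELATED, "neutral_trait"),
        (Category.DISTRACTION, "distractor_trait"),
    ):
        words += [
            WordStimulus(f"{stem}_{i+1:02d}", Section.PERSONALITY, cat)
            for i in range(n)
        ]
    n = config.emotion_words_per_class
    for cat, stem, lo, hi in (
        (Category.POSITIVE, "positive_emotion", 5.5, 7.0),
        (Category.NEUTRAL, "neutral_emotion", 3.5, 4.5),
        (Category.NEGATIVE, "negative_emotion", 1.0, 2.5),
        (Category.DISTRACTION, "distractor_emotion", 3.5, 4.5),
    ):
        norms = _spread(lo, hi, n)
        words += [
            WordStimulus(f"{stem}_{i+1:02d}", Section.EMOTION, cat, float(norms[i]))
            for i in range(n)
        ]
    w = config.words_per_domain
    n_unrel = n_dist = w // 3
    n_rel = w - n_unrel - n_dist
    for section in DAILY_LIFE_SECTIONS:
        stem = section.value
        words += [
            WordStimulus(f"{stem}_issue_{i+1:02d}", section, Category.RELATED)
            for i in range(n_rel)
        ]
        words += [
            WordStimulus(f"{stem}_neutral_{i+1:02d}", section, Category.UNRELATED)
            for i in range(n_unrel)
        ]
        words += [
            WordStimulus(f"{stem}_distractor_{i+1:02d}", section, Category.DISTRACTION)
            for i in range(n_dist)
        ]
    return WordList(words)


def generate_valence_ratings(
    word_list: WordList,
    rating_noise_sd: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, int]:
    """Draw one participant's -3..+3 integer ratings for the emotion words.

    rating = clip(round(rescaled norm + N(0, noise)), -3, +3): the discrete
    survey instrument around the word's population norm.
    """
    rng = rng if rng is not None else np.random.default_rng()
    ratings: dict[str, int] = {}
    for w in word_list.words_in(Section.EMOTION):
        if w.norm_valence is None:
            raise ValidationError(
                f"emotion word {w.text!r} is missing its 1-7 norm valence"
            )
        raw = rescale_valence(w.norm_valence) + rng.normal(0.0, rating_noise_sd)
        ratings[w.text] = int(np.clip(np.rint(raw), -3, 3))
    return ratings


def _participant_stream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate (trials, participants, word_list, truth) for one cohort.

    The same config (including seed) always yields byte-identical tables.
    Suspected-but-undiagnosed participants are generated with the control
    latency model; they exist to exercise the exclusion contract, not to
    model sub-threshold ADHD.
    """
    word_list = build_word_list(config)
    stimuli = list(word_list)
    n_words = len(stimuli)
    sections = np.array([w.section.value for w in stimuli])
    related_mask = np.array([w.category is Category.RELATED for w in stimuli])
    rated_mask = np.array(
        [
            w.section is Section.EMOTION and w.category in RATED_EMOTION_CATEGORIES
            for w in stimuli
        ]
    )
    offsets = np.zeros(n_words)
    if config.section_offsets:
        off = {Section(k).value: float(v) for k, v in config.section_offsets.items()}
        offsets = np.array([off.get(s, 0.0) for s in sections])
    domain_related: dict[str, list[int]] = {
        s.value: [
            i
            for i, w in enumerate(stimuli)
            if w.section is s and w.category is Category.RELATED
        ]
        for s in DAILY_LIFE_SECTIONS
    }

    roster = (
        [Diagnosis.ADHD] * config.n_adhd
        + [Diagnosis.CONTROL] * config.n_control
        + [Diagnosis.EXCLUDED_SUSPECTED] * config.n_excluded_suspected
    )
    participants: list[ParticipantMeta] = []
    planted_truth: dict[str, list[str]] = {}
    trial_frames: list[pd.DataFrame] = []
    expected_frames: list[pd.DataFrame] = []
    contaminated_rows: list[tuple] = []
    n_slow = n_fast = 0
    word_texts = np.array([w.text for w in stimuli])

    for idx, diagnosis in enumerate(roster):
        pid = f"P{idx + 1:04d}"
        rng = _participant_stream(config.seed, idx)
        baseline = rng.normal(0.0, config.baseline_sd_ms)
        is_adhd = diagnosis is Diagnosis.ADHD
        screener_mu = (
            config.screener_mean_adhd if is_adhd else config.screener_mean_control
        )
        screener = float(max(0.0, rng.normal(screener_mu, config.screener_sd)))
        ratings = generate_valence_ratings(
            word_list, config.rating_noise_sd, rng
        )

        planted_idx: list[int] = []
        if (is_adhd or config.plant_in_controls) and config.planted_issues_per_adhd:
            # one issue per daily-life domain first (distinct life areas),
            # cycling through shuffled domains if k exceeds their number
            domains = list(domain_related)
            rng.shuffle(domains)
            pools = {d: rng.permutation(domain_related[d]).tolist() for d in domains}
            k = config.planted_issues_per_adhd
            round_robin = 0
            while len(planted_idx) < k:
                d = domains[round_robin % len(domains)]
                round_robin += 1
                if pools[d]:
                    planted_idx.append(pools[d].pop())
                elif all(not p for p in pools.values()):
                    raise ValidationError(
                        "planted_issues_per_adhd exceeds the related daily-life "
                        "inventory"
                    )
        planted_mask = np.zeros(n_words, dtype=bool)
        planted_mask[planted_idx] = True

        v = np.array([float(ratings.get(w, 0)) for w in word_texts])
        d = 1.0 if is_adhd else 0.0
        expected = (
            config.mu_ms
            + baseline
            + offsets
            + config.related_shift_ms * (related_mask & is_adhd)
            + rated_mask
            * (config.b_valence * v + config.b_diagnosis * d + config.b_interaction * v * d)
            + config.planted_shift_ms * planted_mask
        )

        # two presentations per word: red then blue, later shuffled
        exp2 = np.repeat(expected, 2)
        colors = np.tile(["red", "blue"], n_words)
        latency = (
            exp2
            + rng.normal(0.0, config.sigma_ms, size=2 * n_words)
            + rng.exponential(config.tau_ms, size=2 * n_words)
            if (config.sigma_ms > 0 or config.tau_ms > 0)
            else exp2.copy()
        )
        u = rng.random(2 * n_words)
        slow = u < config.slow_contamination_rate
        fast = (~slow) & (
            u < config.slow_contamination_rate + config.fast_contamination_rate
        )
        if slow.any():
            latency[slow] = rng.uniform(4000.0, 8000.0, size=int(slow.sum()))
        if fast.any():
            latency[fast] = rng.uniform(10.0, 90.0, size=int(fast.sum()))
        n_slow += int(slow.sum())
        n_fast += int(fast.sum())
        words2 = np.repeat(word_texts, 2)
        sections2 = np.repeat(sections, 2)
        for kind, mask in (("slow", slow), ("fast", fast)):
            for j in np.flatnonzero(mask):
                contaminated_rows.append((pid, words2[j], colors[j], kind))

        order = rng.permutation(2 * n_words)
        frame = pd.DataFrame(
            {
                "participant_id": pid,
                "section": sections2[order],
                "word": words2[order],
                "ink_color": colors[order],
                "latency_ms": latency[order],
                "trial_index": np.arange(2 * n_words),
            }
        )
        trial_frames.append(frame)
        expected_frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "word": word_texts,
                    "section": sections,
                    "expected_ms": expected,
                }
            )
        )
        planted_truth[pid] = [str(word_texts[i]) for i in sorted(planted_idx)]
        participants.append(
            ParticipantMeta(
                participant_id=pid,
                diagnosis=diagnosis,
                screener_score=screener,
                valence_ratings=ratings,
            )
        )

    trials = pd.concat(trial_frames, ignore_index=True)
    truth = SyntheticTruth(
        planted_words=planted_truth,
        coefficients={
            "mu_ms": config.mu_ms,
            "b_valence": config.b_valence,
            "b_diagnosis": config.b_diagnosis,
            "b_interaction": config.b_interaction,
            "related_shift_ms": config.related_shift_ms,
            "planted_shift_ms": config.planted_shift_ms,
        },
        expected_latency=pd.concat(expected_frames, ignore_index=True),
        contaminated_trials=pd.DataFrame(
            contaminated_rows,
            columns=["participant_id", "word", "ink_color", "kind"],
        ),
        n_slow_injected=n_slow,
        n_fast_injected=n_fast,
        seed=config.seed,
    )
    return CohortData(
        trials=trials, participants=participants, word_list=word_list, truth=truth
    )
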