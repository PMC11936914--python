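"""Domain types and file IO for emotional-Stroop cohorts.

The experiment presents a participant with words in seven rounds ("sections"):
one on ADHD personality traits, one on emotion words, and five on daily-life
domains (work, relationships, social connections, hobbies, self-image). Each
word is shown once in red and once in blue ink and the response latency of
naming the ink colour is recorded. These types carry that structure from raw
trial logs through to the per-participant "words of interest" report.
"""

from __future__ import annotations

import enum
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "Section",
    "Category",
    "Diagnosis",
    "InkColor",
    "DAILY_LIFE_SECTIONS",
    "EMOTION_CATEGORIES",
    "RATED_EMOTION_CATEGORIES",
    "NON_EMOTION_CATEGORIES",
    "TRIAL_COLUMNS",
    "EmostroopError",
    "ValidationError",
    "WordStimulus",
    "WordList",
    "TrialRecord",
    "ParticipantMeta",
    "FlaggedWord",
    "InterestProfile",
    "rescale_valence",
    "read_word_list",
    "write_word_list",
    "read_trial_log",
    "write_trial_log",
    "trials_to_frame",
    "frame_to_trials",
    "as_trial_frame",
    "read_participants",
    "write_participants",
    "write_report",
    "read_report",
]


class EmostroopError(Exception):
    """Base class for all package errors."""


class ValidationError(EmostroopError, ValueError):
    """Raised when an input record, file or argument violates a contract."""


class Section(str, enum.Enum):
    PERSONALITY = "personality"
    EMOTION = "emotion"
    WORK = "work"
    RELATIONSHIPS = "relationships"
    SOCIAL = "social"
    HOBBY = "hobby"
    SELF_IMAGE = "self_image"


class Category(str, enum.Enum):
    RELATED = "related"
    UNRELATED = "unrelated"
    DISTRACTION = "distraction"
    POSITIVE = "positive"
    NEUTRAL = "neutral"
    NEGATIVE = "negative"


class Diagnosis(str, enum.Enum):
    ADHD = "adhd"
    CONTROL = "control"
    EXCLUDED_SUSPECTED = "excluded_suspected"


class InkColor(str, enum.Enum):
    RED = "red"
    BLUE = "blue"


DAILY_LIFE_SECTIONS: tuple[Section, ...] = (
    Section.WORK,
    Section.RELATIONSHIPS,
    Section.SOCIAL,
    Section.HOBBY,
    Section.SELF_IMAGE,
)

#: Categories legal in the emotion section.
EMOTION_CATEGORIES: tuple[Category, ...] = (
    Category.POSITIVE,
    Category.NEUTRAL,
    Category.NEGATIVE,
    Category.DISTRACTION,
)

#: Emotion categories whose words participants rate on the -3..+3 scale and
#: which enter the valence regression.
RATED_EMOTION_CATEGORIES: tuple[Category, ...] = (
    Category.POSITIVE,
    Category.NEUTRAL,
    Category.NEGATIVE,
)

NON_EMOTION_CATEGORIES: tuple[Category, ...] = (
    Category.RELATED,
    Category.UNRELATED,
    Category.DISTRACTION,
)

TRIAL_COLUMNS = (
    "participant_id",
    "section",
    "word",
    "ink_color",
    "latency_ms",
    "trial_index",
)


def _norm_text(text: str) -> str:
    return unicodedata.normalize("NFC", text).strip()


def rescale_valence(norm_value: float) -> float:
    """Map a 1-7 valence-norm score onto the -3..+3 participant rating scale.

    The linear map sends the 1-7 midpoint 4 to 0, so the neutral selection
    band 3.5-4.5 lands on -0.5..+0.5.
    """
    if not (1.0 <= norm_value <= 7.0):
        raise ValidationError(
            f"norm valence {norm_value!r} outside the 1-7 scale"
        )
    return float(norm_value) - 4.0


@dataclass(frozen=True)
class WordStimulus:
    """One stimulus word with its section and category assignment."""

    text: str
    section: Section
    category: Category
    norm_valence: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "text", _norm_text(self.text))
        object.__setattr__(self, "section", Section(self.section))
        object.__setattr__(self, "category", Category(self.category))
        if not self.text:
            raise ValidationError("stimulus text must be non-empty")
        if self.section is Section.EMOTION:
            if self.category not in EMOTION_CATEGORIES:
                raise ValidationError(
                    f"emotion-section word {self.text!r} has category "
                    f"{self.category.value!r}; expected one of "
                    f"{[c.value for c in EMOTION_CATEGORIES]}"
                )
        elif self.category not in NON_EMOTION_CATEGORIES:
            raise ValidationError(
                f"{self.section.value}-section word {self.text!r} has category "
                f"{self.category.value!r}; expected one of "
                f"{[c.value for c in NON_EMOTION_CATEGORIES]}"
            )
        if self.norm_valence is not None and not (1.0 <= self.norm_valence <= 7.0):
            raise ValidationError(
                f"norm_valence {self.norm_valence} of {self.text!r} "
                "outside the 1-7 scale"
            )


class WordList:
    """The configured stimulus inventory, indexed by section and word."""

    def __init__(self, words: Iterable[WordStimulus]):
        self._words: list[WordStimulus] = list(words)
        self._index: dict[tuple[Section, str], WordStimulus] = {}
        for w in self._words:
            key = (w.section, w.text)
            if key in self._index:
                raise ValidationError(
                    f"duplicate word {w.text!r} in section {w.section.value!r}"
                )
            self._index[key] = w

    def __len__(self) -> int:
        return len(self._words)

    def __iter__(self):
        return iter(self._words)

    def __eq__(self, other) -> bool:
        return isinstance(other, WordList) and self._words == other._words

    def lookup(self, section: Union[Section, str], word: str) -> WordStimulus:
        key = (Section(section), _norm_text(word))
        try:
            return self._index[key]
        except KeyError:
            raise ValidationError(
                f"word {word!r} not in section {Section(section).value!r} "
                "of the word list"
            ) from None

    def __contains__(self, key: tuple[Union[Section, str], str]) -> bool:
        section, word = key
        return (Section(section), _norm_text(word)) in self._index

    def words_in(
        self,
        section: Union[Section, str],
        category: Optional[Union[Category, str]] = None,
    ) -> list[WordStimulus]:
        section = Section(section)
        if category is not None:
            category = Category(category)
        return [
            w
            for w in self._words
            if w.section is section and (category is None or w.category is category)
        ]

    def sections(self) -> list[Section]:
        seen: dict[Section, None] = {}
        for w in self._words:
            seen.setdefault(w.section, None)
        return list(seen)

    def categories_in(self, section: Union[Section, str]) -> list[Category]:
        seen: dict[Category, None] = {}
        for w in self.words_in(section):
            seen.setdefault(w.category, None)
        return list(seen)

    def emotion_words(self, rated_only: bool = False) -> list[WordStimulus]:
        cats = RATED_EMOTION_CATEGORIES if rated_only else EMOTION_CATEGORIES
        return [
            w
            for w in self._words
            if w.section is Section.EMOTION and w.category in cats
        ]

    def daily_life_words(self) -> list[WordStimulus]:
        return [w for w in self._words if w.section in DAILY_LIFE_SECTIONS]

    def to_records(self) -> list[dict]:
        return [
            {
                "text": w.text,
                "section": w.section.value,
                "category": w.category.value,
                "norm_valence": w.norm_valence,
            }
            for w in self._words
        ]

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "WordList":
        return cls(
            WordStimulus(
                text=r["text"],
                section=r["section"],
                category=r["category"],
                norm_valence=r.get("norm_valence"),
            )
            for r in records
        )


def read_word_list(path: Union[str, Path]) -> WordList:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"word list file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise ValidationError(f"word list {path} must be a JSON array")
    return WordList.from_records(records)


def write_word_list(word_list: WordList, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(word_list.to_records(), fh, indent=1, sort_keys=True)
        fh.write("\n")


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation: a word in one ink colour, with its latency."""

    participant_id: str
    word: str
    section: Section
    ink_color: InkColor
    latency_ms: float
    trial_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "section", Section(self.section))
        object.__setattr__(self, "ink_color", InkColor(self.ink_color))
        if not (self.latency_ms > 0 and self.latency_ms == self.latency_ms):
            raise ValidationError(
                f"latency must be a finite positive number of milliseconds, "
                f"got {self.latency_ms!r}"
            )


@dataclass
class ParticipantMeta:
    """Per-participant metadata consumed by the group models.

    ``excluded_suspected`` marks participants who self-reported possible
    undiagnosed ADHD; they keep their individual report but never enter the
    group-level models.
    """

    participant_id: str
    diagnosis: Diagnosis
    screener_score: float = 0.0
    valence_ratings: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diagnosis = Diagnosis(self.diagnosis)
        if self.screener_score < 0:
            raise ValidationError(
                f"screener score of {self.participant_id} must be >= 0"
            )
        for word, rating in self.valence_ratings.items():
            if not (-3 <= int(rating) <= 3):
                raise ValidationError(
                    f"valence rating {rating!r} for {word!r} outside -3..+3"
                )

    @property
    def in_group_analysis(self) -> bool:
        return self.diagnosis is not Diagnosis.EXCLUDED_SUSPECTED


@dataclass(frozen=True)
class FlaggedWord:
    word: str
    section: Section
    category: Category
    z: float


@dataclass
class InterestProfile:
    """Per-participant issue report: flagged words plus category percentages.

    ``flagged_words`` holds the daily-life words whose standardised latency
    exceeded the threshold, ranked slowest-first; ``category_percentages``
    covers every (section, category) of the word list, with the configured
    inventory (not the post-filter observed words) as denominator.
    """

    participant_id: str
    z_threshold: float
    flagged_words: list[FlaggedWord]
    category_percentages: dict[tuple[Section, Category], float]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.flagged_words, self.flagged_words[1:]):
            if cur.z > prev.z:
                raise ValidationError("flagged_words must be sorted z-descending")
        for fw in self.flagged_words:
            if not fw.z > self.z_threshold:
                raise ValidationError(
                    f"flagged word {fw.word!r} has z {fw.z} <= threshold "
                    f"{self.z_threshold}"
                )
        for key, pct in self.category_percentages.items():
            if not (0.0 <= pct <= 100.0):
                raise ValidationError(f"percentage {pct} for {key} outside 0-100")

    @property
    def n_issues(self) -> int:
        """Headline issue count: flagged words in the five daily-life domains."""
        return sum(
            1 for fw in self.flagged_words if fw.section in DAILY_LIFE_SECTIONS
        )


# ---------------------------------------------------------------------------
# Trial-log IO (CSV, UTF-8, header row mandatory, one trial per row)
# ---------------------------------------------------------------------------

def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        (
            t.participant_id,
            t.section.value,
            t.word,
            t.ink_color.value,
            float(t.latency_ms),
            int(t.trial_index),
        )
        for t in trials
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            participant_id=str(r.participant_id),
            word=str(r.word),
            section=r.section,
            ink_color=r.ink_color,
            latency_ms=float(r.latency_ms),
            trial_index=int(r.trial_index),
        )
        for r in frame.itertuples(index=False)
    ]


def as_trial_frame(trials) -> pd.DataFrame:
    """Accept either a trial DataFrame or an iterable of TrialRecord."""
    if isinstance(trials, pd.DataFrame):
        missing = set(TRIAL_COLUMNS) - set(trials.columns)
        if missing:
            raise ValidationError(f"trial table missing columns: {sorted(missing)}")
        return trials
    return trials_to_frame(trials)


def _validate_trial_frame(frame: pd.DataFrame, word_list: WordList, origin: str) -> None:
    lat = pd.to_numeric(frame["latency_ms"], errors="coerce")
    bad = frame.index[~(lat > 0) | ~lat.notna()]
    if len(bad):
        i = int(bad[0])
        raise ValidationError(
            f"{origin}: row {i + 2} has non-numeric or non-positive latency "
            f"{frame.loc[i, 'latency_ms']!r}"
        )
    for i, (section, word) in enumerate(zip(frame["section"], frame["word"])):
        try:
            Section(section)
        except ValueError:
            raise ValidationError(
                f"{origin}: row {i + 2} has unknown section {section!r}"
            ) from None
        if (section, word) not in word_list:
            raise ValidationError(
                f"{origin}: row {i + 2} word {word!r} not in section "
                f"{section!r} of the word list"
            )
    dup = frame.duplicated(subset=["participant_id", "word", "ink_color"], keep=False)
    if dup.any():
        i = int(frame.index[dup][0])
        raise ValidationError(
            f"{origin}: duplicate (participant, word, ink colour) triple "
            f"({frame.loc[i, 'participant_id']!r}, {frame.loc[i, 'word']!r}, "
            f"{frame.loc[i, 'ink_color']!r}) starting at row {i + 2}"
        )


def read_trial_log(path: Union[str, Path], word_list: WordList) -> list[TrialRecord]:
    """Read and validate a CSV trial log against the word list.

    Row order is preserved in ``trial_index`` when the file carries no
    explicit index column.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"trial log not found: {path}")
    frame = pd.read_csv(path, dtype={"participant_id": str, "word": str})
    required = set(TRIAL_COLUMNS) - {"trial_index"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if "trial_index" not in frame.columns:
        frame["trial_index"] = range(len(frame))
    frame["word"] = frame["word"].map(_norm_text)
    _validate_trial_frame(frame, word_list, str(path))
    return frame_to_trials(frame[list(TRIAL_COLUMNS)])


def write_trial_log(trials, path: Union[str, Path]) -> None:
    frame = as_trial_frame(trials)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Participant metadata IO
# ---------------------------------------------------------------------------

def read_participants(
    meta_path: Union[str, Path],
    ratings_path: Optional[Union[str, Path]] = None,
    word_list: Optional[WordList] = None,
) -> list[ParticipantMeta]:
    """Read participant metadata and the companion long-format ratings CSV."""
    meta_path = Path(meta_path)
    if not meta_path.exists():
        raise ValidationError(f"participant metadata not found: {meta_path}")
    meta = pd.read_csv(meta_path, dtype={"participant_id": str})
    ratings: dict[str, dict[str, int]] = {}
    if ratings_path is not None:
        rframe = pd.read_csv(ratings_path, dtype={"participant_id": str, "word": str})
        for r in rframe.itertuples(index=False):
            word = _norm_text(str(r.word))
            if word_list is not None and (Section.EMOTION, word) not in word_list:
                raise ValidationError(
                    f"rating for {word!r} of participant {r.participant_id}: "
                    "not an emotion-section word"
                )
            ratings.setdefault(str(r.participant_id), {})[word] = int(r.rating)
    out = []
    for r in meta.itertuples(index=False):
        pid = str(r.participant_id)
        out.append(
            ParticipantMeta(
                participant_id=pid,
                diagnosis=Diagnosis(str(r.diagnosis)),
                screener_score=float(r.screener_score),
                valence_ratings=ratings.get(pid, {}),
            )
        )
    return out


def write_participants(
    participants: Sequence[ParticipantMeta],
    meta_path: Union[str, Path],
    ratings_path: Optional[Union[str, Path]] = None,
) -> None:
    meta = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "diagnosis": [p.diagnosis.value for p in participants],
            "screener_score": [p.screener_score for p in participants],
        }
    )
    meta.to_csv(meta_path, index=False)
    if ratings_path is not None:
        rows = [
            (p.participant_id, word, rating)
            for p in participants
            for word, rating in sorted(p.valence_ratings.items())
        ]
        pd.DataFrame(rows, columns=["participant_id", "word", "rating"]).to_csv(
            ratings_path, index=False
        )


# ---------------------------------------------------------------------------
# Interest-profile reports (JSON)
# ---------------------------------------------------------------------------

def write_report(
    profile: InterestProfile,
    path: Union[str, Path],
    provenance: Optional[Mapping] = None,
) -> None:
    """Write the per-participant issue report as JSON.

    Flagged words are listed slowest-first — the ranking a therapist would
    read top-down. ``provenance`` (input file, config hash, seed) is embedded
    verbatim for reproducibility.
    """
    payload = {
        "participant_id": profile.participant_id,
        "z_threshold": profile.z_threshold,
        "n_issues": profile.n_issues,
        "flagged_words": [
            {
                "word": fw.word,
                "section": fw.section.value,
                "category": fw.category.value,
                "z": fw.z,
            }
            for fw in profile.flagged_words
        ],
        "category_percentages": [
            {"section": s.value, "category": c.value, "percentage": pct}
            for (s, c), pct in sorted(
                profile.category_percentages.items(),
                key=lambda kv: (kv[0][0].value, kv[0][1].value),
            )
        ],
        "provenance": dict(provenance) if provenance else {},
    }
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise EmostroopError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: Union[str, Path]) -> InterestProfile:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return InterestProfile(
        participant_id=payload["participant_id"],
        z_threshold=float(payload["z_threshold"]),
        flagged_words=[
            FlaggedWord(
                word=fw["word"],
                section=Section(fw["section"]),
                category=Category(fw["category"]),
                z=float(fw["z"]),
            )
            for fw in payload["flagged_words"]
        ],
        category_percentages={
            (Section(e["section"]), Category(e["category"])): float(e["percentage"])
            for e in payload["category_percentages"]
        },
    )
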