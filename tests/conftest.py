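import numpy as np
import pandas as pd
import pytest

from emostroop import (
    Category,
    CohortConfig,
    Section,
    WordList,
    WordStimulus,
    build_word_list,
)


@pytest.fixture(scope="session")
def word_list() -> WordList:
    """Default synthetic inventory: 30 personality, 32 emotion, 50 daily-life."""
    return build_word_list(CohortConfig())


@pytest.fixture
def tiny_word_list() -> WordList:
    return WordList(
        [
            WordStimulus("forgetful", Section.PERSONALITY, Category.RELATED),
            WordStimulus("tidy", Section.PERSONALITY, Category.UNRELATED),
            WordStimulus("lamp", Section.PERSONALITY, Category.DISTRACTION),
            WordStimulus("deadline", Section.WORK, Category.RELATED),
            WordStimulus("printer", Section.WORK, Category.UNRELATED),
            WordStimulus("cloud", Section.WORK, Category.DISTRACTION),
            WordStimulus("joy", Section.EMOTION, Category.POSITIVE, 6.5),
            WordStimulus("table", Section.EMOTION, Category.NEUTRAL, 4.0),
            WordStimulus("grief", Section.EMOTION, Category.NEGATIVE, 1.5),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_trials(rows) -> pd.DataFrame:
    """Rows: (pid, section, word, color, latency[, index])."""
    out = []
    for i, row in enumerate(rows):
        pid, section, word, color, latency = row[:5]
        idx = row[5] if len(row) > 5 else i
        out.append((pid, section, word, color, float(latency), idx))
    return pd.DataFrame(
        out,
        columns=[
            "participant_id",
            "section",
            "word",
            "ink_color",
            "latency_ms",
            "trial_index",
        ],
    )
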