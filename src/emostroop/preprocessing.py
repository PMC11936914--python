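"""Latency derivation: fast-trial filter, red/blue averaging, slow-word filter,
within-participant standardisation.

The pipeline order is fixed and auditable:

1. drop raw trials with latency < ``min_ms`` (anticipatory key presses),
2. average each word's red and blue presentations into one mean latency,
3. remove word means > ``max_ms`` (lapses / distraction),
4. z-score word means within each participant, by default separately per
   section, because mean latency varies a lot between participants and rounds.

Both cut-offs read "smaller/larger than" strictly: a trial at exactly the
boundary is kept. Each stage reports its in/out counts in a
:class:`PreprocessAudit` and logs them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import ValidationError, WordList, as_trial_frame

logger = logging.getLogger(__name__)

__all__ = [
    "WORD_LATENCY_COLUMNS",
    "ZSCORE_COLUMNS",
    "PreprocessingError",
    "ZeroVarianceError",
    "GroupTooSmallError",
    "PreprocessAudit",
    "PreprocessResult",
    "filter_fast_trials",
    "average_color_latencies",
    "filter_slow_word_latencies",
    "zscore_within_participant",
    "preprocess",
]

WORD_LATENCY_COLUMNS = (
    "participant_id",
    "word",
    "section",
    "category",
    "mean_latency_ms",
    "n_colors_used",
)

ZSCORE_COLUMNS = ("participant_id", "word", "section", "category", "z")


class PreprocessingError(ValidationError):
    """Raised when a preprocessing contract is violated."""


class ZeroVarianceError(PreprocessingError):
    """All word latencies equal within a standardisation group."""


class GroupTooSmallError(PreprocessingError):
    """Too few words in a standardisation group for a meaningful z-score."""


@dataclass
class PreprocessAudit:
    """Counts removed per rule, mirroring the study's outlier report."""

    n_trials_in: int = 0
    n_fast_dropped: int = 0
    n_word_means: int = 0
    n_slow_dropped: int = 0
    n_single_color: int = 0
    n_zscored: int = 0

    def log(self) -> None:
        logger.info(
            "preprocess: %d trials in, %d fast trials (<min) dropped, "
            "%d word means (%d single-colour), %d slow means (>max) removed, "
            "%d z-scored",
            self.n_trials_in,
            self.n_fast_dropped,
            self.n_word_means,
            self.n_single_color,
            self.n_slow_dropped,
            self.n_zscored,
        )


@dataclass
class PreprocessResult:
    word_latencies: pd.DataFrame
    z_scores: pd.DataFrame
    audit: PreprocessAudit = field(default_factory=PreprocessAudit)
    dropped_trials: pd.DataFrame | None = None
    dropped_words: pd.DataFrame | None = None


def filter_fast_trials(trials, min_ms: float = 100.0):
    """Partition trials into (kept, dropped) at the fast cut-off.

    A trial is dropped iff its latency is strictly smaller than ``min_ms``;
    exactly-boundary trials are kept. The dropped partition is returned for
    audit logging, never silently discarded.
    """
    if not min_ms > 0:
        raise PreprocessingError(f"min_ms must be positive, got {min_ms}")
    frame = as_trial_frame(trials)
    fast = frame["latency_ms"] < min_ms
    return frame.loc[~fast].copy(), frame.loc[fast].copy()


def average_color_latencies(trials, word_list: WordList) -> pd.DataFrame:
    """Collapse red/blue presentations into one mean latency per word.

    With both colours surviving the fast filter the mean is
    (lat_red + lat_blue)/2 and ``n_colors_used`` is 2; with one survivor the
    word keeps that single latency (``n_colors_used`` 1) rather than being
    dropped, preserving coverage of the issue inventory; with none the word is
    absent from the output.
    """
    frame = as_trial_frame(trials)
    if frame.duplicated(subset=["participant_id", "word", "ink_color"]).any():
        dup = frame[frame.duplicated(subset=["participant_id", "word", "ink_color"])]
        r = dup.iloc[0]
        raise PreprocessingError(
            f"duplicate colour {r['ink_color']!r} for word {r['word']!r} of "
            f"participant {r['participant_id']!r}"
        )
    if frame.empty:
        return pd.DataFrame(columns=list(WORD_LATENCY_COLUMNS))
    grouped = (
        frame.groupby(["participant_id", "section", "word"], sort=True, observed=True)[
            "latency_ms"
        ]
        .agg(mean_latency_ms="mean", n_colors_used="size")
        .reset_index()
    )
    grouped["category"] = [
        word_list.lookup(s, w).category.value
        for s, w in zip(grouped["section"], grouped["word"])
    ]
    return grouped[list(WORD_LATENCY_COLUMNS)]


def filter_slow_word_latencies(latencies: pd.DataFrame, max_ms: float = 2000.0):
    """Partition word means into (kept, dropped) at the slow cut-off.

    A word mean is removed iff it is strictly larger than ``max_ms``.
    """
    slow = latencies["mean_latency_ms"] > max_ms
    return latencies.loc[~slow].copy(), latencies.loc[slow].copy()


def zscore_within_participant(
    latencies: pd.DataFrame,
    scope: str = "per_section",
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Standardise word-mean latencies within each participant.

    ``scope='per_section'`` (default) standardises each Stroop round
    separately, since rounds differ in difficulty and fatigue;
    ``scope='all_sections'`` pools a participant's full inventory for
    sensitivity analysis. Sample SD (n-1 denominator) is used.
    """
    if scope not in ("per_section", "all_sections"):
        raise PreprocessingError(f"unknown z-scoring scope {scope!r}")
    keys = ["participant_id"] + (["section"] if scope == "per_section" else [])
    if latencies.empty:
        return pd.DataFrame(columns=list(ZSCORE_COLUMNS))
    g = latencies.groupby(keys, sort=False, observed=True)["mean_latency_ms"]
    sizes = g.transform("size")
    if (sizes < min_group_size).any():
        bad = latencies.loc[sizes < min_group_size].iloc[0]
        raise GroupTooSmallError(
            f"participant {bad['participant_id']!r} has fewer than "
            f"{min_group_size} words in a standardisation group"
        )
    m = g.transform("mean")
    s = g.transform("std", ddof=1)
    if (s <= 0).any() or s.isna().any():
        bad = latencies.loc[(s <= 0) | s.isna()].iloc[0]
        raise ZeroVarianceError(
            f"zero latency variance for participant {bad['participant_id']!r}"
            + (f" in section {bad['section']!r}" if scope == "per_section" else "")
        )
    out = latencies.copy()
    out["z"] = (latencies["mean_latency_ms"] - m) / s
    return out[list(ZSCORE_COLUMNS)].reset_index(drop=True)


def preprocess(
    trials,
    word_list: WordList,
    min_ms: float = 100.0,
    max_ms: float = 2000.0,
    scope: str = "per_section",
    min_group_size: int = 3,
) -> PreprocessResult:
    """Run the full latency pipeline and return tables plus the audit."""
    frame = as_trial_frame(trials)
    if not max_ms > min_ms:
        raise PreprocessingError(
            f"max_ms ({max_ms}) must exceed min_ms ({min_ms})"
        )
    kept, fast_dropped = filter_fast_trials(frame, min_ms=min_ms)
    latencies = average_color_latencies(kept, word_list)
    latencies, slow_dropped = filter_slow_word_latencies(latencies, max_ms=max_ms)
    z_scores = zscore_within_participant(
        latencies, scope=scope, min_group_size=min_group_size
    )
    audit = PreprocessAudit(
        n_trials_in=len(frame),
        n_fast_dropped=len(fast_dropped),
        n_word_means=len(latencies) + len(slow_dropped),
        n_slow_dropped=len(slow_dropped),
        n_single_color=int((latencies["n_colors_used"] == 1).sum())
        if len(latencies)
        else 0,
        n_zscored=len(z_scores),
    )
    audit.log()
    return PreprocessResult(
        word_latencies=latencies.reset_index(drop=True),
        z_scores=z_scores,
        audit=audit,
        dropped_trials=fast_dropped.reset_index(drop=True),
        dropped_words=slow_dropped.reset_index(drop=True),
    )
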