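"""Group-level models: two-way ANOVA on percentages of interest, moderated
valence regression on emotion-word latencies, and the logistic diagnosis
classifier.

The bespoke content of the pipeline is the derivation of the tables these
models consume; the fits themselves delegate to statsmodels (OLS / type-II
ANOVA / maximum-likelihood logit), which independent brute-force oracles
cross-check in the test suite.

Diagnosis is coded control = 0, ADHD = 1 throughout, so a positive diagnosis
coefficient reads "ADHD slower". Logistic predictors arrive on the 0-100
percentage scale and are refit internally as proportions (0-1); reported odds
ratios are therefore per full-scale change, which is the scale on which the
study's very large odds ratios live.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort_model import (
    DAILY_LIFE_SECTIONS,
    Category,
    Diagnosis,
    ParticipantMeta,
    RATED_EMOTION_CATEGORIES,
    Section,
    ValidationError,
    WordList,
)

__all__ = [
    "AnalysisError",
    "TermStats",
    "AnovaResult",
    "ModeratedRegressionResult",
    "PredictorStats",
    "LogisticResult",
    "ConfusionMetrics",
    "confusion_metrics",
    "diagnosis_codes",
    "anova_words_of_interest",
    "moderated_regression",
    "logistic_diagnosis_model",
    "emotion_observations",
    "logistic_predictor_table",
    "analyze_cohort",
]


class AnalysisError(ValidationError):
    """Raised when a group model's preconditions are not met."""


def diagnosis_codes(
    participants: Iterable[ParticipantMeta],
) -> dict[str, int]:
    """Map participant id -> 0/1 diagnosis code, dropping excluded subjects."""
    return {
        p.participant_id: int(p.diagnosis is Diagnosis.ADHD)
        for p in participants
        if p.in_group_analysis
    }


# ---------------------------------------------------------------------------
# Two-way ANOVA on percentages of interest (Stroop round x diagnosis)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermStats:
    df: int
    F: float
    partial_eta_sq: float
    p: float


@dataclass
class AnovaResult:
    """diagnosis x category ANOVA of the percentage of words of interest."""

    threshold_used: float
    terms: dict[str, TermStats]
    r_squared: float
    df_resid: int
    n_participants: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold_used,
            "r_squared": self.r_squared,
            "df_resid": self.df_resid,
            "n_participants": self.n_participants,
            "terms": {
                name: {
                    "df": t.df,
                    "F": t.F,
                    "partial_eta_sq": t.partial_eta_sq,
                    "p": t.p,
                }
                for name, t in self.terms.items()
            },
        }


def anova_words_of_interest(
    percentages: pd.DataFrame,
    labels: Mapping[str, int],
    threshold: float,
) -> AnovaResult:
    """Two-way ANOVA with interaction on the percentage of words of interest.

    ``percentages`` is long-format with columns participant_id, category,
    percentage — one section's categories per participant. Type-II sums of
    squares are used: the design is balanced within participant (everyone
    contributes all categories) and imbalance arises only between diagnosis
    groups, where type II is conventional. Partial eta squared is
    SS_term / (SS_term + SS_error).
    """
    data = percentages.copy()
    data["diagnosis"] = data["participant_id"].map(labels)
    data = data.dropna(subset=["diagnosis"])
    if data.empty:
        raise AnalysisError("no labelled participants in the percentage table")
    groups = data.groupby("diagnosis", observed=True)["participant_id"].nunique()
    if len(groups) < 2:
        raise AnalysisError("ANOVA needs both diagnosis groups")
    if (groups < 2).any():
        raise AnalysisError("ANOVA needs >= 2 participants per diagnosis group")
    categories = sorted(data["category"].unique())
    cells = data.groupby("participant_id", observed=True)["category"].nunique()
    if (cells < len(categories)).any():
        missing = cells.index[cells < len(categories)][0]
        raise AnalysisError(
            f"participant {missing!r} is missing a category cell"
        )
    model = smf.ols(
        "percentage ~ C(diagnosis) * C(category)", data=data
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_error = float(table.loc["Residual", "sum_sq"])
    name_map = {
        "C(diagnosis)": "diagnosis",
        "C(category)": "category",
        "C(diagnosis):C(category)": "interaction",
    }
    terms = {}
    for row, name in name_map.items():
        ss = float(table.loc[row, "sum_sq"])
        terms[name] = TermStats(
            df=int(table.loc[row, "df"]),
            F=float(table.loc[row, "F"]),
            partial_eta_sq=ss / (ss + ss_error),
            p=float(table.loc[row, "PR(>F)"]),
        )
    return AnovaResult(
        threshold_used=threshold,
        terms=terms,
        r_squared=float(model.rsquared),
        df_resid=int(model.df_resid),
        n_participants=int(data["participant_id"].nunique()),
    )


# ---------------------------------------------------------------------------
# Moderated regression: latency ~ valence * diagnosis on emotion words
# ---------------------------------------------------------------------------

@dataclass
class ModeratedRegressionResult:
    """OLS of word-mean latency on valence, diagnosis and their product.

    The interaction coefficient is the study's quantity of interest: a
    negative value means that the more negative a word's valence, the slower
    the ADHD group responds relative to controls.
    """

    coefficients: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    partial_eta_sq: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    f_statistic: float
    f_p_value: float
    df_model: int
    df_resid: int
    r_squared: float
    n_obs: int

    @property
    def adhd_valence_slope(self) -> float:
        """Implied ms-per-valence-unit slope within the ADHD group."""
        return self.coefficients["valence"] + self.coefficients["interaction"]

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "t_values": self.t_values,
            "p_values": self.p_values,
            "partial_eta_sq": self.partial_eta_sq,
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
            "f_statistic": self.f_statistic,
            "f_p_value": self.f_p_value,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
            "adhd_valence_slope": self.adhd_valence_slope,
        }


def moderated_regression(observations: pd.DataFrame) -> ModeratedRegressionResult:
    """Fit latency ~ valence + diagnosis + valence:diagnosis by OLS.

    ``observations`` is word-level: one row per (participant, rated emotion
    word) with columns latency_ms, valence (the participant's own -3..+3
    rating, consumed as a real number) and diagnosis (0/1).
    """
    required = {"latency_ms", "valence", "diagnosis"}
    missing = required - set(observations.columns)
    if missing:
        raise AnalysisError(f"observations missing columns {sorted(missing)}")
    data = observations.dropna(subset=sorted(required))
    if data["diagnosis"].nunique() < 2:
        raise AnalysisError(
            "moderated regression needs both diagnosis groups to identify "
            "the interaction term"
        )
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "valence": data["valence"].astype(float),
            "diagnosis": data["diagnosis"].astype(float),
            "interaction": data["valence"].astype(float)
            * data["diagnosis"].astype(float),
        }
    )
    fit = sm.OLS(data["latency_ms"].astype(float), X).fit()
    ci = fit.conf_int()
    terms = list(X.columns)
    # partial eta^2 for a single-df regression term: t^2 / (t^2 + df_resid)
    peta = {
        t: float(fit.tvalues[t] ** 2 / (fit.tvalues[t] ** 2 + fit.df_resid))
        for t in terms
        if t != "intercept"
    }
    return ModeratedRegressionResult(
        coefficients={t: float(fit.params[t]) for t in terms},
        t_values={t: float(fit.tvalues[t]) for t in terms},
        p_values={t: float(fit.pvalues[t]) for t in terms},
        partial_eta_sq=peta,
        conf_int={t: (float(ci.loc[t, 0]), float(ci.loc[t, 1])) for t in terms},
        f_statistic=float(fit.fvalue),
        f_p_value=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        n_obs=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# Logistic diagnosis classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorStats:
    coefficient: float
    odds_ratio: float
    wald_z: float
    p: float


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    percent_correct: float


def confusion_metrics(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionMetrics:
    """Sensitivity / specificity / percent correct on the 0-100 scale.

    Positive class is ADHD (1). An empty class yields NaN for its rate.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise AnalysisError("y_true and y_pred must have equal length")
    if yt.size == 0:
        raise AnalysisError("empty label vector")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return ConfusionMetrics(
        sensitivity=sens,
        specificity=spec,
        percent_correct=100.0 * (tp + tn) / yt.size,
    )


@dataclass
class LogisticResult:
    predictors: dict[str, PredictorStats]
    lr_chi2: float
    lr_df: int
    lr_p: float
    pseudo_r2: float
    sensitivity: float
    specificity: float
    percent_correct: float
    classification_threshold: float
    converged: bool
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "predictors": {
                name: {
                    "coefficient": s.coefficient,
                    "odds_ratio": s.odds_ratio,
                    "wald_z": s.wald_z,
                    "p": s.p,
                }
                for name, s in self.predictors.items()
            },
            "lr_chi2": self.lr_chi2,
            "lr_df": self.lr_df,
            "lr_p": self.lr_p,
            "pseudo_r2": self.pseudo_r2,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "percent_correct": self.percent_correct,
            "classification_threshold": self.classification_threshold,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def logistic_diagnosis_model(
    predictors: pd.DataFrame,
    labels: Mapping[str, int],
    screener: Optional[Mapping[str, float]] = None,
    classification_threshold: float = 0.5,
) -> LogisticResult:
    """Predict ADHD diagnosis from percentages of words of interest.

    ``predictors`` is indexed by participant_id with one 0-100 percentage
    column per predictor (personality-related percentage plus the five
    daily-life domains). Percentages are rescaled to proportions before
    fitting, so each odds ratio is per full-scale (0 -> 100%) change.
    ``screener`` optionally adds the ADHD screener total on its native scale.

    Perfect separation is reported via a warning and ``converged=False``;
    classification metrics are still computed from the achieved predictions.
    """
    if not 0.0 < classification_threshold < 1.0:
        raise AnalysisError(
            f"classification threshold must be in (0, 1), got "
            f"{classification_threshold}"
        )
    y = pd.Series(
        {pid: labels[pid] for pid in predictors.index if pid in labels},
        name="diagnosis",
    )
    X = predictors.loc[y.index].astype(float) / 100.0
    if screener is not None:
        X["screener"] = [float(screener[pid]) for pid in y.index]
    if y.nunique() < 2:
        raise AnalysisError("logistic model needs both diagnosis groups")
    X = sm.add_constant(X, prepend=True, has_constant="add")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            # (near-)perfect separation: Newton's Hessian degenerates; a
            # quasi-Newton fit still yields usable predictions
            fit = sm.Logit(y, X).fit(disp=0, maxiter=500, method="bfgs")
            converged = False
    if any(
        issubclass(w.category, (PerfectSeparationWarning, ConvergenceWarning))
        for w in caught
    ):
        converged = False
    converged = converged and bool(fit.mle_retvals.get("converged", True))
    if not converged:
        warnings.warn(
            "logistic fit did not converge cleanly (possible perfect "
            "separation); metrics reported from achieved predictions",
            stacklevel=2,
        )
    phat = np.asarray(fit.predict(X))
    y_pred = (phat >= classification_threshold).astype(int)
    cm = confusion_metrics(y.to_numpy(), y_pred)
    stats = {}
    for name in X.columns:
        if name == "const":
            continue
        coef = float(fit.params[name])
        with np.errstate(over="ignore"):
            odds_ratio = float(np.exp(coef))
        stats[name] = PredictorStats(
            coefficient=coef,
            odds_ratio=odds_ratio,
            wald_z=float(fit.tvalues[name]),
            p=float(fit.pvalues[name]),
        )
    return LogisticResult(
        predictors=stats,
        lr_chi2=float(fit.llr),
        lr_df=int(fit.df_model),
        lr_p=float(fit.llr_pvalue),
        pseudo_r2=float(fit.prsquared),
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        percent_correct=cm.percent_correct,
        classification_threshold=classification_threshold,
        converged=converged,
        n_obs=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# Cohort-level glue: build the model inputs from pipeline tables
# ---------------------------------------------------------------------------

def emotion_observations(
    word_latencies: pd.DataFrame,
    participants: Iterable[ParticipantMeta],
) -> pd.DataFrame:
    """Word-level observations for the moderated valence regression.

    One row per (participant, rated emotion word) with the word-mean latency,
    the participant's own -3..+3 rating consumed as a real number, and the
    0/1 diagnosis code. Distraction words of the emotion round carry no
    rating-model claim and are left out; excluded participants are dropped.
    """
    people = {p.participant_id: p for p in participants}
    codes = diagnosis_codes(people.values())
    rated = {c.value for c in RATED_EMOTION_CATEGORIES}
    sub = word_latencies.loc[
        (word_latencies["section"] == Section.EMOTION.value)
        & (word_latencies["category"].isin(rated))
    ]
    rows = []
    for r in sub.itertuples(index=False):
        pid = r.participant_id
        if pid not in codes:
            continue
        rating = people[pid].valence_ratings.get(r.word)
        if rating is None:
            continue
        rows.append((pid, r.word, float(r.mean_latency_ms), float(rating), codes[pid]))
    return pd.DataFrame(
        rows, columns=["participant_id", "word", "latency_ms", "valence", "diagnosis"]
    )


def logistic_predictor_table(
    percentages: pd.DataFrame, word_list: WordList
) -> pd.DataFrame:
    """Per-participant predictors for the diagnosis classifier.

    ``perc_personality_related`` is the related-category percentage of the
    personality round; each daily-life predictor is that domain's overall
    percentage of words of interest (flagged out of the domain's full
    inventory), obtained by recombining the category percentages with their
    word-list denominators.
    """
    counts = {
        (s, c): len(word_list.words_in(s, c))
        for s in word_list.sections()
        for c in word_list.categories_in(s)
    }
    wide = percentages.pivot_table(
        index="participant_id",
        columns=["section", "category"],
        values="percentage",
        sort=False,
    )
    out = pd.DataFrame(index=wide.index)
    out["perc_personality_related"] = wide[
        (Section.PERSONALITY.value, Category.RELATED.value)
    ]
    for section in DAILY_LIFE_SECTIONS:
        cats = [c for c in word_list.categories_in(section)]
        total = sum(counts[(section, c)] for c in cats)
        flagged = sum(
            wide[(section.value, c.value)] * counts[(section, c)] / 100.0
            for c in cats
        )
        out[f"perc_{section.value}"] = 100.0 * flagged / total
    out.index.name = "participant_id"
    return out


def analyze_cohort(
    z_scores: pd.DataFrame,
    word_latencies: pd.DataFrame,
    participants: Sequence[ParticipantMeta],
    word_list: WordList,
    z_threshold: float = 1.5,
    anova_thresholds: Optional[Sequence[float]] = None,
    classification_threshold: float = 0.5,
) -> dict:
    """Run all three group models and return a JSON-ready results bundle.

    The ANOVA block mirrors the study's threshold sweep on the personality
    round; the regression runs on rated emotion words; the logistic block
    fits the daily-life classifier at ``z_threshold`` with and without the
    screener. Participants flagged excluded_suspected never enter any model.
    """
    from .interest_scoring import ScoringConfig, score_cohort

    included = [p for p in participants if p.in_group_analysis]
    labels = diagnosis_codes(included)
    if anova_thresholds is None:
        anova_thresholds = [z_threshold]
    results: dict = {"anova": {}, "z_threshold": z_threshold}

    for threshold in anova_thresholds:
        config = ScoringConfig(z_threshold=threshold)
        _, pct = score_cohort(z_scores, included, word_list, config)
        personality = pct.loc[pct["section"] == Section.PERSONALITY.value]
        results["anova"][f"{threshold:g}"] = anova_words_of_interest(
            personality, labels, threshold
        ).to_dict()

    obs = emotion_observations(word_latencies, included)
    results["moderated_regression"] = moderated_regression(obs).to_dict()

    config = ScoringConfig(z_threshold=z_threshold)
    _, pct = score_cohort(z_scores, included, word_list, config)
    predictors = logistic_predictor_table(pct, word_list)
    screener = {p.participant_id: p.screener_score for p in included}
    results["logistic"] = {
        "model1": logistic_diagnosis_model(
            predictors, labels, classification_threshold=classification_threshold
        ).to_dict(),
        "model2": logistic_diagnosis_model(
            predictors,
            labels,
            screener=screener,
            classification_threshold=classification_threshold,
        ).to_dict(),
    }
    return results
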