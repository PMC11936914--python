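"""ANOVA, moderated regression and logistic classifier against independent
oracles: explicit sums-of-squares decomposition, permutation null, planted
single-predictor signal, and confusion-matrix identities."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emostroop import (
    AnalysisError,
    anova_words_of_interest,
    confusion_metrics,
    logistic_diagnosis_model,
    moderated_regression,
)


def balanced_percentage_table(cell_means, n_per_cell, noise_sd, rng):
    """Long table for a 2 (diagnosis) x 3 (category) between design."""
    rows = []
    labels = {}
    pid = 0
    for d in (0, 1):
        for _ in range(n_per_cell):
            pid += 1
            labels[f"P{pid}"] = d
            for c, cat in enumerate(("related", "unrelated", "distraction")):
                rows.append(
                    (
                        f"P{pid}",
                        cat,
                        cell_means[d][c] + noise_sd * rng.normal(),
                    )
                )
    frame = pd.DataFrame(rows, columns=["participant_id", "category", "percentage"])
    return frame, labels


def anova_ss_oracle(frame, labels):
    """From-scratch balanced two-way ANOVA decomposition (plain loops)."""
    data = {}
    for r in frame.itertuples(index=False):
        data.setdefault((labels[r.participant_id], r.category), []).append(
            r.percentage
        )
    diags = sorted({k[0] for k in data})
    cats = sorted({k[1] for k in data})
    n = len(next(iter(data.values())))
    all_vals = [v for vals in data.values() for v in vals]
    grand = sum(all_vals) / len(all_vals)
    mean_d = {
        d: sum(v for c in cats for v in data[(d, c)]) / (len(cats) * n) for d in diags
    }
    mean_c = {
        c: sum(v for d in diags for v in data[(d, c)]) / (len(diags) * n) for c in cats
    }
    cell = {k: sum(v) / len(v) for k, v in data.items()}
    ss_d = len(cats) * n * sum((mean_d[d] - grand) ** 2 for d in diags)
    ss_c = len(diags) * n * sum((mean_c[c] - grand) ** 2 for c in cats)
    ss_i = n * sum(
        (cell[(d, c)] - mean_d[d] - mean_c[c] + grand) ** 2
        for d in diags
        for c in cats
    )
    ss_e = sum(
        (v - cell[(d, c)]) ** 2 for (d, c), vals in data.items() for v in vals
    )
    df_e = len(all_vals) - len(diags) * len(cats)
    ms_e = ss_e / df_e
    return {
        "diagnosis": (ss_d / (len(diags) - 1)) / ms_e,
        "category": (ss_c / (len(cats) - 1)) / ms_e,
        "interaction": (ss_i / ((len(diags) - 1) * (len(cats) - 1))) / ms_e,
        "partial_eta": {
            "diagnosis": ss_d / (ss_d + ss_e),
            "category": ss_c / (ss_c + ss_e),
            "interaction": ss_i / (ss_i + ss_e),
        },
    }


class TestAnova:
    def test_matches_manual_ss_decomposition(self, rng):
        frame, labels = balanced_percentage_table(
            [[10.0, 20.0, 15.0], [25.0, 18.0, 12.0]], 6, 4.0, rng
        )
        result = anova_words_of_interest(frame, labels, threshold=1.5)
        oracle = anova_ss_oracle(frame, labels)
        for term in ("diagnosis", "category", "interaction"):
            assert result.terms[term].F == pytest.approx(oracle[term], rel=1e-10)
            assert result.terms[term].partial_eta_sq == pytest.approx(
                oracle["partial_eta"][term], rel=1e-10
            )
        assert result.terms["diagnosis"].df == 1
        assert result.terms["category"].df == 2
        assert result.terms["interaction"].df == 2

    def test_null_f_statistics_stay_below_099_quantile(self):
        """Identical cell means: each term's F exceeds its 0.99 null quantile
        in at most a few of 100 seeded runs."""
        exceed = {"diagnosis": 0, "category": 0, "interaction": 0}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frame, labels = balanced_percentage_table(
                [[15.0] * 3, [15.0] * 3], 5, 5.0, rng
            )
            result = anova_words_of_interest(frame, labels, threshold=1.5)
            for term, ts in result.terms.items():
                if ts.F > stats.f.ppf(0.99, ts.df, result.df_resid):
                    exceed[term] += 1
        for term, count in exceed.items():
            assert count <= 5, f"{term} exceeded the null quantile {count}/100 times"

    def test_partial_eta_bounded(self, rng):
        frame, labels = balanced_percentage_table(
            [[0.0, 40.0, 5.0], [80.0, 2.0, 60.0]], 4, 10.0, rng
        )
        result = anova_words_of_interest(frame, labels, threshold=0.5)
        for ts in result.terms.values():
            assert 0.0 <= ts.partial_eta_sq <= 1.0

    def test_single_group_rejected(self, rng):
        frame, labels = balanced_percentage_table(
            [[10.0] * 3, [12.0] * 3], 4, 2.0, rng
        )
        only_adhd = {k: v for k, v in labels.items() if v == 1}
        with pytest.raises(AnalysisError):
            anova_words_of_interest(frame, only_adhd, threshold=1.5)

    def test_missing_cell_rejected(self, rng):
        frame, labels = balanced_percentage_table(
            [[10.0] * 3, [12.0] * 3], 4, 2.0, rng
        )
        frame = frame.drop(frame.index[0])
        with pytest.raises(AnalysisError, match="missing"):
            anova_words_of_interest(frame, labels, threshold=1.5)


def synth_regression_data(
    rng, n_per_group=30, n_words=12, noise_sd=0.0,
    b0=600.0, b_val=2.68, b_diag=20.89, b_int=-8.36,
):
    rows = []
    for pid in range(2 * n_per_group):
        d = int(pid < n_per_group)
        for w in range(n_words):
            v = float(rng.integers(-3, 4))
            latency = b0 + b_val * v + b_diag * d + b_int * v * d
            if noise_sd:
                latency += noise_sd * rng.normal()
            rows.append((f"P{pid}", f"w{w}", latency, v, d))
    return pd.DataFrame(
        rows, columns=["participant_id", "word", "latency_ms", "valence", "diagnosis"]
    )


class TestModeratedRegression:
    def test_noise_free_recovery_of_generating_coefficients(self, rng):
        """Noise-free data from the reported coefficient values must be
        recovered exactly (to numerical precision)."""
        data = synth_regression_data(rng, noise_sd=0.0)
        fit = moderated_regression(data)
        assert fit.coefficients["intercept"] == pytest.approx(600.0, abs=1e-8)
        assert fit.coefficients["valence"] == pytest.approx(2.68, abs=1e-8)
        assert fit.coefficients["diagnosis"] == pytest.approx(20.89, abs=1e-8)
        assert fit.coefficients["interaction"] == pytest.approx(-8.36, abs=1e-8)
        # implied slope for the ADHD group: valence + interaction
        assert fit.adhd_valence_slope == pytest.approx(2.68 - 8.36, abs=1e-8)

    def test_single_group_rejected(self, rng):
        data = synth_regression_data(rng)
        with pytest.raises(AnalysisError):
            moderated_regression(data[data["diagnosis"] == 1])

    def test_interaction_t_matches_permutation_oracle(self, rng):
        """On null data the parametric p of the interaction agrees with a
        participant-level label-permutation p."""
        data = synth_regression_data(
            rng, n_per_group=20, n_words=10, noise_sd=50.0, b_val=0, b_diag=0, b_int=0
        )
        fit = moderated_regression(data)
        observed_t = fit.t_values["interaction"]
        pids = data["participant_id"].unique()
        labels = data.groupby("participant_id")["diagnosis"].first()
        perm_ts = []
        for _ in range(400):
            shuffled = dict(zip(pids, rng.permutation(labels.values)))
            perm = data.copy()
            perm["diagnosis"] = perm["participant_id"].map(shuffled)
            perm_ts.append(moderated_regression(perm).t_values["interaction"])
        perm_ts = np.asarray(perm_ts)
        perm_p = float(np.mean(np.abs(perm_ts) >= abs(observed_t)))
        assert abs(perm_p - fit.p_values["interaction"]) < 0.1
        # the permutation t distribution is approximately standard normal
        assert abs(perm_ts.mean()) < 0.2
        assert 0.7 < perm_ts.std() < 1.4

    def test_confidence_interval_coverage_near_nominal(self, rng):
        """95% CI covers the generating interaction at nominal rate +/-4pp."""
        covered = 0
        n_rep = 500
        for _ in range(n_rep):
            data = synth_regression_data(
                rng, n_per_group=20, n_words=8, noise_sd=60.0
            )
            fit = moderated_regression(data)
            lo, hi = fit.conf_int["interaction"]
            covered += lo <= -8.36 <= hi
        assert 0.91 <= covered / n_rep <= 0.99


class TestConfusionMetrics:
    def test_all_control_predictions(self):
        """Degenerate classifier: sensitivity 0, specificity 100."""
        cm = confusion_metrics([1, 1, 0, 0, 0], [0, 0, 0, 0, 0])
        assert cm.sensitivity == 0.0
        assert cm.specificity == 100.0
        assert cm.percent_correct == 60.0

    def test_exhaustive_small_tables(self):
        """Identities hold on every 2x2 table with both classes present,
        up to N = 30."""
        for n in range(2, 31):
            for npos in range(1, n):
                nneg = n - npos
                for tp in range(npos + 1):
                    for tn in range(nneg + 1):
                        y_true = [1] * npos + [0] * nneg
                        y_pred = (
                            [1] * tp + [0] * (npos - tp)
                            + [0] * tn + [1] * (nneg - tn)
                        )
                        cm = confusion_metrics(y_true, y_pred)
                        assert cm.sensitivity == pytest.approx(100.0 * tp / npos)
                        assert cm.specificity == pytest.approx(100.0 * tn / nneg)
                        assert cm.percent_correct == pytest.approx(
                            100.0 * (tp + tn) / n
                        )


def synth_predictors(rng, n_per_group=50, social_gap=12.0):
    """Percentage predictors where only the social domain separates groups
    (lower in ADHD, i.e. a negative coefficient)."""
    names = [
        "perc_personality_related",
        "perc_work",
        "perc_relationships",
        "perc_social",
        "perc_hobby",
        "perc_self_image",
    ]
    rows, labels = {}, {}
    for pid in range(2 * n_per_group):
        d = int(pid < n_per_group)
        vals = 15.0 + 5.0 * rng.normal(size=6)
        if d:
            vals[3] -= social_gap
        rows[f"P{pid}"] = np.clip(vals, 0.0, 100.0)
        labels[f"P{pid}"] = d
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    frame.index.name = "participant_id"
    return frame, labels


class TestLogistic:
    def test_odds_ratio_is_exp_coefficient(self, rng):
        predictors, labels = synth_predictors(rng)
        result = logistic_diagnosis_model(predictors, labels)
        for s in result.predictors.values():
            assert s.odds_ratio == pytest.approx(math.exp(s.coefficient), rel=1e-12)
        assert result.lr_df == 6

    def test_screener_model_adds_predictor(self, rng):
        predictors, labels = synth_predictors(rng)
        screener = {
            pid: 14.0 + 3 * rng.normal() if d else 8.0 + 3 * rng.normal()
            for pid, d in labels.items()
        }
        result = logistic_diagnosis_model(predictors, labels, screener=screener)
        assert "screener" in result.predictors
        assert result.lr_df == 7
        assert result.predictors["screener"].coefficient > 0

    def test_planted_social_signal_dominates_wald_z(self):
        """With signal only in the social domain its |Wald z| leads in >=90%
        of replicates, with the expected negative sign."""
        wins = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            predictors, labels = synth_predictors(rng)
            result = logistic_diagnosis_model(predictors, labels)
            zs = {k: abs(s.wald_z) for k, s in result.predictors.items()}
            if max(zs, key=zs.get) == "perc_social":
                wins += result.predictors["perc_social"].coefficient < 0
        assert wins >= 0.9 * n_rep

    def test_threshold_trades_sensitivity_for_specificity(self, rng):
        predictors, labels = synth_predictors(rng, social_gap=6.0)
        prev_sens, prev_spec = None, None
        for threshold in (0.2, 0.4, 0.6, 0.8):
            r = logistic_diagnosis_model(
                predictors, labels, classification_threshold=threshold
            )
            if prev_sens is not None:
                assert r.sensitivity <= prev_sens
                assert r.specificity >= prev_spec
            prev_sens, prev_spec = r.sensitivity, r.specificity

    def test_separated_data_flags_nonconvergence_but_reports_metrics(self):
        predictors = pd.DataFrame(
            {"perc_social": [1.0, 2.0, 3.0, 30.0, 31.0, 32.0]},
            index=[f"P{i}" for i in range(6)],
        )
        predictors.index.name = "participant_id"
        labels = {f"P{i}": int(i < 3) for i in range(6)}
        with pytest.warns(UserWarning):
            result = logistic_diagnosis_model(predictors, labels)
        assert not result.converged
        assert result.percent_correct == 100.0
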