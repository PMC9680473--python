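"""Logistic modelling, forward-LR selection, ROC/DeLong/LOOCV oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ivimdce.diagnostics import (
    delong_test,
    fit_logistic,
    forward_lr_select,
    loocv_accuracy,
    model_candidates,
    roc_report,
)


class TestFitLogistic:
    def test_binary_predictor_equals_log_odds_ratio(self):
        """With one binary predictor, the slope is the 2x2-table log OR."""
        # Table: x=0 -> 30 events of 100; x=1 -> 70 events of 100.
        x = np.repeat([0.0, 1.0], 100)
        y = np.concatenate([np.repeat([1, 0], [30, 70]),
                            np.repeat([1, 0], [70, 30])])
        fit = fit_logistic(x, y)
        log_or = np.log((70 / 30) / (30 / 70))
        assert fit.params[1] == pytest.approx(log_or, rel=1e-6)
        assert fit.params[0] == pytest.approx(np.log(30 / 70), rel=1e-6)

    def test_uninformative_predictor_adds_no_deviance(self, rng):
        y = rng.integers(0, 2, 300).astype(float)
        x = rng.normal(0, 1, 300)
        fit = fit_logistic(x, y)
        p = y.mean()
        null_llf = 300 * (p * np.log(p) + (1 - p) * np.log(1 - p))
        lr = 2 * (fit.llf - null_llf)
        assert 0 <= lr < stats.chi2.ppf(0.999, 1)

    def test_fitted_probabilities_monotone_in_strong_predictor(self, rng):
        x = np.linspace(-3, 3, 200)
        y = (x + rng.normal(0, 0.3, 200) > 0).astype(float)
        fit = fit_logistic(x, y)
        assert fit.params[1] > 0  # monotone link

    def test_complete_separation_flagged_and_capped(self):
        x = np.concatenate([np.linspace(-2, -1, 20), np.linspace(1, 2, 20)])
        y = np.repeat([0.0, 1.0], 20)
        fit = fit_logistic(x, y)
        assert fit.separation
        assert np.all(np.abs(fit.params) <= 30.0)

    def test_singular_design_rejected(self, rng):
        x = rng.normal(0, 1, 50)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="singular"):
            fit_logistic(X, (x > 0).astype(float))


class TestForwardLR:
    def test_single_informative_variable_found(self):
        """One 2-SD effect among five pure-noise candidates is selected, and
        nothing but it in the clear majority of replicates."""
        exact = 0
        contains = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 200
            y = rng.integers(0, 2, n).astype(float)
            X = pd.DataFrame({f"noise{i}": rng.normal(0, 1, n) for i in range(5)})
            X["signal"] = rng.normal(0, 1, n) + 2.0 * y
            fm = forward_lr_select(X, y, list(X.columns))
            contains += "signal" in fm.selected
            exact += fm.selected == ["signal"]
        assert contains >= 95
        # Each of the five remaining null candidates enters at roughly the
        # 5% level, so the exactly-one-variable outcome occurs in about
        # (0.95)^5 ~ 77% of replicates; allow for the LR test's mild
        # anticonservatism at n=200.
        assert exact >= 55

    def test_all_noise_selection_rate_matches_entry_alpha(self):
        """With k independent null candidates the chance that none enters is
        about (1 - alpha)^k; the observed empty-selection rate agrees."""
        empty = 0
        n_rep = 200
        k = 6
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            n = 150
            y = rng.integers(0, 2, n).astype(float)
            X = pd.DataFrame({f"n{i}": rng.normal(0, 1, n) for i in range(k)})
            fm = forward_lr_select(X, y, list(X.columns))
            empty += not fm.selected
        expected = (1 - 0.05) ** k
        se = np.sqrt(expected * (1 - expected) / n_rep)
        assert empty / n_rep == pytest.approx(expected, abs=4 * se)

    def test_selection_is_deterministic(self, rng):
        n = 120
        y = rng.integers(0, 2, n).astype(float)
        X = pd.DataFrame({"a": rng.normal(0, 1, n) + y,
                          "b": rng.normal(0, 1, n)})
        first = forward_lr_select(X, y, ["a", "b"])
        second = forward_lr_select(X, y, ["a", "b"])
        assert first.selected == second.selected
        assert np.allclose(first.coefficients, second.coefficients)


class TestROC:
    def test_perfect_separation(self):
        rep = roc_report([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert rep.auc == 1.0
        assert rep.sensitivity == 100.0 and rep.specificity == 100.0

    def test_pair_counting_oracle(self):
        rep = roc_report([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert rep.auc == pytest.approx(0.75)

    def test_rank_statistic_identity(self, rng):
        """AUC equals U/(n1 n0) and sklearn's value on random instances."""
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            labels = rng.integers(0, 2, 60)
            if labels.min() == labels.max():
                continue
            scores = rng.normal(0, 1, 60) + labels
            rep = roc_report(scores, labels)
            u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
            n1, n0 = labels.sum(), (1 - labels).sum()
            assert rep.auc == pytest.approx(u / (n1 * n0), rel=1e-12)
            assert rep.auc == pytest.approx(roc_auc_score(labels, scores), rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, 80)
        labels[:5] = 1
        labels[5:10] = 0
        scores = rng.normal(0, 1, 80)
        base = roc_report(scores, labels)
        trans = roc_report(np.exp(2.0 * scores) + 5.0, labels)
        assert trans.auc == pytest.approx(base.auc, rel=1e-12)
        assert trans.sensitivity == base.sensitivity

    def test_youden_tie_breaks_toward_specificity(self):
        # Two cuts achieve J = 0.5; the higher threshold (better specificity)
        # must win.
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        rep = roc_report(scores, labels)
        assert rep.specificity == 100.0 and rep.sensitivity == 50.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_report([0.1, 0.2], [1, 1])


def bootstrap_delong_oracle(scores_a, scores_b, labels, n_boot, seed):
    """Paired-bootstrap z-test of the AUC difference."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)

    def auc(scores, p_idx, n_idx):
        sp = scores[p_idx][:, None]
        sn = scores[n_idx][None, :]
        return ((sp > sn) + 0.5 * (sp == sn)).mean(axis=(-2, -1))

    diffs = np.empty(n_boot)
    chunk = 2000
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        bp = rng.choice(pos, size=(m, pos.size))
        bn = rng.choice(neg, size=(m, neg.size))
        for j in range(m):
            diffs[done + j] = (auc(scores_a, bp[j], bn[j])
                               - auc(scores_b, bp[j], bn[j]))
        done += m
    d_obs = (auc(scores_a, pos, neg) - auc(scores_b, pos, neg))
    z = d_obs / diffs.std(ddof=1)
    return float(2 * stats.norm.sf(abs(z)))


class TestDeLong:
    def test_model_against_itself_is_degenerate(self, rng):
        s = rng.normal(0, 1, 40)
        labels = np.repeat([0, 1], 20)
        rep = delong_test(s, s, labels)
        assert rep.p == 1.0 and rep.degenerate and rep.auc_difference == 0.0

    def test_agrees_with_paired_bootstrap(self, rng):
        n = 40
        labels = np.repeat([0, 1], [10, 30])
        base = rng.normal(0, 1, n) + 0.9 * labels
        scores_a = base + rng.normal(0, 0.4, n)
        scores_b = 0.6 * base + rng.normal(0, 0.8, n)
        rep = delong_test(scores_a, scores_b, labels)
        p_boot = bootstrap_delong_oracle(scores_a, scores_b, labels,
                                         n_boot=100_000, seed=1)
        assert rep.p == pytest.approx(p_boot, abs=0.02)

    def test_hanley_mcneil_limit(self, rng):
        """DeLong SE approaches the binormal Hanley-McNeil SE at n=500."""
        n1 = n0 = 250
        scores = np.concatenate([rng.normal(0, 1, n0), rng.normal(1, 1, n1)])
        labels = np.repeat([0, 1], [n0, n1])
        rep = roc_report(scores, labels)
        a = rep.auc
        q1 = a / (2 - a)
        q2 = 2 * a**2 / (1 + a)
        hm = np.sqrt((a * (1 - a) + (n1 - 1) * (q1 - a**2)
                      + (n0 - 1) * (q2 - a**2)) / (n1 * n0))
        assert rep.se == pytest.approx(hm, rel=0.15)


class TestLOOCV:
    def make_df(self, x, y):
        return pd.DataFrame({"x": x, "group": np.where(y == 1, "malignant", "benign")})

    def test_separable_data_is_perfectly_classified(self):
        x = np.concatenate([np.linspace(-3, -1, 10), np.linspace(1, 3, 10)])
        y = np.repeat([0.0, 1.0], 10)
        acc = loocv_accuracy(pd.DataFrame({"x": x}), y, ["x"])
        assert acc == 1.0

    def test_permuted_balanced_labels_give_chance_accuracy(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 60)
            y = np.repeat([0.0, 1.0], 30)
            rng.shuffle(y)
            accs.append(loocv_accuracy(pd.DataFrame({"x": x}), y, ["x"]))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    def test_imbalanced_null_data_tracks_base_rate(self):
        """With 20/80 classes and no signal, the classifier defaults to the
        majority class, so accuracy sits near 0.8."""
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 100)
            y = np.repeat([0.0, 1.0], [20, 80])
            accs.append(loocv_accuracy(pd.DataFrame({"x": x}), y, ["x"]))
        assert np.mean(accs) == pytest.approx(0.8, abs=0.07)

    def test_too_few_lesions_rejected(self):
        with pytest.raises(ValueError):
            loocv_accuracy(pd.DataFrame({"x": [1.0] * 5}), np.ones(5), ["x"])


def test_model_candidates_partition_by_family():
    screened = ["ADC_mean", "ADC_min", "D_mean", "f_min", "Dstar_max",
                "Ktrans_max", "Kep_max", "Ve_mean"]
    cands = model_candidates(screened)
    assert cands["model_ADC"] == ["ADC_mean", "ADC_min"]
    assert cands["model_IVIM"] == ["D_mean", "f_min", "Dstar_max"]
    assert cands["model_DCE"] == ["Ktrans_max", "Kep_max", "Ve_mean"]
    assert set(cands["model_DCE+IVIM"]) == set(cands["model_DCE"]) | set(cands["model_IVIM"])
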