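"""Rank tests, ROC machinery, concordance, panels and stratification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from srmquant.stats import (
    bh_adjust,
    concordance,
    fit_panel,
    optimal_cutoff,
    rank_test,
    roc,
    search_panels,
    stratify,
)


def brute_force_auc(pos, neg):
    """P(X > Y) + 0.5 P(X = Y) over all positive/negative pairs."""
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


class TestRankTest:
    def test_fully_separated_small_groups(self):
        """a below b gives U=0 and exact two-sided P = 2/20 = 0.1."""
        u, p = rank_test([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_groups_maximal_p(self):
        _, p = rank_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        """Exhaustive check of the exact P against independent
        enumeration for every dataset shape with n1+n2 <= 8."""
        for n1, n2 in [(1, 3), (2, 2), (3, 3), (4, 4), (2, 6), (3, 5)]:
            vals = np.round(rng.normal(size=n1 + n2), 1)  # rounding forces ties
            a, b = vals[:n1], vals[n1:]
            u_obs, p_impl = rank_test(a, b)
            # oracle: relabel every partition, midrank U via scipy rankdata
            mu = n1 * n2 / 2
            hits = total = 0
            for subset in itertools.combinations(range(n1 + n2), n1):
                rest = [i for i in range(n1 + n2) if i not in subset]
                ranks = sps.rankdata(vals)
                u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2
                total += 1
                if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                    hits += 1
            assert p_impl == pytest.approx(hits / total)

    def test_large_sample_approximation_close_to_exact_regime(self, rng):
        """At n=30/30 the asymptotic P agrees with scipy's within 0.01."""
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        _, p = rank_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(ref, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_test([], [1.0])


class TestRoc:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(1.0)
        assert not r.flipped

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        r = roc(scores, labels, orient=False)
        assert r.auc_raw == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_u_over_n1n2(self, rng):
        """Mann-Whitney identity AUC = U/(n1 n2), tie-adjusted, on random
        small datasets with forced ties."""
        for _ in range(50):
            n1, n2 = rng.integers(3, 9), rng.integers(3, 9)
            pos = np.round(rng.normal(0.5, 1, n1), 0)
            neg = np.round(rng.normal(0, 1, n2), 0)
            scores = np.concatenate([pos, neg])
            labels = np.r_[np.ones(n1, int), np.zeros(n2, int)]
            r = roc(scores, labels, orient=False)
            u, _ = rank_test(pos, neg)
            assert r.auc_raw == pytest.approx(u / (n1 * n2), abs=1e-9)
            assert r.auc_raw == pytest.approx(brute_force_auc(pos, neg), abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        r1 = roc(scores, labels)
        r2 = roc(np.exp(scores / 2), labels)
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)

    def test_flip_recorded_for_inverted_marker(self):
        r = roc([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert r.flipped
        assert r.auc == pytest.approx(1.0)
        assert r.auc_raw == pytest.approx(0.0)

    def test_delong_ci_coverage(self, rng):
        """95% DeLong intervals cover the true binormal AUC >= 90% of
        the time at the pilot cohort size (n = 14 vs 6)."""
        auc_true = 0.75
        d = math.sqrt(2) * sps.norm.ppf(auc_true)
        covered = 0
        n_rep = 500
        for _ in range(n_rep):
            pos = rng.normal(d, 1, 14)
            neg = rng.normal(0, 1, 6)
            r = roc(np.r_[pos, neg], np.r_[np.ones(14, int), np.zeros(6, int)],
                    orient=False)
            if r.ci_low <= auc_true <= r.ci_high:
                covered += 1
        assert covered / n_rep >= 0.90

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [1, 1, 1])


class TestOptimalCutoff:
    def test_separated_data(self):
        cut = optimal_cutoff(roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]))
        assert cut.sensitivity == 1.0
        assert cut.specificity == 1.0
        assert not cut.degenerate

    def test_all_equal_scores_degenerate(self):
        cut = optimal_cutoff(roc([5, 5, 5, 5], [0, 1, 0, 1], orient=False))
        assert cut.youden_sum == pytest.approx(1.0)
        assert cut.degenerate

    def test_matches_exhaustive_threshold_scan(self):
        """Six-point set with a known Youden maximizer."""
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        cut = optimal_cutoff(roc(scores, labels))
        # brute force over all thresholds (midpoints + extremes)
        best = -1.0
        for thr in np.unique(scores):
            sens = np.mean(scores[labels == 1] >= thr)
            spec = np.mean(scores[labels == 0] < thr)
            best = max(best, sens + spec)
        assert cut.youden_sum == pytest.approx(best)


class TestConcordance:
    def test_exact_linear_relation(self):
        m = pd.DataFrame({"p1": [1.0, 2, 3, 4], "p2": [2.0, 4, 6, 8]})
        rep = concordance(m, {"p1": "PROT", "p2": "PROT"})
        pair = rep[0].pairs[0]
        assert pair.r_squared == pytest.approx(1.0)
        assert pair.n_used == 4
        assert not pair.discordant_candidate

    def test_constant_column_skipped(self):
        m = pd.DataFrame({"p1": [1.0, 2, 3], "p2": [5.0, 5, 5]})
        pair = concordance(m, {"p1": "X", "p2": "X"})[0].pairs[0]
        assert pair.r_squared is None
        assert pair.skip_reason == "zero variance"

    def test_pairwise_complete_counting(self):
        m = pd.DataFrame({"p1": [1.0, 2, np.nan, 4], "p2": [2.0, np.nan, 6, 9]})
        pair = concordance(m, {"p1": "X", "p2": "X"})[0].pairs[0]
        assert pair.n_used == 2
        assert pair.skip_reason is not None  # below min_n=3

    def test_programmed_correlation_recovered(self, rng):
        """rho = 0.8 at n = 200 lands r^2 inside the sampling band
        rho^2 +/- 0.1."""
        n, rho = 200, 0.8
        z = rng.standard_normal(n)
        x = math.sqrt(rho) * z + math.sqrt(1 - rho) * rng.standard_normal(n)
        y = math.sqrt(rho) * z + math.sqrt(1 - rho) * rng.standard_normal(n)
        m = pd.DataFrame({"p1": x, "p2": y})
        pair = concordance(m, {"p1": "X", "p2": "X"})[0].pairs[0]
        assert 0.54 <= pair.r_squared <= 0.74


class TestFitPanel:
    def _cohort(self, rng, n=40):
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        m = pd.DataFrame({
            "A": rng.normal(y * 1.0, 1.0),
            "B": rng.normal(y * 1.0, 1.0),
        }, index=[f"s{i}" for i in range(n)])
        return m, pd.Series(y, index=m.index)

    def test_single_member_auc_matches_roc(self, rng):
        m, y = self._cohort(rng)
        fit = fit_panel(m, y, ["A"])
        direct = roc(m["A"].to_numpy(), y.to_numpy(), orient=False)
        assert fit.auc == pytest.approx(direct.auc_raw, abs=1e-9)

    def test_redundant_member_adds_nothing(self, rng):
        m, y = self._cohort(rng)
        m["A2"] = m["A"]
        single = fit_panel(m, y, ["A"])
        double = fit_panel(m, y, ["A", "A2"])
        assert double.auc == pytest.approx(single.auc, abs=1e-6)

    def test_two_informative_markers_beat_each_single(self, rng):
        """Two independent d=1 markers combine to a higher training AUC
        than either alone in >= 90% of replicates."""
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            m, y = self._cohort(rng, n=40)
            panel = fit_panel(m, y, ["A", "B"]).auc
            singles = max(fit_panel(m, y, ["A"]).auc, fit_panel(m, y, ["B"]).auc)
            wins += panel > singles
        assert wins / n_rep >= 0.90

    def test_perfect_separation_survives_ridge(self):
        m = pd.DataFrame({"A": [0.0, 1, 2, 10, 11, 12]}, index=list("abcdef"))
        y = pd.Series([0, 0, 0, 1, 1, 1], index=m.index)
        fit = fit_panel(m, y, ["A"])
        assert np.isfinite(fit.coefficients["A"])
        assert fit.auc == pytest.approx(1.0)

    def test_search_orders_by_auc(self, rng):
        m, y = self._cohort(rng)
        m["NOISE"] = rng.normal(size=len(m))
        fits = search_panels(m, y, max_size=2)
        aucs = [f.auc for f in fits]
        assert aucs == sorted(aucs, reverse=True)

    def test_missing_rows_dropped_and_counted(self, rng):
        m, y = self._cohort(rng)
        m.iloc[0, 0] = np.nan
        fit = fit_panel(m, y, ["A"])
        assert fit.n_dropped == 1
        assert fit.n_used == len(m) - 1


class TestStratify:
    def _sig(self, n_lo=6, n_hi=5):
        ids = [f"c{i}" for i in range(n_lo + n_hi)]
        return pd.Series(["low_grade"] * n_lo + ["significant"] * n_hi, index=ids)

    def test_null_p_values_calibrated(self, rng):
        """Strata drawn from one distribution give valid P values over
        200 simulations: never anti-conservative at any level (the exact
        test's discreteness makes it conservative, not liberal), and not
        degenerate."""
        ps = []
        sig = self._sig()
        for _ in range(200):
            m = pd.DataFrame({"pep": rng.lognormal(0, 1, 11)}, index=sig.index)
            ps.append(stratify(m, sig)["p_value"].iloc[0])
        ps = np.asarray(ps)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            assert (ps <= alpha).mean() <= alpha + 0.05
        assert (ps <= 0.5).mean() >= 0.30

    def test_twelvefold_shift_detected_at_cohort_size(self, rng):
        """A 12-fold mean shift is detected (P < 0.05) in >= 80% of
        replicates at n = 6 vs 5."""
        sig = self._sig()
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            lo = rng.lognormal(0, 1, 6)
            hi = rng.lognormal(np.log(12), 1, 5)
            m = pd.DataFrame({"pep": np.r_[lo, hi]}, index=sig.index)
            hits += stratify(m, sig)["p_value"].iloc[0] < 0.05
        assert hits / n_rep >= 0.80

    def test_printed_fold_difference(self):
        """The reported transcript intensities differ by at least
        12-fold."""
        assert 3004.10 / 238.41 >= 12.0

    def test_single_stratum_rejected(self):
        sig = pd.Series(["low_grade"] * 4, index=list("abcd"))
        m = pd.DataFrame({"pep": [1.0, 2, 3, 4]}, index=sig.index)
        with pytest.raises(ValueError):
            stratify(m, sig)


def test_bh_adjustment_is_monotone_and_bounded():
    p = pd.Series([0.001, 0.01, 0.04, 0.8, np.nan], index=list("abcde"))
    adj = bh_adjust(p)
    ok = adj.dropna()
    assert (ok >= p.dropna()).all()
    assert (ok <= 1.0).all()
    assert np.isnan(adj["e"])
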