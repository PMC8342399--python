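"""Statistical battery: normality, ANOVA, Tamhane T2, letter display."""

import numpy as np
import pytest
from scipy import stats as sps

from shrinkvec.stats import (GroupSample, PosthocTable, StatsError,
                             letters_from_pairs, one_way_anova, shapiro_wilk,
                             tamhane_t2)


def _groups(*arrays, labels=None):
    labels = labels or [f"g{i}" for i in range(len(arrays))]
    return [GroupSample(l, np.asarray(a, dtype=float))
            for l, a in zip(labels, arrays)]


class TestShapiroWilk:
    def test_needs_at_least_three_values(self):
        with pytest.raises(StatsError):
            shapiro_wilk([1.0, 2.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            shapiro_wilk([3.0] * 10)

    def test_normal_samples_rarely_rejected(self):
        """p > 0.05 in ≥ 95% of seeded standard-normal samples (n=500)."""
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            _, p = shapiro_wilk(rng.standard_normal(500))
            hits += p > 0.05
        assert hits >= 95

    def test_exponential_samples_reliably_rejected(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(2000 + rep)
            _, p = shapiro_wilk(rng.exponential(size=500))
            hits += p < 0.05
        assert hits >= 95

    def test_large_samples_use_deterministic_subsample(self, rng):
        big = rng.standard_normal(20_000)
        w1, p1 = shapiro_wilk(big)
        w2, p2 = shapiro_wilk(big)
        assert (w1, p1) == (w2, p2)
        assert 0 < w1 <= 1


class TestOneWayAnova:
    def test_hand_computed_example(self):
        """{1,2,3},{2,3,4},{3,4,5}: SSB=6, SSW=6, F=3 with df (2, 6)."""
        res = one_way_anova(_groups([1, 2, 3], [2, 3, 4], [3, 4, 5]))
        assert res.F == pytest.approx(3.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_groups_give_f_zero_p_one(self):
        res = one_way_anova(_groups([1, 2, 3], [1, 2, 3]))
        assert res.F == 0.0 and res.p == 1.0

    def test_zero_within_variance_with_unequal_means_flagged(self):
        res = one_way_anova(_groups([1, 1, 1], [2, 2, 2]))
        assert np.isinf(res.F) and res.p == 0.0 and res.degenerate

    def test_agrees_with_scipy_on_random_datasets(self):
        """Independent oracle: scipy.stats.f_oneway, 50 seeded datasets."""
        for rep in range(50):
            rng = np.random.default_rng(3000 + rep)
            k = int(rng.integers(2, 6))
            data = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2),
                               size=int(rng.integers(5, 40)))
                    for _ in range(k)]
            res = one_way_anova(_groups(*data))
            F_ref, p_ref = sps.f_oneway(*data)
            assert res.F == pytest.approx(F_ref, rel=1e-10)
            assert res.p == pytest.approx(p_ref, rel=1e-10, abs=1e-300)

    def test_invariance_under_shift_and_scale(self, rng):
        data = [rng.normal(size=12), rng.normal(1.0, 2.0, size=9),
                rng.normal(-0.5, 0.7, size=15)]
        f0 = one_way_anova(_groups(*data)).F
        shifted = [d + 100.0 for d in data]
        scaled = [d * 37.5 for d in data]
        assert one_way_anova(_groups(*shifted)).F == pytest.approx(f0, rel=1e-9)
        assert one_way_anova(_groups(*scaled)).F == pytest.approx(f0, rel=1e-9)

    def test_preconditions(self):
        with pytest.raises(StatsError):
            one_way_anova(_groups([1, 2, 3]))
        with pytest.raises(StatsError):
            one_way_anova(_groups([1, 2], [3]))


def _tamhane_oracle(data, alpha=0.05):
    """Step-by-step Welch + Sidak reference via scipy.ttest_ind."""
    k = len(data)
    m = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            t, p = sps.ttest_ind(data[i], data[j], equal_var=False)
            out.append(min(1.0, 1.0 - (1.0 - p) ** m))
    return out


class TestTamhaneT2:
    def test_identical_groups_not_significant(self):
        tab = tamhane_t2(_groups([1, 2, 3, 4], [1, 2, 3, 4]))
        row = tab.pairs.iloc[0]
        assert row.welch_t == 0.0 and row.adjusted_p == 1.0
        assert not row.significant

    def test_two_groups_have_no_multiplicity_penalty(self, rng):
        a, b = rng.normal(size=20), rng.normal(0.5, 2.0, size=15)
        tab = tamhane_t2(_groups(a, b))
        row = tab.pairs.iloc[0]
        assert row.adjusted_p == pytest.approx(row.raw_p, rel=1e-12)

    def test_agrees_with_independent_oracle(self):
        for rep in range(50):
            rng = np.random.default_rng(4000 + rep)
            k = int(rng.integers(2, 6))
            data = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.3, 3),
                               size=int(rng.integers(5, 40)))
                    for _ in range(k)]
            tab = tamhane_t2(_groups(*data))
            ref = _tamhane_oracle(data)
            np.testing.assert_allclose(tab.pairs["adjusted_p"], ref,
                                       rtol=1e-10, atol=1e-300)

    def test_adjusted_p_dominates_raw_p(self, rng):
        data = [rng.normal(size=10) for _ in range(4)]
        tab = tamhane_t2(_groups(*data))
        assert (tab.pairs["adjusted_p"] >= tab.pairs["raw_p"] - 1e-15).all()
        assert (tab.pairs["adjusted_p"] <= 1.0).all()

    def test_familywise_error_controlled_under_null(self):
        """All-null, unequal variances, k=5, n=30: FWER ≤ 0.06 at α=0.05."""
        sds = [0.5, 1.0, 2.0, 4.0, 8.0]
        false_alarms = 0
        reps = 2000
        rng = np.random.default_rng(20210127)
        for _ in range(reps):
            data = [rng.normal(0.0, sd, size=30) for sd in sds]
            tab = tamhane_t2(_groups(*data))
            false_alarms += bool(tab.pairs["significant"].any())
        assert false_alarms / reps <= 0.06

    def test_bonferroni_option_is_more_conservative(self, rng):
        data = [rng.normal(i * 0.1, 1.0, size=12) for i in range(4)]
        sidak = tamhane_t2(_groups(*data), adjustment="sidak")
        bonf = tamhane_t2(_groups(*data), adjustment="bonferroni")
        assert (bonf.pairs["adjusted_p"]
                >= sidak.pairs["adjusted_p"] - 1e-12).all()


class TestLetters:
    def _table_from_flags(self, labels, sig_pairs, alpha=0.05):
        import pandas as pd

        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                sig = (labels[i], labels[j]) in sig_pairs
                rows.append({"group_i": labels[i], "group_j": labels[j],
                             "mean_difference": 0.0, "welch_t": 0.0,
                             "welch_df": 10.0,
                             "raw_p": 0.001 if sig else 0.9,
                             "adjusted_p": 0.001 if sig else 0.9,
                             "significant": sig})
        return PosthocTable(pairs=pd.DataFrame(rows), alpha=alpha)

    def test_no_significant_pairs_share_one_letter(self):
        tab = self._table_from_flags(["a", "b", "c"], set())
        letters = letters_from_pairs(tab, order=["a", "b", "c"])
        assert set(letters.values()) == {"a"}

    def test_all_pairs_significant_get_distinct_letters(self):
        labels = ["g1", "g2", "g3"]
        sig = {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}
        letters = letters_from_pairs(self._table_from_flags(labels, sig),
                                     order=labels)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_letter_sharing_matches_flags_on_random_patterns(self):
        """Groups share a letter iff their pair is not significant."""
        for rep in range(50):
            rng = np.random.default_rng(5000 + rep)
            k = int(rng.integers(3, 7))
            labels = [f"g{i}" for i in range(k)]
            sig = set()
            for i in range(k):
                for j in range(i + 1, k):
                    if rng.random() < 0.4:
                        sig.add((labels[i], labels[j]))
            letters = letters_from_pairs(
                self._table_from_flags(labels, sig), order=labels)
            for i in range(k):
                for j in range(i + 1, k):
                    shared = set(letters[labels[i]]) & set(letters[labels[j]])
                    if (labels[i], labels[j]) in sig:
                        assert not shared, (rep, labels[i], labels[j])
                    else:
                        assert shared, (rep, labels[i], labels[j])
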