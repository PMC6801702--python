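"""Validation statistics: z-standardization, binning, Welch ANOVA, Tukey-Kramer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.cluster import hierarchy

import cathmap as cm
from cathmap.stats import PROBABILITY_BIN_LABELS


def _event_frame(counts, positions=None, **cond):
    positions = positions or list(range(5, 5 + len(counts)))
    base = {"substrate_id": "s", "cathepsin": "catS", "time_h": 24.0, "ph": 6.0}
    base.update(cond)
    return pd.DataFrame([{**base, "p1prime": p, "count": c}
                         for p, c in zip(positions, counts) if c > 0])


class TestZStandardize:
    def test_hand_calculation(self):
        """counts [0,0,0,4]: mean 1, sample SD 2 -> z = [-.5,-.5,-.5,1.5]."""
        ev = _event_frame([0, 0, 0, 4])
        zs = cm.z_standardize(ev, {"s": [5, 6, 7, 8]})
        np.testing.assert_allclose(sorted(zs.zscore), [-0.5, -0.5, -0.5, 1.5])

    def test_unobserved_bonds_enter_as_zero(self):
        ev = _event_frame([4], positions=[8])
        zs = cm.z_standardize(ev, {"s": [5, 6, 7, 8]})
        assert len(zs) == 4
        assert (zs.loc[zs.p1prime != 8, "count"] == 0).all()

    def test_constant_stratum_flagged_all_zero(self):
        ev = _event_frame([2, 2, 2])
        zs = cm.z_standardize(ev, {"s": [5, 6, 7]})
        assert (zs.zscore == 0).all() and (zs.flag == "constant").all()

    def test_mean_zero_sd_one_identity(self, rng):
        counts = rng.poisson(2, size=30)
        ev = _event_frame(list(counts), positions=list(range(5, 35)))
        zs = cm.z_standardize(ev, {"s": list(range(5, 35))})
        assert abs(zs.zscore.mean()) < 1e-12
        assert zs.zscore.std(ddof=1) == pytest.approx(1.0)

    def test_singleton_stratum_flagged(self):
        ev = _event_frame([3], positions=[5])
        zs = cm.z_standardize(ev, {"s": [5]})
        assert (zs.flag == "singleton").all()


class TestBinning:
    @pytest.mark.parametrize("p,label", [
        (0.0, "0-0.19"), (0.19, "0-0.19"), (0.20, "0.2-0.39"),
        (0.59, "0.4-0.59"), (0.6, "0.6-0.79"), (0.8, "0.8-1"), (1.0, "0.8-1"),
    ])
    def test_boundaries(self, p, label):
        assert cm.bin_by_probability([p])[0] == label

    def test_every_probability_in_exactly_one_bin(self, rng):
        p = rng.rand(500)
        bins = cm.bin_by_probability(p)
        assert bins.isna().sum() == 0
        counts = pd.Series(bins).value_counts()
        assert counts.sum() == 500
        assert list(bins.categories) == PROBABILITY_BIN_LABELS

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cm.bin_by_probability([1.2])


class TestWelchAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        F, df1, df2, p = cm.welch_anova([g, g.copy(), g.copy()])
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_reduces_to_classical_anova_for_balanced_homoscedastic_pair(self, rng):
        """With two groups of equal size and identical sample variance the
        Welch correction vanishes and F equals the classical one-way F.
        (For k > 2 the Welch denominator 1 + 2*lam*(k-2)/3 exceeds 1 even
        under exact homoscedasticity, so exact equality holds only at k=2.)
        """
        base = rng.randn(12)
        groups = [base + 0.5, base - 0.2]  # identical sample variances
        F, df1, df2, p = cm.welch_anova(groups)
        F_classic = sps.f_oneway(*groups).statistic
        assert F == pytest.approx(F_classic, abs=1e-9)
        assert df1 == 1

    def test_approaches_classical_anova_under_homoscedasticity(self, rng):
        base = rng.randn(40)
        groups = [base + 0.5, base + 1.0, base - 0.2]
        F, *_ = cm.welch_anova(groups)
        F_classic = sps.f_oneway(*groups).statistic
        assert F == pytest.approx(F_classic, rel=0.05)
        assert F < F_classic  # correction strictly shrinks F

    def test_two_groups_equal_squared_welch_t(self, rng):
        a, b = rng.randn(10), rng.randn(14) * 2 + 1
        F, df1, df2, p = cm.welch_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert F == pytest.approx(t.statistic**2, abs=1e-9)
        assert p == pytest.approx(t.pvalue, abs=1e-9)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        groups = [rng.randn(8), rng.randn(12) * 3 + 1, rng.randn(20) - 1]
        F, df1, df2, p = cm.welch_anova(groups)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [8, 12, 20]),
        })
        res = pingouin.welch_anova(data=df, dv="y", between="g")
        assert F == pytest.approx(res["F"][0], rel=1e-9)
        assert p == pytest.approx(res["p_unc"][0], rel=1e-6)
        assert df2 == pytest.approx(res["ddof2"][0], rel=1e-6)

    def test_degenerate_groups_dropped(self):
        with pytest.warns(UserWarning):
            F, *_ = cm.welch_anova([[1.0, 2.0, 3.0], [5.0], [2.0, 4.0, 6.0]])
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                cm.welch_anova([[1.0, 2.0], [5.0]])


class TestTukeyKramer:
    def test_separated_groups_get_distinct_letters(self, rng):
        groups = {"lo": rng.randn(20), "hi": rng.randn(20) + 50}
        out = cm.tukey_kramer(groups)
        letters = out.set_index("group")["letters"]
        assert letters["lo"] != letters["hi"]

    def test_identical_groups_share_a_letter(self, rng):
        g = rng.randn(15)
        out = cm.tukey_kramer({"a": g, "b": g + 1e-9, "c": g - 1e-9})
        assert set(out["letters"]) == {"A"}

    def test_three_group_decisions_match_studentized_range(self, rng):
        """Brute-force Tukey-Kramer on a toy set with unequal n."""
        groups = {"a": rng.randn(8), "b": rng.randn(12) + 2.0,
                  "c": rng.randn(10) + 2.2}
        out = cm.tukey_kramer(groups, alpha=0.05)
        names = sorted(groups)
        ns = {g: len(groups[g]) for g in names}
        means = {g: np.mean(groups[g]) for g in names}
        df_w = sum(ns.values()) - len(names)
        s2 = sum((ns[g] - 1) * np.var(groups[g], ddof=1) for g in names) / df_w
        qcrit = sps.studentized_range.ppf(0.95, len(names), df_w)
        oracle = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                se = np.sqrt(s2 / 2 * (1 / ns[a] + 1 / ns[b]))
                oracle[(a, b)] = abs(means[a] - means[b]) / se > qcrit
        letters = out.set_index("group")["letters"]
        for (a, b), significant in oracle.items():
            share = bool(set(letters[a]) & set(letters[b]))
            assert share != significant

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            cm.tukey_kramer({"only": np.arange(5.0)})


class TestCoverageFraction:
    def _profile(self, probs):
        return pd.DataFrame({"substrate_id": "s",
                             "p1prime": range(5, 5 + len(probs)),
                             "probability": probs})

    def test_count_ratio(self):
        profile = self._profile([0.9, 0.85, 0.95, 0.8, 0.1])
        events = _event_frame([1, 1, 1], positions=[5, 6, 7])
        assert cm.coverage_fraction(profile, events, 0.8) == 0.75

    def test_full_coverage(self):
        profile = self._profile([0.9, 0.9])
        events = _event_frame([2, 1], positions=[5, 6])
        assert cm.coverage_fraction(profile, events, 0.8) == 1.0

    def test_no_sites_above_threshold_is_missing(self):
        profile = self._profile([0.1, 0.2])
        assert np.isnan(cm.coverage_fraction(profile, _event_frame([1]), 0.8))

    def test_matches_set_intersection_oracle(self, rng):
        probs = rng.rand(40)
        profile = self._profile(list(probs))
        counts = rng.poisson(0.5, 40)
        events = _event_frame(list(counts), positions=list(range(5, 45)))
        frac = cm.coverage_fraction(profile, events, 0.6)
        high = {p for p, pr in zip(range(5, 45), probs) if pr >= 0.6}
        hit = {p for p, c in zip(range(5, 45), counts) if c >= 1}
        assert frac == pytest.approx(len(high & hit) / len(high))


class TestLengthDistribution:
    def test_window_count(self):
        out = cm.length_distribution([ "A" * n for n in (5, 12, 19, 45)])
        assert out["frac_class_II"][0] == 0.5

    def test_uniform_lengths(self):
        out = cm.length_distribution(["A" * 15] * 4)
        assert out["mean_length"][0] == 15
        assert out["frac_class_II"][0] == 1.0

    def test_matches_histogram_oracle(self, rng):
        lengths = rng.randint(4, 50, size=200)
        out = cm.length_distribution(["A" * n for n in lengths])
        assert out["frac_class_II"][0] == pytest.approx(
            np.mean((lengths >= 11) & (lengths <= 20)))
        assert out["frac_class_I"][0] == pytest.approx(
            np.mean((lengths >= 8) & (lengths <= 11)))


class TestDistanceToHighProbSite:
    def _profile(self, sites):
        rows = [{"substrate_id": "s", "p1prime": p, "probability": 0.9}
                for p in sites]
        rows.append({"substrate_id": "s", "p1prime": 99, "probability": 0.1})
        return pd.DataFrame(rows)

    def test_event_at_site_has_distance_zero(self):
        ev = _event_frame([1], positions=[10])
        out = cm.distance_to_high_prob_site(ev, self._profile([10]))
        assert out.distance.tolist() == [0.0]

    def test_signed_offset(self):
        ev = _event_frame([1], positions=[7])
        out = cm.distance_to_high_prob_site(ev, self._profile([10]))
        assert out.distance.tolist() == [-3.0]

    def test_no_high_prob_site_gives_missing(self):
        ev = _event_frame([1], positions=[7])
        out = cm.distance_to_high_prob_site(ev, self._profile([]))
        assert out.distance.isna().all()

    def test_matches_exhaustive_search(self, rng):
        sites = sorted(rng.choice(range(5, 95), size=6, replace=False))
        positions = sorted(rng.choice(range(5, 95), size=20, replace=False))
        ev = _event_frame([1] * 20, positions=positions)
        out = cm.distance_to_high_prob_site(ev, self._profile(sites))
        for row in out.itertuples():
            offsets = [row.p1prime - s for s in sites]
            best = min(abs(o) for o in offsets)
            expected = min(o for o in offsets if abs(o) == best)
            assert row.distance == expected


class TestClusterSamples:
    def test_identical_pair_merges_first(self):
        presence = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
            index=["s1", "s2", "s3"])
        res = cm.cluster_samples(presence)
        Z = res["linkage"]
        assert Z[0, 2] == 0.0  # first merge at height zero
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_matches_lance_williams_recurrence(self):
        """Ward heights from the explicit Lance-Williams update on a toy matrix."""
        X = np.array([[0.0, 0.0], [1.0, 0.0], [4.0, 0.0], [4.0, 3.0]])
        presence = pd.DataFrame(X, index=list("abcd"))
        Z = cm.cluster_samples(presence)["linkage"]

        # brute-force Ward via Lance-Williams on squared Euclidean distances
        clusters = {i: [i] for i in range(4)}
        sizes = {i: 1 for i in range(4)}
        d2 = {}
        for i in range(4):
            for j in range(i + 1, 4):
                d2[(i, j)] = ((X[i] - X[j]) ** 2).sum()
        heights = []
        next_id = 4
        while len(clusters) > 1:
            (i, j), dij = min(d2.items(), key=lambda kv: kv[1])
            heights.append(np.sqrt(dij))
            ni, nj = sizes[i], sizes[j]
            new = {}
            for (a, b), dab in d2.items():
                if i in (a, b) or j in (a, b):
                    continue
                new[(a, b)] = dab
            for k in clusters:
                if k in (i, j):
                    continue
                nk = sizes[k]
                dik = d2[tuple(sorted((i, k)))]
                djk = d2[tuple(sorted((j, k)))]
                upd = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
                new[tuple(sorted((k, next_id)))] = upd
            del clusters[i], clusters[j]
            clusters[next_id] = True
            sizes[next_id] = ni + nj
            d2 = new
            next_id += 1
        np.testing.assert_allclose(sorted(Z[:, 2]), sorted(heights), atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cm.cluster_samples(pd.DataFrame([[1, 0]], index=["s1"]))
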