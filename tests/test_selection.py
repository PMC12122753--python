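import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from claimseg import synthetic as S
from claimseg.lca import fit_lca, posterior
from claimseg.selection import (FitSummary, average_silhouette, bic_elbow,
                                bootstrap_stability, compare_partitions,
                                correlation_screen, fit_grid,
                                holdout_confirmation, select, split_sample)

# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------


class TestScreen:
    def test_identical_columns_flagged(self, rng):
        a = rng.integers(0, 3, 500)
        df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.integers(0, 3, 500)})
        res = correlation_screen(df)
        assert any({"a", "b"} == {x, y} for x, y, _ in res.flagged_pairs)
        assert len(res.dropped) == 1

    def test_independent_columns_not_flagged(self, rng):
        df = pd.DataFrame({f"v{j}": rng.integers(0, 3, 10_000) for j in range(5)})
        res = correlation_screen(df)
        off_diag = res.correlation.to_numpy() - np.eye(5)
        assert np.abs(off_diag).max() < 0.05
        assert res.flagged_pairs == []
        assert res.dropped == []

    def test_noisy_copy_is_the_variable_dropped(self, spec):
        """The planted creatinine copy of HbA1c is removed, not HbA1c."""
        profiles, _ = S.sample_indicator_profiles(spec, 10_000, seed=3)
        res = correlation_screen(profiles)
        assert res.dropped == ["creatinine_cat"]
        assert res.retained.shape[1] == 10
        assert "hba1c_cat" in res.retained.columns


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------


class TestSplit:
    def test_sizes(self):
        train, val = split_sample(10, 0.7, seed=0)
        assert (len(train), len(val)) == (7, 3)

    def test_disjoint_exhaustive_and_deterministic(self):
        a_train, a_val = split_sample(40_561, 0.7, seed=9)
        b_train, b_val = split_sample(40_561, 0.7, seed=9)
        assert np.array_equal(a_train, b_train)
        assert len(np.intersect1d(a_train, a_val)) == 0
        assert len(a_train) + len(a_val) == 40_561

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            split_sample(10, 1.0)


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------


def brute_force_silhouette(X, labels):
    n = len(X)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.mean(X[i] != X[j])
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / (own.sum() - 1)
        b = min(d[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(s.mean())


class TestSilhouette:
    def test_duplicated_distinct_rows_score_one(self):
        df = pd.DataFrame([[0, 0, 0]] * 5 + [[2, 2, 2]] * 5, columns=list("abc"))
        labels = np.array([1] * 5 + [2] * 5)
        assert average_silhouette(df, labels) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 50))
            df = pd.DataFrame(rng.integers(0, 3, (n, 4)), columns=list("abcd"))
            labels = rng.integers(1, 4, n)
            if len(np.unique(labels)) < 2:
                continue
            ours = average_silhouette(df, labels)
            brute = brute_force_silhouette(df.to_numpy(), labels)
            assert ours == pytest.approx(brute, abs=1e-12)

    def test_random_partition_scores_near_zero(self, rng):
        df = pd.DataFrame(rng.integers(0, 3, (2000, 6)))
        df.columns = [f"v{j}" for j in range(6)]
        labels = rng.integers(1, 4, 2000)
        assert abs(average_silhouette(df, labels)) < 0.05

    def test_singleton_cluster_convention(self):
        df = pd.DataFrame([[0, 0], [0, 1], [2, 2]], columns=list("ab"))
        labels = np.array([1, 1, 2])
        # the singleton's s(i)=0 enters the average
        assert average_silhouette(df, labels) == pytest.approx(
            brute_force_silhouette(df.to_numpy(), labels))

    def test_requires_two_clusters(self):
        df = pd.DataFrame([[0], [1]], columns=["a"])
        with pytest.raises(ValueError):
            average_silhouette(df, np.array([1, 1]))

    def test_bounded(self, rng):
        df = pd.DataFrame(rng.integers(0, 3, (100, 4)), columns=list("abcd"))
        labels = rng.integers(1, 3, 100)
        assert -1.0 <= average_silhouette(df, labels) <= 1.0


# ---------------------------------------------------------------------------
# elbow
# ---------------------------------------------------------------------------


class TestElbow:
    def test_single_kink(self):
        # piecewise linear, kink at K=3
        bic = [100, 80, 60, 58, 56, 54]
        assert bic_elbow(bic) == 3

    def test_linear_sequence_warns(self):
        with pytest.warns(UserWarning, match="elbow"):
            assert bic_elbow([100, 90, 80, 70]) == 2

    def test_convex_decreasing_sequence(self):
        # second differences: K=2 -> 25, K=3 -> 12, K=4 -> 2
        assert bic_elbow([100, 60, 45, 42, 41]) == 2

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            bic_elbow([10, 9])


# ---------------------------------------------------------------------------
# decision rule
# ---------------------------------------------------------------------------


def _summary(bic, asw, icl, share=None, post=None):
    K = len(bic)
    table = pd.DataFrame({
        "K": range(1, K + 1), "bic": bic, "icl": icl,
        "asw": [np.nan] + list(asw[1:]),
        "min_class_share": share or [1.0] + [0.3] * (K - 1),
        "min_avg_posterior": post or [1.0] + [0.9] * (K - 1),
        "converged": True,
    }).set_index("K")
    return FitSummary(table, {})


class TestSelect:
    def test_unanimous_choice(self):
        # second differences of the BIC: K=2 -> -5, K=3 -> 24, K=4 -> 0.5
        s = _summary(bic=[100, 80, 55, 54, 53.5],
                     asw=[np.nan, 0.2, 0.5, 0.3, 0.2],
                     icl=[100, 75, 60, 70, 80])
        rep = select(s)
        assert rep.candidates == {"bic_elbow": 3, "max_asw": 3, "min_icl": 3}
        assert rep.chosen_K == 3 and not rep.failed

    def test_no_majority_falls_back_to_asw(self):
        s = _summary(bic=[100, 70, 55, 54, 53.9],   # elbow 2... craft distinct
                     asw=[np.nan, 0.2, 0.3, 0.5, 0.2],
                     icl=[100, 75, 70, 69, 60])
        rep = select(s)
        assert len(set(rep.candidates.values())) == 3
        assert rep.chosen_K == rep.candidates["max_asw"]
        assert any("no majority" in t for t in rep.trace)

    def test_constraint_violation_moves_to_next_candidate(self):
        share = [1.0, 0.3, 0.03, 0.3, 0.3]  # K=3 has a 3% class
        s = _summary(bic=[100, 70, 55, 54, 53.5],
                     asw=[np.nan, 0.4, 0.5, 0.3, 0.2],
                     icl=[100, 75, 60, 70, 80], share=share)
        rep = select(s)
        assert rep.chosen_K == 2  # next candidate by ASW rank
        assert any("violates" in t for t in rep.trace)

    def test_total_failure_is_flagged(self):
        share = [1.0, 0.01, 0.01, 0.01, 0.01]
        s = _summary(bic=[100, 70, 55, 54, 53.5],
                     asw=[np.nan, 0.4, 0.5, 0.3, 0.2],
                     icl=[100, 75, 60, 70, 80], share=share)
        rep = select(s)
        assert rep.failed and rep.chosen_K is None

    def test_chosen_model_respects_constraints(self, spec):
        """Whatever is chosen satisfies the share and posterior floors."""
        profiles, _ = S.sample_indicator_profiles(spec, 3000, seed=31)
        ten = profiles.drop(columns=["creatinine_cat"])
        summary = fit_grid(ten, Kmax=4, restarts=5, seed=31)
        rep = select(summary)
        assert rep.chosen_K is not None
        row = summary.table.loc[rep.chosen_K]
        assert row["min_class_share"] >= rep.constraints["min_class_share"]
        assert row["min_avg_posterior"] >= rep.constraints["min_avg_posterior"]


# ---------------------------------------------------------------------------
# partition agreement
# ---------------------------------------------------------------------------


def brute_force_pair_counts(a, b):
    n11 = n10 = n01 = n00 = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        n11 += sa and sb
        n10 += sa and not sb
        n01 += sb and not sa
        n00 += not sa and not sb
    return n11, n10, n01, n00


def brute_force_ari(a, b):
    n11, n10, n01, n00 = brute_force_pair_counts(a, b)
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = ((n11 + n10) + (n11 + n01)) / 2
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


class TestComparePartitions:
    def test_identity_and_label_swap(self):
        a = np.array([1, 1, 2, 2, 3])
        assert compare_partitions(a, a) == (1.0, 1.0)
        swapped = np.array([3, 3, 1, 1, 2])
        assert compare_partitions(a, swapped) == (1.0, 1.0)

    def test_matches_exhaustive_pair_enumeration(self):
        a, b = np.array([1, 1, 1, 2]), np.array([1, 1, 2, 2])
        ari, jac = compare_partitions(a, b)
        n11, n10, n01, _ = brute_force_pair_counts(a, b)
        assert jac == pytest.approx(n11 / (n11 + n10 + n01))
        assert ari == pytest.approx(brute_force_ari(a, b))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(1, 4), min_size=3, max_size=30))
    def test_symmetric_and_oracle_consistent(self, labels):
        rng = np.random.default_rng(len(labels))
        a = np.asarray(labels)
        b = rng.integers(1, 4, len(a))
        ari_ab, jac_ab = compare_partitions(a, b)
        ari_ba, jac_ba = compare_partitions(b, a)
        assert ari_ab == pytest.approx(ari_ba)
        assert jac_ab == pytest.approx(jac_ba)
        assert ari_ab == pytest.approx(brute_force_ari(a, b))
        # permutation invariance
        perm = {1: 4, 2: 3, 3: 2, 4: 1}
        b_perm = np.asarray([perm[x] for x in b])
        assert compare_partitions(a, b_perm) == pytest.approx((ari_ab, jac_ab))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_partitions(np.array([1, 2]), np.array([1, 2, 3]))


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------


class TestStability:
    def test_zero_resamples_empty_report(self, spec):
        profiles, _ = S.sample_indicator_profiles(spec, 300, seed=1)
        ten = profiles.drop(columns=["creatinine_cat"])
        model = fit_lca(ten, 3, restarts=3, seed=1)
        rep = bootstrap_stability(ten, model, B=0)
        assert len(rep.per_resample) == 0

    def test_well_separated_classes_are_stable(self, spec):
        profiles, _ = S.sample_indicator_profiles(spec, 3000, seed=17)
        ten = profiles.drop(columns=["creatinine_cat"])
        model = fit_lca(ten, 3, restarts=10, seed=17)
        rep = bootstrap_stability(ten, model, B=5, seed=17, restarts=5)
        assert rep.mean_ari >= 0.9
        assert rep.mean_jaccard >= 0.85

    def test_pure_noise_is_unstable(self, rng):
        noise = pd.DataFrame(rng.integers(0, 3, (1000, 8)))
        noise.columns = [f"v{j}" for j in range(8)]
        model = fit_lca(noise, 3, restarts=5, seed=0)
        rep = bootstrap_stability(noise, model, B=5, seed=0, restarts=5)
        assert rep.mean_ari < 0.2

    def test_holdout_confirms_on_same_generator(self, spec):
        profiles, _ = S.sample_indicator_profiles(spec, 4000, seed=23)
        ten = profiles.drop(columns=["creatinine_cat"])
        train_idx, val_idx = split_sample(4000, 0.7, seed=23)
        model = fit_lca(ten.iloc[train_idx], 3, restarts=10, seed=23)
        rep = holdout_confirmation(model, ten.iloc[val_idx], seed=24)
        assert rep.passed
        assert rep.mean_ari >= 0.9
        assert rep.min_avg_posterior >= 0.8

    def test_holdout_rejects_empty_validation(self, spec):
        profiles, _ = S.sample_indicator_profiles(spec, 200, seed=1)
        ten = profiles.drop(columns=["creatinine_cat"])
        model = fit_lca(ten, 2, restarts=2, seed=1)
        with pytest.raises(ValueError):
            holdout_confirmation(model, ten.iloc[0:0])
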