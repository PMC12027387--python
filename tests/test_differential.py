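"""Normalization, imputation, moderated statistics, permutation FDR, k-means."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosphoprimer.differential import (
    Contrast,
    call_features,
    impute_missing,
    kmeans_de_clusters,
    median_normalize,
    moderated_test,
    permutation_fdr,
)
from phosphoprimer.io_tables import FeatureMatrix

CONTRAST = Contrast("mck1del", "WT", "PDS")


def pds_columns(n=3):
    return [f"WT_PDS_{i+1}" for i in range(n)] + [
        f"mck1del_PDS_{i+1}" for i in range(n)
    ]


def random_matrix(n_features, n=3, seed=0, layer="protein"):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.normal(20.0, 1.0, size=(n_features, 2 * n)),
        index=[f"f{i}" for i in range(n_features)],
        columns=pds_columns(n),
    )
    return FeatureMatrix(values, layer)


class TestMedianNormalize:
    def test_idempotent(self):
        m = random_matrix(50, seed=1)
        once = median_normalize(m)
        twice = median_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values, atol=1e-12, rtol=0)

    def test_removes_shift_between_samples(self):
        # a one-sample shift is removed exactly: the two normalized matrices
        # agree up to one global constant, which cancels in every contrast
        m = random_matrix(50, seed=2)
        shifted = m.copy()
        shifted.values.iloc[:, 0] += 1.0
        a = median_normalize(m)
        b = median_normalize(shifted)
        diff = (b.values - a.values).to_numpy()
        assert np.allclose(diff, diff[0, 0], atol=1e-12)

    def test_per_sample_medians_equalized(self):
        rng = np.random.default_rng(3)
        m = random_matrix(80, seed=3)
        m.values.iloc[rng.integers(0, 80, 40), 2] = np.nan  # absences survive
        out = median_normalize(m)
        med = out.values.median(axis=0, skipna=True)
        assert np.allclose(med, med.iloc[0], atol=1e-12)
        assert out.values.isna().sum().sum() == m.values.isna().sum().sum()

    def test_all_absent_sample_rejected(self):
        m = random_matrix(10)
        m.values.iloc[:, 1] = np.nan
        with pytest.raises(ValueError, match="no present values"):
            median_normalize(m)

    def test_scale_equivariance_through_pipeline(self):
        """Adding a constant to one sample changes nothing downstream."""
        m = random_matrix(200, seed=4)
        shifted = m.copy()
        shifted.values["WT_PDS_2"] += 3.7
        r1 = moderated_test(median_normalize(m), CONTRAST)
        r2 = moderated_test(median_normalize(shifted), CONTRAST)
        pd.testing.assert_frame_equal(r1, r2, atol=1e-9, rtol=0)


class TestImpute:
    def test_identity_without_missing(self):
        m = random_matrix(30, seed=5)
        out = impute_missing(m, seed=1)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_narrow_width_draws_below_mean(self):
        m = random_matrix(500, seed=6)
        rng = np.random.default_rng(0)
        mask = rng.random(m.values.shape) < 0.2
        m.values[mask] = np.nan
        out = impute_missing(m, width_factor=0.01, downshift=1.8, seed=2)
        for col in m.values.columns:
            observed = m.values[col].dropna()
            imputed = out.values.loc[m.values[col].isna(), col]
            assert (imputed < observed.mean()).all()

    def test_imputed_mean_matches_downshifted_normal(self):
        # one sample with 10^4 absences; empirical mean within 3 s.e. of
        # mean - 1.8 sd
        rng = np.random.default_rng(7)
        n = 2 * 10**4
        values = pd.DataFrame(
            rng.normal(20, 1, size=(n, 4)),
            index=[f"f{i}" for i in range(n)],
            columns=["WT_PDS_1", "WT_PDS_2", "mck1del_PDS_1", "mck1del_PDS_2"],
        )
        values.iloc[: 10**4, 0] = np.nan
        m = FeatureMatrix(values, "protein")
        observed = values["WT_PDS_1"].dropna()
        mu, sd = observed.mean(), observed.std(ddof=1)
        out = impute_missing(m, width_factor=0.3, downshift=1.8, seed=3)
        imputed = out.values.iloc[: 10**4, 0]
        se = 0.3 * sd / np.sqrt(10**4)
        assert abs(imputed.mean() - (mu - 1.8 * sd)) < 3 * se

    def test_too_few_present_values_rejected(self):
        m = random_matrix(5)
        m.values.iloc[:3, 0] = np.nan
        with pytest.raises(ValueError, match="present values"):
            impute_missing(m)


class TestModeratedTest:
    def test_prior_off_equals_ordinary_t(self):
        m = random_matrix(300, seed=8)
        res = moderated_test(m, CONTRAST, d0=0)
        x1 = m.values[m.samples_for("mck1del", "PDS")].to_numpy()
        x2 = m.values[m.samples_for("WT", "PDS")].to_numpy()
        ref = stats.ttest_ind(x1, x2, axis=1, equal_var=True)
        assert np.allclose(res["t"], ref.statistic, atol=1e-9)
        assert np.allclose(res["p_value"], ref.pvalue, atol=1e-9)

    def test_identical_variances_collapse_to_ordinary_t(self):
        # every feature shows the same replicate pattern, hence identical s^2
        base = np.linspace(10, 30, 100)
        pattern = np.array([0.0, 1.0, 2.0, 0.5, 1.5, 2.5])
        values = pd.DataFrame(
            base[:, None] + pattern[None, :],
            index=[f"f{i}" for i in range(100)],
            columns=pds_columns(3),
        )
        m = FeatureMatrix(values, "protein")
        res = moderated_test(m, CONTRAST)
        ref = moderated_test(m, CONTRAST, d0=0)
        assert np.isinf(res.attrs["df_total"])
        assert np.allclose(res["t"], ref["t"], atol=1e-9)

    def test_null_pvalues_uniform(self):
        m = random_matrix(2000, seed=9)
        res = moderated_test(m, CONTRAST)
        ks = stats.kstest(res["p_value"], "uniform").statistic
        assert ks < 1.628 / np.sqrt(2000)  # 1% critical value

    def test_missing_values_rejected(self):
        m = random_matrix(10)
        m.values.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            moderated_test(m, CONTRAST)


class TestPermutationFdr:
    def test_strong_effect_reaches_low_q(self):
        m = random_matrix(1000, seed=10)
        m.values.loc["f0", m.samples_for("mck1del", "PDS")] += 4.0
        res = permutation_fdr(m, CONTRAST, n_permutations=9, seed=0)
        assert res["q_value"].loc["f0"] < 0.05
        assert np.abs(res["t"]).idxmax() == "f0"

    def test_q_monotone_in_abs_t(self):
        m = random_matrix(500, seed=11)
        m.values.iloc[:50, 3:] += 1.0
        res = permutation_fdr(m, CONTRAST, n_permutations=9, seed=0)
        ordered = res.reindex(np.abs(res["t"]).sort_values(ascending=False).index)
        assert (np.diff(ordered["q_value"]) >= -1e-12).all()

    def test_requesting_more_permutations_warns(self):
        m = random_matrix(50, seed=12)
        with pytest.warns(UserWarning, match="distinct label permutations"):
            permutation_fdr(m, CONTRAST, n_permutations=100, seed=0)

    def test_null_fraction_discovered_is_tiny(self):
        fractions = []
        for seed in range(20):
            m = random_matrix(1000, seed=100 + seed)
            res = permutation_fdr(m, CONTRAST, n_permutations=9, seed=seed)
            fractions.append((res["q_value"] < 0.05).mean())
        assert np.mean(fractions) <= 0.01


class TestCalls:
    def _frame(self, lfc, q):
        return pd.DataFrame({"log2FC": [lfc], "t": [0.0], "p_value": [q],
                             "q_value": [q]}, index=["f0"])

    @pytest.mark.parametrize(
        "lfc,q,expected",
        [
            (-1.2, 0.01, "reduced"),
            (-1.2, 0.2, "unchanged"),
            (1.2, 0.01, "enhanced"),
            (-0.9, 0.01, "unchanged"),  # below the 2-fold cut
        ],
    )
    def test_thresholds(self, lfc, q, expected):
        out = call_features(self._frame(lfc, q), fold_threshold=2.0,
                            fdr_threshold=0.05)
        assert out["call"].iloc[0] == expected

    def test_invalid_fold_rejected(self):
        with pytest.raises(ValueError, match="fold_threshold"):
            call_features(self._frame(0, 1), fold_threshold=0.0)

    def test_missing_q_rejected(self):
        frame = self._frame(0, 1).drop(columns="q_value")
        with pytest.raises(ValueError, match="q_values"):
            call_features(frame)

    def test_planted_effect_recovery(self):
        """Planted 2 log2 reductions at cv 0.2, n=3: high sensitivity, low FPR."""
        rng = np.random.default_rng(13)
        sd = np.sqrt(np.log1p(0.2**2)) / np.log(2)
        n_feat, n_true = 2000, 100
        values = pd.DataFrame(
            rng.normal(20, 1, size=(n_feat, 1)) + rng.normal(0, sd, (n_feat, 6)),
            index=[f"f{i}" for i in range(n_feat)],
            columns=pds_columns(3),
        )
        m = FeatureMatrix(values, "phospho")
        mut = m.samples_for("mck1del", "PDS")
        m.values.iloc[:n_true, [m.sample_ids.index(s) for s in mut]] -= 2.0
        res = call_features(
            permutation_fdr(m, CONTRAST, n_permutations=9, seed=1), 2.0, 0.05
        )
        calls = res["call"]
        sensitivity = (calls.iloc[:n_true] == "reduced").mean()
        fpr = (calls.iloc[n_true:] != "unchanged").mean()
        assert sensitivity >= 0.8
        assert fpr <= 0.05


class TestKmeans:
    def _planted_profiles(self, per_cluster=30, seed=0):
        # four separable profiles over the 4 genotype-phase groups
        rng = np.random.default_rng(seed)
        group_profiles = {
            "up_in_pds": [0, 0, 0, 0, 5, 5, 5, 5, 0, 0, 0, 0, 5, 5, 5, 5],
            "down_in_pds": [5, 5, 5, 5, 0, 0, 0, 0, 5, 5, 5, 5, 0, 0, 0, 0],
            "wt_only_up": [5, 5, 5, 5, 5, 5, 5, 5, 0, 0, 0, 0, 0, 0, 0, 0],
            "mut_only_up": [0, 0, 0, 0, 0, 0, 0, 0, 5, 5, 5, 5, 5, 5, 5, 5],
        }
        cols = [
            f"{g}_{p}_{r+1}"
            for g in ("WT", "mck1del")
            for p in ("EXP", "PDS")
            for r in range(4)
        ]
        rows, labels = [], []
        for label, profile in group_profiles.items():
            for _ in range(per_cluster):
                rows.append(np.array(profile) + rng.normal(0, 0.3, 16))
                labels.append(label)
        values = pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(rows))], columns=cols
        )
        return FeatureMatrix(values, "transcript"), labels

    def test_planted_cluster_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        m, labels = self._planted_profiles(seed=1)
        out = kmeans_de_clusters(m, k=4, seed=0, n_restarts=10)
        assert adjusted_rand_score(labels, out["cluster"]) >= 0.95

    def test_k1_single_cluster(self):
        m, _ = self._planted_profiles(per_cluster=5, seed=2)
        out = kmeans_de_clusters(m, k=1, seed=0, n_restarts=2)
        assert (out["cluster"] == 1).all()

    def test_same_seed_same_assignments(self):
        m, _ = self._planted_profiles(per_cluster=10, seed=3)
        a = kmeans_de_clusters(m, k=4, seed=5, n_restarts=5)
        b = kmeans_de_clusters(m, k=4, seed=5, n_restarts=5)
        pd.testing.assert_frame_equal(a, b)

    def test_k_exceeding_features_rejected(self):
        m, _ = self._planted_profiles(per_cluster=1, seed=4)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_de_clusters(m, k=10)

    def test_clusters_ordered_by_size(self):
        m, _ = self._planted_profiles(per_cluster=10, seed=5)
        extra, _ = self._planted_profiles(per_cluster=2, seed=6)
        out = kmeans_de_clusters(m, k=4, seed=0, n_restarts=5)
        sizes = out["cluster"].value_counts().sort_index()
        assert (np.diff(sizes.to_numpy()) <= 0).all()
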