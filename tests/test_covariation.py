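import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peakcovar.core import EnrichmentMatrix
from peakcovar import covariation as cov
from peakcovar import enrichment as enr
from peakcovar.simulate import simulate_annotation, simulate_counts


def linear_frame(rows, samples=4):
    cols = [f"s{i}" for i in range(samples)]
    return pd.DataFrame(rows, columns=cols, index=[f"r{i}" for i in range(len(rows))])


class TestFoldChangeOverMean:
    def test_constant_row_is_zero(self):
        prof = cov.fold_change_over_mean(linear_frame([[2, 2, 2, 2]]))
        assert np.allclose(prof.fc_over_mean.to_numpy(), 0.0)

    def test_arithmetic(self):
        prof = cov.fold_change_over_mean(linear_frame([[1, 1, 1, 5]]))
        assert prof.fc_over_mean.iloc[0, 3] == pytest.approx(np.log2(2.5))

    def test_linear_row_mean_one(self):
        rng = np.random.default_rng(0)
        prof = cov.fold_change_over_mean(linear_frame(rng.gamma(3, 10, (50, 4))))
        assert np.allclose((2.0 ** prof.fc_over_mean).mean(axis=1), 1.0, atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cov.fold_change_over_mean(linear_frame([[1]], samples=1))

    def test_within_twofold_decreases_with_dispersion(self, small_sim_config):
        fracs = []
        for disp in (0.02, 0.5):
            cfg = small_sim_config(3, n_genes=300, n_broad_peaks=200, dispersion=disp,
                                   n_cluster_regions=0, n_de_regions=0)
            sim = simulate_annotation(cfg)
            _, broad, *_ = simulate_counts(cfg, sim)
            sf = enr.size_factors_median_ratio(broad)
            prof = cov.fold_change_over_mean(broad.values / sf)
            fracs.append(prof.fraction_within_twofold.mean())
        assert fracs[0] > 0.9
        assert fracs[0] > fracs[1]


class TestTopVariable:
    def test_k_equals_n_returns_all(self):
        df = linear_frame([[1, 2, 3, 4], [4, 4, 4, 4]])
        assert set(cov.top_variable(df, k=2)) == {"r0", "r1"}

    def test_constant_rows_rank_last(self):
        df = linear_frame([[4, 4, 4, 4], [1, 9, 1, 9]])
        assert cov.top_variable(df, k=1) == ["r1"]

    def test_invalid_k(self):
        df = linear_frame([[1, 2, 3, 4]])
        with pytest.raises(ValueError):
            cov.top_variable(df, k=0)
        with pytest.raises(ValueError):
            cov.top_variable(df, k=5)

    def test_planted_factor_regions_dominate_topk(self, small_sim_config):
        cfg = small_sim_config(4, n_genes=500, n_broad_peaks=400, depth=800_000,
                               n_cluster_regions=40, n_de_regions=0, loading=2.5)
        sim = simulate_annotation(cfg)
        _, broad, _, truth = simulate_counts(cfg, sim)
        sf = enr.size_factors_median_ratio(broad)
        log2m = enr.normalize_log2(broad, sf)
        top = set(cov.top_variable(log2m, k=80))
        planted = set(truth.cluster_members)
        assert len(top & planted) / 80 >= 0.95


class TestCorrelationWithP:
    def test_self_and_antisymmetric(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        df = pd.DataFrame([x, -x], index=["a", "b"],
                          columns=[f"s{i}" for i in range(6)])
        res = cov.correlation_with_p(df)
        assert res.r.loc["a", "a"] == 1.0
        assert res.r.loc["a", "b"] == pytest.approx(-1.0)
        assert res.p.loc["a", "b"] == 0.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(6, 10)),
                          index=[f"r{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(10)])
        res = cov.correlation_with_p(df)
        for i in range(6):
            for j in range(i + 1, 6):
                r, p = stats.pearsonr(df.iloc[i], df.iloc[j])
                assert res.r.iloc[i, j] == pytest.approx(r)
                assert res.p.iloc[i, j] == pytest.approx(p, rel=1e-6)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        y = 0.8 * x + 0.6 * rng.normal(size=10)
        df = pd.DataFrame([x, y], index=["a", "b"],
                          columns=[f"s{i}" for i in range(10)])
        res = cov.correlation_with_p(df)
        r_obs = res.r.loc["a", "b"]
        n_perm = 10_000
        hits = 0
        for _ in range(n_perm):
            hits += abs(np.corrcoef(x, rng.permutation(y))[0, 1]) >= abs(r_obs)
        p_perm = (hits + 1) / (n_perm + 1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p.loc["a", "b"] - p_perm) < max(mc_err, 5e-3)

    def test_zero_variance_row_flagged(self):
        df = linear_frame([[1, 1, 1, 1], [1, 2, 3, 4]])
        res = cov.correlation_with_p(df)
        assert np.isnan(res.r.loc["r0", "r1"])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cov.correlation_with_p(linear_frame([[1, 2, 3]], samples=3))


def opposing_matrix():
    """Two perfect anti-correlated pairs across clusters."""
    f = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5, 1.5, -1.5])
    cols = [f"s{i}" for i in range(8)]
    rows = {"a1": f, "a2": f * 2 + 0.01, "b1": -f, "b2": -f * 3 - 0.02}
    return pd.DataFrame(rows, index=cols).T


class TestExtractOpposingSubset:
    def test_two_pairs_full_split(self):
        res = cov.extract_opposing_subset(cov.correlation_with_p(opposing_matrix()))
        assert sorted(res.selected_ids) == ["a1", "a2", "b1", "b2"]
        assert {res.cluster_label["a1"], res.cluster_label["b1"]} == {"A", "B"}
        assert res.cluster_label["a1"] == res.cluster_label["a2"]
        assert res.cluster_label["b1"] == res.cluster_label["b2"]

    def test_all_positive_matrix_empty(self):
        f = np.arange(8.0)
        df = pd.DataFrame({"a": f, "b": f * 2 + 0.1, "c": f + 0.2},
                          index=[f"s{i}" for i in range(8)]).T
        res = cov.extract_opposing_subset(cov.correlation_with_p(df))
        assert res.selected_ids == []

    def test_deterministic_and_relabel_invariant(self):
        mat = opposing_matrix()
        r1 = cov.extract_opposing_subset(cov.correlation_with_p(mat))
        r2 = cov.extract_opposing_subset(cov.correlation_with_p(mat))
        assert r1.cluster_label == r2.cluster_label
        renamed = mat.rename(index={"a1": "z9"})
        r3 = cov.extract_opposing_subset(cov.correlation_with_p(renamed))
        assert len(r3.selected_ids) == 4 and "z9" in r3.selected_ids

    def test_membership_invariant_holds(self, small_sim_config):
        cfg = small_sim_config(5, n_genes=500, n_broad_peaks=400, depth=800_000,
                               n_cluster_regions=30, n_de_regions=0)
        sim = simulate_annotation(cfg)
        _, broad, _, truth = simulate_counts(cfg, sim)
        sf = enr.size_factors_median_ratio(broad)
        log2m = enr.normalize_log2(broad, sf)
        corr = cov.correlation_with_p(log2m, cov.top_variable(log2m, k=300))
        res = cov.extract_opposing_subset(corr)
        assert res.selected_ids
        for rid in res.selected_ids:
            own = [x for x in res.selected_ids
                   if res.cluster_label[x] == res.cluster_label[rid] and x != rid]
            other = [x for x in res.selected_ids
                     if res.cluster_label[x] != res.cluster_label[rid]]
            assert max(corr.r.loc[rid, own]) >= 0.8
            assert min(corr.r.loc[rid, other]) <= -0.8

    def test_null_data_mostly_empty(self):
        sizes = []
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            df = pd.DataFrame(rng.normal(size=(150, 12)),
                              index=[f"r{i}" for i in range(150)],
                              columns=[f"s{i}" for i in range(12)])
            res = cov.extract_opposing_subset(cov.correlation_with_p(df))
            sizes.append(len(res.selected_ids))
        assert np.median(sizes) == 0


class TestPcaVariance:
    def test_rank_one_matrix(self):
        f = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 2.0])
        loadings = np.array([[1.0], [2.0], [-1.0], [0.5]])
        df = pd.DataFrame(loadings @ f[None, :],
                          index=[f"r{i}" for i in range(4)],
                          columns=[f"s{i}" for i in range(6)])
        fractions, _, _ = cov.pca_variance(df)
        assert fractions[0] == pytest.approx(1.0)

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(400, 12)),
                          index=[f"r{i}" for i in range(400)],
                          columns=[f"s{i}" for i in range(12)])
        fractions, _, _ = cov.pca_variance(df)
        # pure noise: PC1 share near 1/11 (row-centering removes one df),
        # well below any factor-driven share
        assert fractions[0] < 0.2
        assert fractions.sum() == pytest.approx(1.0)

    def test_subset_share_exceeds_full_share(self, small_sim_config):
        cfg = small_sim_config(6, n_genes=500, n_broad_peaks=400, depth=800_000,
                               n_cluster_regions=40, n_de_regions=0)
        sim = simulate_annotation(cfg)
        _, broad, _, truth = simulate_counts(cfg, sim)
        sf = enr.size_factors_median_ratio(broad)
        log2m = enr.normalize_log2(broad, sf)
        model = cov.CovariationAnalysis(log2m, cfg.sample_meta())
        res = model.fit(top_k=400)
        assert res.selected_ids
        assert res.pc_variance_subset[0] > res.pc_variance_full[0]
        assert "group" in res.factor_association
        assert "Opposing-cluster" in res.summary()
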