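import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from peakcovar.core import EnrichmentMatrix, PeakSet, SampleMeta
from peakcovar import diffenrich as de
from peakcovar import genomic_io as gio
from peakcovar.enrichment import size_factors_median_ratio
from peakcovar.simulate import simulate_annotation, simulate_counts


def brute_force_bh(p):
    """Step-up definition, written independently of the implementation."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.full(m, np.nan)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBhAdjust:
    def test_closed_form(self):
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(de.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    def test_nan_propagates_and_excluded_from_m(self):
        q = de.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], de.bh_adjust([0.01, 0.04]))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_bruteforce(self, p):
        p = np.asarray(p)
        assert np.allclose(de.bh_adjust(p), brute_force_bh(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        _, q_sm, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(de.bh_adjust(p), q_sm)


class TestEstimateDispersions:
    def test_poisson_data_near_floor(self, meta_4v4, nb_matrix_factory):
        mat = nb_matrix_factory(0, n_regions=2000, mu=300.0, alpha=0.0)
        sf = pd.Series(1.0, index=mat.values.columns)
        disp = de.estimate_dispersions(mat, meta_4v4, sf)
        assert disp.median() <= 0.01

    def test_nb_dispersion_recovered(self, meta_4v4, nb_matrix_factory):
        mat = nb_matrix_factory(1, n_regions=2000, mu=300.0, alpha=0.05)
        sf = pd.Series(1.0, index=mat.values.columns)
        disp = de.estimate_dispersions(mat, meta_4v4, sf)
        assert 0.03 <= disp.median() <= 0.08

    def test_constant_counts_hit_floor(self, meta_4v4):
        values = pd.DataFrame(7, index=[f"r{i}" for i in range(20)],
                              columns=meta_4v4.sample_ids)
        sf = pd.Series(1.0, index=meta_4v4.sample_ids)
        disp = de.estimate_dispersions(EnrichmentMatrix(values), meta_4v4, sf)
        assert (disp == de.DISPERSION_FLOOR).all()

    def test_single_sample_group_rejected(self):
        meta = SampleMeta(pd.DataFrame({"group": ["CTRL", "CTRL", "MS"]},
                                       index=["a", "b", "c"]))
        values = pd.DataFrame(1, index=["r0"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            de.estimate_dispersions(EnrichmentMatrix(values), meta,
                                    pd.Series(1.0, index=["a", "b", "c"]))


class TestNbWaldTest:
    def test_matches_statsmodels_glm(self, meta_4v4, nb_matrix_factory):
        import statsmodels.api as sm

        alpha = 0.08
        mat = nb_matrix_factory(2, n_regions=15, mu=200.0, alpha=alpha, fc_test=1.7)
        sf = pd.Series(np.linspace(0.8, 1.2, 8), index=mat.values.columns)
        disp = pd.Series(alpha, index=mat.values.index)
        tab = de.nb_wald_test(mat, meta_4v4, sf, disp, ("MS", "CTRL"))
        X = sm.add_constant(np.array([0.0] * 4 + [1.0] * 4))
        for i in range(15):
            fit = sm.GLM(mat.values.iloc[i].to_numpy(), X,
                         family=sm.families.NegativeBinomial(alpha=alpha),
                         offset=np.log(sf.to_numpy())).fit()
            assert tab["log2fc"].iloc[i] == pytest.approx(fit.params[1] / np.log(2), abs=1e-6)
            assert tab["se"].iloc[i] == pytest.approx(fit.bse[1] / np.log(2), abs=1e-6)

    def test_poisson_limit_equals_mean_ratio(self, meta_4v4, nb_matrix_factory):
        mat = nb_matrix_factory(3, n_regions=50, mu=500.0, alpha=0.0, fc_test=2.0)
        sf = pd.Series(1.0, index=mat.values.columns)
        disp = pd.Series(1e-12, index=mat.values.index)
        tab = de.nb_wald_test(mat, meta_4v4, sf, disp, ("MS", "CTRL"))
        y = mat.values
        expected = np.log2(y.iloc[:, 4:].mean(axis=1) / y.iloc[:, :4].mean(axis=1))
        assert np.allclose(tab["log2fc"], expected, atol=1e-6)

    def test_all_zero_region_flagged(self, meta_4v4):
        values = pd.DataFrame(0, index=["r0"], columns=meta_4v4.sample_ids)
        mat = EnrichmentMatrix(values)
        sf = pd.Series(1.0, index=meta_4v4.sample_ids)
        tab = de.nb_wald_test(mat, meta_4v4, sf, pd.Series(0.05, index=["r0"]))
        assert np.isnan(tab["wald_p"].iloc[0])
        assert not tab["converged"].iloc[0]

    def test_planted_fold_change_recovered(self, meta_4v4, nb_matrix_factory):
        mat = nb_matrix_factory(4, n_regions=500, mu=500.0, alpha=0.01, fc_test=2.0)
        sf = pd.Series(1.0, index=mat.values.columns)
        disp = pd.Series(0.01, index=mat.values.index)
        tab = de.nb_wald_test(mat, meta_4v4, sf, disp, ("MS", "CTRL"))
        assert 0.8 <= tab["log2fc"].median() <= 1.2

    def test_missing_contrast_group_rejected(self, meta_4v4, nb_matrix_factory):
        mat = nb_matrix_factory(5, n_regions=5)
        sf = pd.Series(1.0, index=mat.values.columns)
        with pytest.raises(ValueError, match="contrast"):
            de.nb_wald_test(mat, meta_4v4, sf, pd.Series(0.05, index=mat.values.index),
                            ("HD", "CTRL"))


def assigned_peaks(sim):
    return gio.assign_peaks(sim.broad_peaks, sim.annotation.tss)


class TestPeakWorkflow:
    def test_final_calls_nested_in_fdr_calls(self, small_sim_config):
        cfg = small_sim_config(11, depth=500_000)
        sim = simulate_annotation(cfg)
        _, broad, inp, truth = simulate_counts(cfg, sim)
        res = de.de_peak_workflow(broad, cfg.sample_meta(), assigned_peaks(sim), inp,
                                  contrasts=(("MS", "CTRL"),))[("MS", "CTRL")]
        calls = res.calls
        assert (calls["final"] <= calls["passes_fdr"]).all()
        assert set(calls.index) == set(broad.values.index)
        assert "NB differential enrichment" in res.summary()

    def test_input_biased_region_excluded(self, meta_4v4, nb_matrix_factory):
        # a clear enrichment difference whose input is 4x biased must not be final
        mat = nb_matrix_factory(6, n_regions=60, mu=400.0, alpha=0.01)
        strong = mat.values.copy()
        strong.iloc[0, 4:] = (strong.iloc[0, 4:] * 6).astype(int)  # huge MS effect
        mat = EnrichmentMatrix(strong)
        inp = pd.DataFrame(100, index=mat.values.index, columns=mat.values.columns)
        inp.iloc[0, 4:] = 400  # 4-fold input bias in MS
        input_counts = EnrichmentMatrix(inp)
        peaks_df = pd.DataFrame(
            {"chrom": "chr1",
             "start": np.arange(60) * 1000,
             "end": np.arange(60) * 1000 + 500},
            index=mat.values.index)
        peaks = PeakSet(peaks_df)
        peaks.gene_assignments = {rid: ["g"] for rid in mat.values.index}
        res = de.de_peak_workflow(mat, meta_4v4, peaks, input_counts,
                                  contrasts=(("MS", "CTRL"),))[("MS", "CTRL")]
        rid = mat.values.index[0]
        assert res.calls.loc[rid, "passes_fdr"]
        assert not res.calls.loc[rid, "input_bias_ok"]
        assert not res.calls.loc[rid, "final"]

    def test_missing_input_skips_bias_filter_with_warning(self, small_sim_config):
        cfg = small_sim_config(12, n_genes=200, n_broad_peaks=150, depth=100_000,
                               n_cluster_regions=0, n_de_regions=0)
        sim = simulate_annotation(cfg)
        _, broad, _, _ = simulate_counts(cfg, sim)
        with pytest.warns(UserWarning, match="input"):
            res = de.de_peak_workflow(broad, cfg.sample_meta(), assigned_peaks(sim),
                                      None, contrasts=(("MS", "CTRL"),))
        assert res[("MS", "CTRL")].calls["input_bias_ok"].isna().all()


class TestWindowWorkflow:
    def write_uniform_fragments(self, tmp_path, meta, chrom_size, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        paths = {}
        for s in meta.sample_ids:
            mids = rng.integers(100, chrom_size - 100, n)
            rows = "".join(
                f"chr1\t{m - 73}\t{m + 74}\tf\t30\t.\n" for m in np.sort(mids)
            )
            p = tmp_path / f"{s}.bed"
            p.write_text(rows)
            paths[s] = p
        return paths

    def test_uniform_coverage_nothing_retained(self, tmp_path, meta_4v4):
        paths = self.write_uniform_fragments(tmp_path, meta_4v4, 300_000)
        with pytest.raises(ValueError, match="abundance filter"):
            de.window_workflow(paths, meta_4v4, {"chr1": 300_000})

    def test_planted_domain_merged(self, tmp_path, meta_4v4):
        rng = np.random.default_rng(1)
        chrom_size = 200_000
        paths = {}
        for s in meta_4v4.sample_ids:
            bg = rng.integers(100, chrom_size - 100, 1000)
            dom = rng.integers(50_000, 50_600, 2000)  # 600-bp enriched domain
            mids = np.sort(np.concatenate([bg, dom]))
            p = tmp_path / f"{s}.bed"
            p.write_text("".join(f"chr1\t{m - 73}\t{m + 74}\tf\t30\t.\n" for m in mids))
            paths[s] = p
        res = de.window_workflow(paths, meta_4v4, {"chr1": chrom_size})
        big = res.regions[res.regions["n_windows"] >= 3]
        assert len(big) >= 1
        assert (big["start"] <= 50_600).any() and (big["end"] >= 50_000).any()

    def test_tmm_factors_recover_depth_ratio(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(200, size=(300, 4)).astype(float)
        counts = pd.DataFrame(base, columns=list("abcd"))
        counts["d"] = counts["d"] * 2  # double efficiency
        f = de.size_factors_tmm(counts)
        assert f["d"] / f["a"] == pytest.approx(2.0, rel=0.05)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)
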