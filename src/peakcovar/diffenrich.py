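"""Negative-binomial differential enrichment with promoter and input-bias
post-filters, plus the sliding-window alternative workflow.

The count model is NB with variance mu + alpha * mu^2 and a log link,
design ~ group, fitted per region by iteratively reweighted least squares
(vectorized across regions; the design matrix is shared). Group contrasts
are tested with a Wald z statistic and corrected per contrast by the
Benjamini-Hochberg step-up procedure at 10% FDR by default. Two
post-filters produce the final call list: the region must lie in a promoter
window (±1 kb around an annotated TSS) and must show no substantial input
bias (|log2 ratio of group-mean input coverage| below a cap).

The model surface is statsmodels-style: ``NBEnrichmentModel(counts, meta,
...).fit(contrast=("MS", "CTRL"))`` returns a :class:`DEResults` whose
``table`` holds per-region statistics and whose ``summary()`` prints a
digest.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import EnrichmentMatrix, PeakSet, SampleMeta
from .enrichment import read_fragments, size_factors_median_ratio

DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(k) = min_{j >= k} (m * p_(j) / j) in the original order. NaN entries
    propagate as NaN and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# Dispersion estimation


def estimate_dispersions(
    counts: EnrichmentMatrix,
    meta: SampleMeta,
    size_factors: pd.Series,
    trend_weight: float = 50.0,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-region NB dispersions: method-of-moments, shrunk to a 1/mu trend.

    The raw estimate uses the pooled within-group variance of normalized
    counts, alpha_hat = (s^2 - mu * mean(1/sf)) / mu^2 (the mean(1/sf) term
    accounts for the sampling variance of count/sf). A trend
    alpha_tr(mu) = a0 + a1/mu is fitted by least squares over regions and the
    final estimate is the precision-weighted blend
    (df * alpha_hat + w * alpha_tr) / (df + w), floored at ``floor``.
    """
    sf = size_factors.reindex(counts.values.columns)
    groups = meta.df.loc[counts.values.columns, "group"]
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 samples for dispersion estimation")
    y = counts.values / sf
    n, n_groups = y.shape[1], groups.nunique()
    resid_df = n - n_groups
    ss = np.zeros(len(y))
    for g in groups.unique():
        sub = y.loc[:, groups[groups == g].index]
        ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1).to_numpy()
    s2 = ss / resid_df
    mu = y.mean(axis=1).to_numpy()
    inv_sf_mean = float((1.0 / sf).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mu * inv_sf_mean) / mu**2
    raw = np.where(mu > 0, raw, 0.0)
    raw = np.maximum(raw, floor)

    # trend fit a0 + a1/mu on informative regions
    use = (mu > 0) & np.isfinite(raw)
    trend = np.full(len(raw), floor)
    if use.sum() >= 10:
        x = 1.0 / mu[use]
        design = np.column_stack([np.ones(use.sum()), x])
        coef, *_ = np.linalg.lstsq(design, raw[use], rcond=None)
        coef = np.maximum(coef, 0.0)
        with np.errstate(divide="ignore"):
            trend = np.where(mu > 0, coef[0] + coef[1] / np.maximum(mu, 1e-12), floor)
    shrunk = (resid_df * raw + trend_weight * trend) / (resid_df + trend_weight)
    shrunk = np.maximum(shrunk, floor)
    return pd.Series(shrunk, index=counts.values.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB GLM Wald test (vectorized IRLS over regions; shared 2-column design)


def _irls_two_group(
    y: np.ndarray,
    x: np.ndarray,
    log_sf: np.ndarray,
    alpha: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Fit log mu = b0 + b1*x + log sf for every region (row of y).

    Returns (b0, b1, se1, converged). x is the 0/1 test-group indicator.
    """
    n_regions, n = y.shape
    eps = 1e-8
    ref, tst = x == 0, x == 1
    sf = np.exp(log_sf)
    mean_ref = (y[:, ref] / sf[ref]).mean(axis=1)
    mean_tst = (y[:, tst] / sf[tst]).mean(axis=1)
    b0 = np.log(np.maximum(mean_ref, eps))
    b1 = np.log(np.maximum(mean_tst, eps)) - b0
    alpha = alpha[:, None]
    converged = np.zeros(n_regions, dtype=bool)
    a11 = a12 = a22 = det = None
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta + log_sf[None, :], -30.0, 30.0))
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        a11 = w.sum(axis=1)
        a12 = (w * x).sum(axis=1)
        a22 = a12  # x is binary, x^2 == x
        b1v = (w * z).sum(axis=1)
        b2v = (w * x * z).sum(axis=1)
        det = a11 * a22 - a12**2
        bad = det <= 1e-12
        det_safe = np.where(bad, 1.0, det)
        new_b0 = (a22 * b1v - a12 * b2v) / det_safe
        new_b1 = (a11 * b2v - a12 * b1v) / det_safe
        new_b0 = np.where(bad, b0, np.clip(new_b0, -30.0, 30.0))
        new_b1 = np.where(bad, b1, np.clip(new_b1, -30.0, 30.0))
        step = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        newly = step < tol
        converged |= newly
        if converged.all():
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 1e-12, a11 / det, np.nan))
    at_bound = np.abs(b1) >= 30.0 - 1e-6
    converged &= ~at_bound
    return b0, b1, se1, converged


def nb_wald_test(
    counts: EnrichmentMatrix,
    meta: SampleMeta,
    size_factors: pd.Series,
    dispersions: pd.Series,
    contrast: tuple[str, str] = ("MS", "CTRL"),
) -> pd.DataFrame:
    """Per-region NB Wald test of ``contrast[0]`` versus ``contrast[1]``.

    Returns a table with base_mean, log2fc, se, wald_p, q_value and the
    dispersion used. Regions that are all-zero or fail to converge carry
    NaN p-values and are excluded from the BH correction.
    """
    test_g, ref_g = contrast
    groups = meta.df.loc[counts.values.columns, "group"]
    samples = [s for s in counts.values.columns if groups[s] in (test_g, ref_g)]
    if not any(groups[s] == test_g for s in samples) or not any(
        groups[s] == ref_g for s in samples
    ):
        raise ValueError(f"contrast groups {contrast} not both present")
    y = counts.values[samples].to_numpy(dtype=float)
    x = np.array([1.0 if groups[s] == test_g else 0.0 for s in samples])
    sf = size_factors.reindex(samples).to_numpy(dtype=float)
    alpha = dispersions.reindex(counts.values.index).to_numpy(dtype=float)
    log_sf = np.log(sf)

    testable = y.sum(axis=1) > 0
    b0 = np.full(len(y), np.nan)
    b1 = np.full(len(y), np.nan)
    se1 = np.full(len(y), np.nan)
    conv = np.zeros(len(y), dtype=bool)
    if testable.any():
        b0t, b1t, se1t, convt = _irls_two_group(
            y[testable], x, log_sf, alpha[testable]
        )
        b0[testable], b1[testable], se1[testable], conv[testable] = b0t, b1t, se1t, convt
    n_failed = int(testable.sum() - conv[testable].sum())
    if n_failed:
        warnings.warn(f"{n_failed} regions did not converge; excluded from BH")

    ln2 = np.log(2.0)
    log2fc = b1 / ln2
    se_log2 = se1 / ln2
    with np.errstate(invalid="ignore", divide="ignore"):
        z = b1 / se1
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    wald_p[~conv | ~np.isfinite(se1)] = np.nan
    base_mean = (y / sf).mean(axis=1)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se_log2,
            "wald_p": wald_p,
            "q_value": bh_adjust(wald_p),
            "dispersion": alpha,
            "converged": conv,
        },
        index=counts.values.index,
    )


# ---------------------------------------------------------------------------
# Model / Results surface


@dataclass
class DEResults:
    """Differential-enrichment results for one contrast."""

    table: pd.DataFrame
    contrast: tuple[str, str]
    fdr: float = 0.10
    calls: pd.DataFrame | None = None

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["q_value"] <= self.fdr]

    def summary(self) -> str:
        n = len(self.table)
        tested = int(self.table["wald_p"].notna().sum())
        sig = len(self.significant())
        lines = [
            f"NB differential enrichment: {self.contrast[0]} vs {self.contrast[1]}",
            "=" * 52,
            f"regions               {n}",
            f"tested (converged)    {tested}",
            f"q <= {self.fdr:<4.2g}            {sig}",
        ]
        if self.calls is not None:
            final = self.calls["final"]
            lines.append(f"final calls           {int(final.sum())}")
            if final.any():
                bidir = self.calls.loc[final, "bidirectional"].mean()
                lines.append(f"bidirectional share   {bidir:.1%}")
        return "\n".join(lines)


class NBEnrichmentModel:
    """NB count model for peak-level differential enrichment.

    Parameters
    ----------
    counts : EnrichmentMatrix
        Raw counts, regions x samples.
    meta : SampleMeta
        Sample sheet with group labels.
    size_factors, dispersions : optional
        Estimated with the package defaults when omitted.
    """

    def __init__(
        self,
        counts: EnrichmentMatrix,
        meta: SampleMeta,
        size_factors: pd.Series | None = None,
        dispersions: pd.Series | None = None,
    ):
        self.counts = counts
        self.meta = meta
        self.size_factors = (
            size_factors if size_factors is not None else size_factors_median_ratio(counts)
        )
        self.dispersions = dispersions

    def fit(
        self, contrast: tuple[str, str] = ("MS", "CTRL"), fdr: float = 0.10
    ) -> DEResults:
        disp = self.dispersions
        if disp is None:
            disp = estimate_dispersions(self.counts, self.meta, self.size_factors)
            self.dispersions = disp
        table = nb_wald_test(self.counts, self.meta, self.size_factors, disp, contrast)
        return DEResults(table=table, contrast=contrast, fdr=fdr)


# ---------------------------------------------------------------------------
# Peak workflow with post-filters


def input_bias_flags(
    input_counts: EnrichmentMatrix,
    meta: SampleMeta,
    contrast: tuple[str, str],
    bias_log2_max: float = 1.0,
    min_depth: int = 10,
) -> pd.Series:
    """Per-region flag: no substantial input bias between contrast groups.

    Bias is |log2 ratio of group-mean input coverage| (library-size scaled);
    regions whose total input depth falls below ``min_depth`` cannot be
    assessed and pass by default.
    """
    vals = input_counts.values
    cols = [c for c in vals.columns if meta.df.loc[c, "group"] in contrast]
    vals = vals[cols]
    scaled = vals / vals.sum(axis=0).replace(0, np.nan) * vals.sum(axis=0).mean()
    g = meta.df.loc[cols, "group"]
    mean_test = scaled[[c for c in cols if g[c] == contrast[0]]].mean(axis=1)
    mean_ref = scaled[[c for c in cols if g[c] == contrast[1]]].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bias = np.abs(np.log2((mean_test + 0.5) / (mean_ref + 0.5)))
    shallow = vals.sum(axis=1) < min_depth
    ok = (bias <= bias_log2_max) | shallow
    return pd.Series(ok, index=vals.index, name="input_bias_ok")


def de_peak_workflow(
    counts: EnrichmentMatrix,
    meta: SampleMeta,
    peaks: PeakSet,
    input_counts: EnrichmentMatrix | None = None,
    contrasts: tuple[tuple[str, str], ...] = (("HD", "CTRL"), ("MS", "CTRL")),
    fdr: float = 0.10,
    bias_log2_max: float = 1.0,
    min_input_depth: int = 10,
) -> dict[tuple[str, str], DEResults]:
    """Full peak-level pipeline: NB test per contrast + the two post-filters.

    ``peaks`` must already carry promoter assignments (see
    :func:`peakcovar.genomic_io.assign_peaks`); the final call for a region
    requires q <= fdr, a promoter assignment, and an unbiased input.
    """
    model = NBEnrichmentModel(counts, meta)
    in_promoter = pd.Series(
        {rid: bool(peaks.gene_assignments.get(rid)) for rid in counts.values.index}
    )
    bidirectional = pd.Series(
        {rid: bool(peaks.bidirectional.get(rid, False)) for rid in counts.values.index}
    )
    results: dict[tuple[str, str], DEResults] = {}
    for contrast in contrasts:
        res = model.fit(contrast=contrast, fdr=fdr)
        if input_counts is not None:
            bias_ok = input_bias_flags(
                input_counts, meta, contrast, bias_log2_max, min_input_depth
            ).reindex(counts.values.index)
        else:
            warnings.warn("no input counts provided; input-bias filter skipped")
            bias_ok = pd.Series(pd.NA, index=counts.values.index, dtype="boolean")
        passes_fdr = res.table["q_value"] <= fdr
        final = passes_fdr & in_promoter & bias_ok.fillna(True).astype(bool)
        res.calls = pd.DataFrame(
            {
                "passes_fdr": passes_fdr,
                "in_promoter": in_promoter,
                "input_bias_ok": bias_ok,
                "final": final,
                "bidirectional": bidirectional,
                "genes": [
                    ",".join(peaks.gene_assignments.get(rid, []))
                    for rid in counts.values.index
                ],
            },
            index=counts.values.index,
        )
        results[contrast] = res
    return results


# ---------------------------------------------------------------------------
# Window workflow (csaw-style)


def size_factors_tmm(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-log-ratios normalization factors (geometric mean 1).

    Efficiency-bias normalization for window counts: each sample is compared
    to the geometric-mean reference; the mean log-ratio is taken after
    trimming the extremes of the M (log-ratio) and A (log-abundance)
    distributions.
    """
    arr = counts.to_numpy(dtype=float) + 0.5
    log_ref = np.log2(arr).mean(axis=1)
    factors = []
    for j in range(arr.shape[1]):
        m = np.log2(arr[:, j]) - log_ref
        a = 0.5 * (np.log2(arr[:, j]) + log_ref)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        factors.append(2.0 ** m[keep].mean() if keep.any() else 1.0)
    f = np.asarray(factors)
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="size_factor")


@dataclass
class WindowResult:
    """Window-level testing outcome for one contrast."""

    windows: pd.DataFrame  # retained windows with per-window statistics
    regions: pd.DataFrame  # merged regions with combined p and q
    contrast: tuple[str, str]
    fdr: float

    def significant_regions(self) -> pd.DataFrame:
        return self.regions[self.regions["q_value"] <= self.fdr]


def window_workflow(
    fragment_paths: dict[str, object],
    meta: SampleMeta,
    chrom_sizes: dict[str, int],
    contrast: tuple[str, str] = ("MS", "CTRL"),
    window: int = 150,
    global_fold: float = 5.0,
    fdr: float = 0.10,
    min_mapq: int = 10,
    background_bin: int = 2000,
    dispersion_trend_weight: float = 10.0,
) -> WindowResult:
    """Window-based differential testing without predefined peaks.

    The genome is tiled into non-overlapping ``window``-bp windows; fragment
    midpoints (mapq >= ``min_mapq``) are counted per window. Windows are
    retained when their cross-sample average count is at least
    ``global_fold`` times the global background (median count of
    ``background_bin``-bp bins rescaled to window width). Retained windows
    are normalized with trimmed-mean factors (efficiency bias), tested with
    the NB Wald machinery, merged into regions when adjacent (gap of at most
    one window), and the per-region Simes-combined p-values are BH-corrected.
    """
    win_counts: dict[str, pd.Series] = {}
    bg_counts: dict[str, pd.Series] = {}
    window_index: list[tuple[str, int]] = []
    for chrom, size in sorted(chrom_sizes.items()):
        window_index += [(chrom, w) for w in range(int(np.ceil(size / window)))]
    widx = pd.MultiIndex.from_tuples(window_index, names=["chrom", "win"])
    for sample_id, path in fragment_paths.items():
        frags = read_fragments(path)
        frags = frags[frags["mapq"] >= min_mapq]
        mids = (frags["start"] + frags["end"]) // 2
        per_win = np.zeros(len(widx), dtype=np.int64)
        bg_all = []
        offset = 0
        for chrom, size in sorted(chrom_sizes.items()):
            n_win = int(np.ceil(size / window))
            m = mids[frags["chrom"] == chrom].to_numpy()
            m = m[(m >= 0) & (m < size)]
            per_win[offset : offset + n_win] = np.bincount(m // window, minlength=n_win)
            n_bg = int(np.ceil(size / background_bin))
            bg_all.append(np.bincount(m // background_bin, minlength=n_bg))
            offset += n_win
        win_counts[sample_id] = pd.Series(per_win, index=widx)
        bg_counts[sample_id] = pd.Series(np.concatenate(bg_all))
    counts = pd.DataFrame(win_counts)
    bg = pd.DataFrame(bg_counts)

    # global background abundance at window scale
    bg_window_scale = bg.mean(axis=1) * (window / background_bin)
    background = float(np.median(bg_window_scale))
    ave = counts.mean(axis=1)
    retained = counts[ave >= global_fold * max(background, 1e-9)]
    if retained.empty:
        raise ValueError("no windows pass abundance filter")

    tmm = size_factors_tmm(retained)
    region_ids = [f"{c}:{w * window}-{min((w + 1) * window, chrom_sizes[c])}"
                  for c, w in retained.index]
    win_matrix = EnrichmentMatrix(
        retained.reset_index(drop=True).set_axis(region_ids, axis=0),
        resolution="window",
    )
    meta_sub = SampleMeta(meta.df.loc[list(fragment_paths.keys())])
    # window-level dispersions are heterogeneous (peak-shape noise varies along
    # a peak), so the trend gets less weight here than at peak level
    disp = estimate_dispersions(
        win_matrix, meta_sub, tmm, trend_weight=dispersion_trend_weight
    )
    table = nb_wald_test(win_matrix, meta_sub, tmm, disp, contrast)
    # moderated reference: the plug-in dispersion carries only (n - G) residual
    # df plus the trend's prior weight, so the Wald ratio is t-like, not normal
    groups_here = meta_sub.df.loc[win_matrix.values.columns, "group"]
    resid_df = len([s for s in win_matrix.values.columns if groups_here[s] in contrast]) - 2
    t_df = resid_df + dispersion_trend_weight
    with np.errstate(invalid="ignore", divide="ignore"):
        z = table["log2fc"] / table["se"]
    p_mod = 2.0 * stats.t.sf(np.abs(z), df=t_df)
    p_mod[table["wald_p"].isna()] = np.nan
    table["wald_p"] = p_mod
    table["q_value"] = bh_adjust(p_mod)
    table["chrom"] = [c for c, _ in retained.index]
    table["win"] = [w for _, w in retained.index]

    # merge adjacent retained windows (gap <= 1 window) into regions
    region_rows = []
    tab = table.sort_values(["chrom", "win"])
    cur = None
    for rid, row in tab.iterrows():
        if cur is not None and row["chrom"] == cur["chrom"] and row["win"] - cur["end_win"] <= 2:
            cur["end_win"] = row["win"]
            cur["p_values"].append(row["wald_p"])
            cur["n_windows"] += 1
        else:
            if cur is not None:
                region_rows.append(cur)
            cur = {
                "chrom": row["chrom"],
                "start_win": row["win"],
                "end_win": row["win"],
                "p_values": [row["wald_p"]],
                "n_windows": 1,
            }
    if cur is not None:
        region_rows.append(cur)
    regions = []
    for r in region_rows:
        pvals = np.array([p for p in r["p_values"] if np.isfinite(p)])
        if pvals.size:
            k = pvals.size
            simes = float(np.min(np.sort(pvals) * k / np.arange(1, k + 1)))
        else:
            simes = np.nan
        regions.append(
            {
                "chrom": r["chrom"],
                "start": int(r["start_win"] * window),
                "end": int(min((r["end_win"] + 1) * window, chrom_sizes[r["chrom"]])),
                "n_windows": r["n_windows"],
                "p_value": simes,
            }
        )
    region_df = pd.DataFrame(regions)
    region_df["q_value"] = bh_adjust(region_df["p_value"]) if len(region_df) else []
    return WindowResult(windows=table, regions=region_df, contrast=contrast, fdr=fdr)
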