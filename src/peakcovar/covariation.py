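"""Inter-individual variability and opposing-cluster covariation analysis.

The analysis asks how much promoter histone-mark enrichment varies across
individuals and whether the most variable regions co-vary as two clusters
moving in opposite directions — the signature of a single latent sample
factor loading one cluster positively and the other negatively.

The statistical core is exposed statsmodels-style: build a
:class:`CovariationAnalysis` from an enrichment matrix, call ``fit()`` and
inspect the returned :class:`CovariationResult` (``summary()`` gives a
human-readable digest).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import EnrichmentMatrix, SampleMeta


@dataclass
class VariabilityProfile:
    """Per-region log2 fold-changes over the cross-sample mean enrichment."""

    fc_over_mean: pd.DataFrame
    per_sample_spread: pd.DataFrame
    fraction_within_twofold: pd.Series


def fold_change_over_mean(matrix: EnrichmentMatrix | pd.DataFrame) -> VariabilityProfile:
    """log2 fold-change of each cell over its region's mean across samples.

    Expects linear-scale normalized enrichment (counts / size factor).
    Rows with zero mean are dropped with a warning.
    """
    values = matrix.normalized_linear() if isinstance(matrix, EnrichmentMatrix) else matrix
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    row_mean = values.mean(axis=1)
    zero = row_mean <= 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} regions with zero mean enrichment")
        values = values.loc[~zero]
        row_mean = row_mean.loc[~zero]
    with np.errstate(divide="ignore"):
        fc = np.log2(values.div(row_mean, axis=0))
    spread = pd.DataFrame(
        {
            "median": fc.median(axis=0),
            "iqr": fc.quantile(0.75, axis=0) - fc.quantile(0.25, axis=0),
            "sd": fc.std(axis=0, ddof=1),
        }
    )
    within = ((fc >= -1.0) & (fc <= 1.0)).mean(axis=0)
    return VariabilityProfile(fc, spread, within)


def top_variable(matrix: EnrichmentMatrix | pd.DataFrame, k: int = 1000) -> list[str]:
    """The k regions with the largest cross-sample variance of log2 enrichment.

    Ties are broken deterministically by region_id.
    """
    values = matrix.values if isinstance(matrix, EnrichmentMatrix) else matrix
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(values):
        raise ValueError(f"k={k} exceeds number of regions ({len(values)})")
    var = values.var(axis=1, ddof=1)
    order = sorted(values.index, key=lambda rid: (-var[rid], rid))
    return order[:k]


@dataclass
class CorrelationResult:
    """Pairwise region-region correlations with two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_samples: int


def correlation_with_p(
    matrix: EnrichmentMatrix | pd.DataFrame,
    subset: list[str] | None = None,
    method: str = "pearson",
) -> CorrelationResult:
    """Pairwise correlations of region profiles across samples, with p-values.

    p is two-sided from t = r * sqrt((n-2) / (1-r^2)) on n-2 df. Regions with
    zero variance get NaN correlations (their pairs are excluded downstream).
    """
    values = matrix.values if isinstance(matrix, EnrichmentMatrix) else matrix
    if subset is not None:
        values = values.loc[subset]
    n = values.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples for correlation p-values")
    arr = values.to_numpy(dtype=float)
    if method == "spearman":
        arr = np.apply_along_axis(stats.rankdata, 1, arr)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    rc = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rc * np.sqrt((n - 2) / (1.0 - rc**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rc), 1.0), 0.0, p)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    p[np.isnan(r)] = np.nan
    idx = values.index
    return CorrelationResult(
        pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx), n
    )


@dataclass
class CovariationResult:
    """Extracted opposing-cluster structure plus PCA variance shares."""

    selected_ids: list[str]
    cluster_label: dict[str, str]
    partner: dict[str, str]
    pc_variance_full: np.ndarray = field(default_factory=lambda: np.array([]))
    pc_variance_subset: np.ndarray = field(default_factory=lambda: np.array([]))
    factor_association: dict[str, float] = field(default_factory=dict)

    @property
    def cluster_a(self) -> list[str]:
        return [r for r in self.selected_ids if self.cluster_label[r] == "A"]

    @property
    def cluster_b(self) -> list[str]:
        return [r for r in self.selected_ids if self.cluster_label[r] == "B"]

    def summary(self) -> str:
        lines = [
            "Opposing-cluster covariation analysis",
            "=" * 44,
            f"selected regions          {len(self.selected_ids)}",
            f"cluster A / cluster B     {len(self.cluster_a)} / {len(self.cluster_b)}",
        ]
        if self.pc_variance_full.size:
            lines.append(f"PC1 share, full set       {self.pc_variance_full[0]:.1%}")
        if self.pc_variance_subset.size:
            lines.append(f"PC1 share, subset         {self.pc_variance_subset[0]:.1%}")
        for k, v in self.factor_association.items():
            lines.append(f"PC1 vs {k:<18} p = {v:.3g}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": [self.cluster_label[r] for r in self.selected_ids],
                "partner": [self.partner.get(r, "") for r in self.selected_ids],
            },
            index=pd.Index(self.selected_ids, name="region_id"),
        )


def extract_opposing_subset(
    cor: CorrelationResult,
    r_pos: float = 0.8,
    r_neg: float = 0.8,
    alpha: float = 0.01,
    max_passes: int = 100,
) -> CovariationResult:
    """Grow two anti-correlated clusters from the strongest negative pair.

    Seeded bipartite growth: start from the most negative significant pair
    (one region per cluster); iteratively admit regions with a significant
    correlation >= r_pos to a member of one cluster AND <= -r_neg to a member
    of the other, assigning to the positively matching side; iterate to a
    fixpoint; then prune members that lose either link, again to a fixpoint.
    Deterministic given the tie-break (strongest positive link, then id).
    """
    r, p = cor.r, cor.p
    ids = list(r.index)
    rv = r.to_numpy(dtype=float)
    pv = p.to_numpy(dtype=float)
    sig = pv <= alpha
    pos_link = sig & (rv >= r_pos)
    neg_link = sig & (rv <= -r_neg)
    np.fill_diagonal(pos_link, False)
    np.fill_diagonal(neg_link, False)

    neg_vals = np.where(neg_link, rv, np.inf)
    if not np.isfinite(neg_vals).any():
        warnings.warn("no significant negative pair; empty covariation subset")
        return CovariationResult([], {}, {})
    i, j = np.unravel_index(np.argmin(neg_vals), neg_vals.shape)
    if ids[i] > ids[j]:
        i, j = j, i
    label = np.zeros(len(ids), dtype=int)  # 0 unassigned, 1 = A, 2 = B
    label[i], label[j] = 1, 2

    for _ in range(max_passes):
        changed = False
        for k in np.argsort(ids):
            if label[k]:
                continue
            in_a, in_b = label == 1, label == 2
            pos_a = pos_link[k] & in_a
            pos_b = pos_link[k] & in_b
            neg_a = neg_link[k] & in_a
            neg_b = neg_link[k] & in_b
            can_a = pos_a.any() and neg_b.any()
            can_b = pos_b.any() and neg_a.any()
            if can_a and can_b:
                # join the side with the stronger positive link
                choice = 1 if rv[k][pos_a].max() >= rv[k][pos_b].max() else 2
            elif can_a:
                choice = 1
            elif can_b:
                choice = 2
            else:
                continue
            label[k] = choice
            changed = True
        if not changed:
            break
    else:
        raise RuntimeError("opposing-subset growth did not converge")

    # prune to the membership invariant: each member needs a surviving positive
    # link within its cluster and a negative link into the other
    for _ in range(max_passes):
        in_a, in_b = label == 1, label == 2
        drop = np.zeros(len(ids), dtype=bool)
        for k in np.flatnonzero(label):
            own = in_a if label[k] == 1 else in_b
            other = in_b if label[k] == 1 else in_a
            own = own.copy()
            own[k] = False
            if not ((pos_link[k] & own).any() and (neg_link[k] & other).any()):
                drop[k] = True
        if not drop.any():
            break
        label[drop] = 0
    if (label == 1).sum() == 0 or (label == 2).sum() == 0:
        return CovariationResult([], {}, {})

    selected = [ids[k] for k in np.flatnonzero(label)]
    selected.sort()
    cluster = {ids[k]: ("A" if label[k] == 1 else "B") for k in np.flatnonzero(label)}
    partner = {}
    for rid in selected:
        k = ids.index(rid)
        row = np.where(np.isnan(rv[k]), np.inf, rv[k].copy())
        row[k] = np.inf
        partner[rid] = ids[int(np.argmin(row))]
    return CovariationResult(selected, cluster, partner)


def pca_variance(
    matrix: EnrichmentMatrix | pd.DataFrame,
    subset: list[str] | None = None,
    meta: SampleMeta | None = None,
):
    """Sample-space PCA of row-centered log2 enrichment.

    Returns ``(fractions, scores, associations)``: the per-component variance
    fractions, PC1 sample scores, and p-values for PC1 against experimental
    group (one-way ANOVA), litter (one-way ANOVA) and library enrichment
    (Pearson correlation test), when metadata is available.
    """
    values = matrix.values if isinstance(matrix, EnrichmentMatrix) else matrix
    if subset is not None:
        values = values.loc[subset]
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    fractions = var / var.sum() if var.sum() > 0 else var
    scores = pd.Series(vt[0] * s[0], index=values.columns, name="PC1")
    associations: dict[str, float] = {}
    if meta is not None:
        mdf = meta.df.loc[values.columns]
        by_group = [scores[mdf["group"] == g] for g in mdf["group"].unique()]
        if len(by_group) >= 2 and all(len(g) >= 2 for g in by_group):
            associations["group"] = float(stats.f_oneway(*by_group).pvalue)
        if "litter" in mdf.columns:
            by_litter = [scores[mdf["litter"] == l] for l in mdf["litter"].unique()]
            if len(by_litter) >= 2 and all(len(g) >= 2 for g in by_litter):
                associations["litter"] = float(stats.f_oneway(*by_litter).pvalue)
        if "library_total" in mdf.columns and mdf["library_total"].notna().all():
            associations["library_total"] = float(
                stats.pearsonr(scores, mdf["library_total"]).pvalue
            )
    return fractions, scores, associations


class CovariationAnalysis:
    """Model object tying the variability workflow together.

    Parameters
    ----------
    matrix : EnrichmentMatrix
        Normalized log2 enrichment (broad resolution).
    meta : SampleMeta, optional
        Sample sheet for factor-association tests.
    """

    def __init__(self, matrix: EnrichmentMatrix, meta: SampleMeta | None = None):
        self.matrix = matrix
        self.meta = meta

    def fit(
        self,
        top_k: int = 1000,
        r_pos: float = 0.8,
        r_neg: float = 0.8,
        alpha: float = 0.01,
        method: str = "pearson",
    ) -> CovariationResult:
        k = min(top_k, len(self.matrix.values))
        subset = top_variable(self.matrix, k=k)
        cor = correlation_with_p(self.matrix, subset, method=method)
        result = extract_opposing_subset(cor, r_pos=r_pos, r_neg=r_neg, alpha=alpha)
        result.pc_variance_full, _, result.factor_association = pca_variance(
            self.matrix, meta=self.meta
        )
        if result.selected_ids:
            result.pc_variance_subset, _, _ = pca_variance(
                self.matrix, subset=result.selected_ids
            )
        return result


def export_heatmap_matrix(
    matrix: EnrichmentMatrix, result: CovariationResult, path
) -> pd.DataFrame:
    """Cluster-sorted enrichment matrix (left panel) next to each region's
    highest anti-correlated partner profile (right panel), TSV export."""
    order = result.cluster_a + result.cluster_b
    left = matrix.values.loc[order]
    right = matrix.values.loc[[result.partner[r] for r in order]]
    right.index = [f"partner_of_{r}" for r in order]
    out = pd.concat([left, right])
    out.rename_axis("region_id").to_csv(path, sep="\t")
    return out
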