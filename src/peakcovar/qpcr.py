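"""qPCR layers: ChIP fold-enrichment QC and relative expression (ddCt).

Fold enrichment gates ChIP samples before sequencing:
FE = 2^(Ct_input - Ct_IP) at a positive-control locus divided by the same
quantity at a negative-control locus; only samples with FE above a threshold
(default 25) pass. Relative expression uses the ddCt method against the mean
Ct of housekeeping genes whose stability must satisfy geNorm M < 0.5 and
CV < 0.25; group comparisons use one-way ANOVA with Fisher's LSD post hoc.
Amplification efficiency is fixed at 2 (the ddCt assumption).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SampleMeta

_CT_COLS = ["sample_id", "target", "fraction", "replicate", "ct"]
FRACTIONS = ("IP", "input", "cDNA")


def read_ct_table(path) -> pd.DataFrame:
    """Long-format Ct table TSV: sample_id, target, fraction, replicate, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "target": str})
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(_CT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    unknown = set(df["fraction"]) - set(FRACTIONS)
    if unknown:
        raise ValueError(f"unknown fractions: {sorted(unknown)}")
    return df[_CT_COLS].copy()


def _mean_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates: one Ct per (sample, target, fraction)."""
    return ct.groupby(["sample_id", "target", "fraction"], as_index=False)["ct"].mean()


def fold_enrichment(
    ct: pd.DataFrame, pos_locus: str, neg_locus: str, gate: float = 25.0
) -> pd.DataFrame:
    """Per-sample ChIP fold enrichment with pass/fail gate.

    FE = 2^(dCt_pos) / 2^(dCt_neg), dCt = Ct_input - Ct_IP, replicates
    averaged first.
    """
    ct = validate_ct_table(ct)
    mean = _mean_ct(ct)
    rows = []
    for sample_id, sub in mean.groupby("sample_id"):
        vals = {}
        for locus, frac in itertools.product((pos_locus, neg_locus), ("IP", "input")):
            sel = sub[(sub["target"] == locus) & (sub["fraction"] == frac)]
            if sel.empty:
                raise ValueError(f"sample {sample_id!r}: missing {frac} Ct for {locus!r}")
            vals[(locus, frac)] = float(sel["ct"].iloc[0])
        dct_pos = vals[(pos_locus, "input")] - vals[(pos_locus, "IP")]
        dct_neg = vals[(neg_locus, "input")] - vals[(neg_locus, "IP")]
        fe = 2.0**dct_pos / 2.0**dct_neg
        rows.append({"sample_id": sample_id, "fe": fe, "passes": fe > gate})
    return pd.DataFrame(rows).set_index("sample_id")


def genorm_stability(ct: pd.DataFrame, candidates: list[str]) -> tuple[pd.Series, float]:
    """geNorm stability M per candidate gene and the CV of the normalization factor.

    M_j is the mean over other candidates k of the standard deviation across
    samples of log2(q_j / q_k), with relative quantities q = 2^-Ct. The CV is
    the coefficient of variation of the per-sample normalization factor (the
    geometric mean of candidate quantities).
    """
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate genes")
    ct = validate_ct_table(ct)
    mean = _mean_ct(ct[ct["fraction"] == "cDNA"])
    wide = mean.pivot_table(index="sample_id", columns="target", values="ct")
    missing = [g for g in candidates if g not in wide.columns]
    if missing:
        raise ValueError(f"candidates absent from Ct table: {missing}")
    wide = wide[candidates].dropna()
    if len(wide) < 3:
        raise ValueError("need >= 3 samples with complete candidate Cts")
    log_q = -wide  # log2 of q = 2^-Ct
    m_values = {}
    for gj in candidates:
        sds = [
            float((log_q[gj] - log_q[gk]).std(ddof=1)) for gk in candidates if gk != gj
        ]
        m_values[gj] = float(np.mean(sds))
    norm_factor = 2.0 ** log_q.mean(axis=1)
    cv = float(norm_factor.std(ddof=1) / norm_factor.mean())
    return pd.Series(m_values, name="M"), cv


def ddct_expression(
    ct: pd.DataFrame,
    targets: list[str],
    housekeepers: list[str],
    meta: SampleMeta,
    reference_group: str = "CTRL",
    m_max: float = 0.5,
    cv_max: float = 0.25,
) -> pd.DataFrame:
    """Relative expression by the ddCt method, normalized to housekeeping genes.

    dCt = Ct_target - mean(Ct_housekeepers) per sample; ddCt subtracts the
    reference-group mean dCt; rel_expr = 2^-ddCt. Housekeeper stability is
    checked against the geNorm gates (M < m_max, CV < cv_max); failure is a
    warning plus a qc flag, not an error.
    """
    ct = validate_ct_table(ct)
    m_vals, cv = genorm_stability(ct, housekeepers)
    qc_pass = bool((m_vals < m_max).all() and cv < cv_max)
    if not qc_pass:
        warnings.warn(
            f"housekeepers fail stability gates (M={m_vals.to_dict()}, CV={cv:.3f})"
        )
    mean = _mean_ct(ct[ct["fraction"] == "cDNA"])
    wide = mean.pivot_table(index="sample_id", columns="target", values="ct")
    ref_samples = [s for s in meta.samples_in(reference_group) if s in wide.index]
    if not ref_samples:
        raise ValueError(f"reference group {reference_group!r} empty")
    hk_mean = wide[housekeepers].mean(axis=1)
    rows = []
    for gene in targets:
        dct = wide[gene] - hk_mean
        ddct = dct - dct.loc[ref_samples].mean()
        rel = 2.0**-ddct
        for sample_id in wide.index:
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene": gene,
                    "group": meta.group_of(sample_id),
                    "ddct": float(ddct.loc[sample_id]),
                    "rel_expr": float(rel.loc[sample_id]),
                    "qc_pass": qc_pass,
                }
            )
    return pd.DataFrame(rows)


def group_fold_changes(
    expr: pd.DataFrame, reference_group: str = "CTRL"
) -> pd.DataFrame:
    """Geometric-mean fold change of each group versus the reference."""
    rows = []
    for gene, sub in expr.groupby("gene"):
        ref = sub[sub["group"] == reference_group]["rel_expr"]
        ref_geo = float(np.exp(np.mean(np.log(ref))))
        for group, gsub in sub.groupby("group"):
            geo = float(np.exp(np.mean(np.log(gsub["rel_expr"]))))
            rows.append({"gene": gene, "group": group, "fold_change": geo / ref_geo})
    return pd.DataFrame(rows)


def group_stats(
    values: pd.Series, meta: SampleMeta, log_transform: bool = False
) -> dict:
    """One-way ANOVA across groups plus Fisher's LSD pairwise comparisons.

    ``values`` is indexed by sample_id. LSD uses the pooled MSE from the
    ANOVA with N - G degrees of freedom; with two groups F equals t^2 and the
    LSD p equals the pooled-variance t-test p.
    """
    groups = meta.df.loc[values.index, "group"]
    labels = list(groups.unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    by_group = {g: values[groups == g].to_numpy(dtype=float) for g in labels}
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("every group needs >= 2 samples")
    if log_transform:
        by_group = {g: np.log(v) for g, v in by_group.items()}
    f_stat, p = stats.f_oneway(*by_group.values())
    n_total = sum(len(v) for v in by_group.values())
    df_err = n_total - len(labels)
    mse = sum(((v - v.mean()) ** 2).sum() for v in by_group.values()) / df_err
    pairwise = {}
    for g1, g2 in itertools.combinations(labels, 2):
        v1, v2 = by_group[g1], by_group[g2]
        se = np.sqrt(mse * (1.0 / len(v1) + 1.0 / len(v2)))
        t = (v1.mean() - v2.mean()) / se
        pairwise[(g1, g2)] = float(2.0 * stats.t.sf(abs(t), df=df_err))
    return {"F": float(f_stat), "p": float(p), "df": (len(labels) - 1, df_err), "lsd": pairwise}
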