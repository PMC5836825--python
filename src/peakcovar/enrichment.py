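"""Peak-by-sample count matrices, normalization, and TSS metaprofiles.

Fragments are assigned to a region when their midpoint falls inside it
(half-open); this avoids double counting across adjacent nucleosome-sized
subpeaks. Mapping quality is carried in the BED score column and fragments
below ``min_mapq`` (default 10) are discarded before counting.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import EnrichmentMatrix, PeakSet, SampleMeta, TssRecord


def read_fragments(path) -> pd.DataFrame:
    """Per-sample fragment BED6: chrom, start, end, name, mapq (score), strand."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 4],
        names=["chrom", "start", "end", "mapq"],
        dtype={0: str, 1: np.int64, 2: np.int64, 4: np.int64},
        comment="#",
    )
    if (df["mapq"] < 0).any():
        raise ValueError(f"{path}: negative mapping quality")
    return df


def _regions_disjoint_sorted(df: pd.DataFrame) -> bool:
    for _, sub in df.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            return False
    return True


def _count_midpoints(mids: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Count fragment midpoints per region; regions may overlap."""
    counts = np.zeros(len(regions), dtype=np.int64)
    region_pos = {rid: i for i, rid in enumerate(regions.index)}
    if _regions_disjoint_sorted(regions):
        for chrom, sub in regions.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            m = mids.loc[mids["chrom"] == chrom, "mid"].to_numpy()
            if m.size == 0:
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            idx = np.searchsorted(starts, m, side="right") - 1
            ok = (idx >= 0) & (m < ends[np.clip(idx, 0, len(ends) - 1)])
            hit_idx, hit_n = np.unique(idx[ok], return_counts=True)
            rows = [region_pos[sub.index[i]] for i in hit_idx]
            counts[rows] += hit_n
    else:
        trees: dict[str, IntervalTree] = {}
        for rid, row in regions.iterrows():
            trees.setdefault(row["chrom"], IntervalTree()).addi(
                row["start"], row["end"], region_pos[rid]
            )
        for chrom, sub in mids.groupby("chrom", sort=False):
            tree = trees.get(chrom)
            if tree is None:
                continue
            for m in sub["mid"].to_numpy():
                for iv in tree.overlap(m, m + 1):
                    counts[iv.data] += 1
    return counts


def count_fragments(
    fragment_paths: dict[str, object], regions: PeakSet, min_mapq: int = 10
) -> EnrichmentMatrix:
    """Count MAPQ-filtered fragment midpoints of each sample at each region."""
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    if len(regions) == 0:
        raise ValueError("empty region set")
    mat = {}
    rdf = regions.df
    for sample_id, path in fragment_paths.items():
        frags = read_fragments(path)
        frags = frags[frags["mapq"] >= min_mapq]
        mids = pd.DataFrame(
            {"chrom": frags["chrom"], "mid": (frags["start"] + frags["end"]) // 2}
        )
        mat[sample_id] = _count_midpoints(mids, rdf)
    values = pd.DataFrame(mat, index=rdf.index)
    return EnrichmentMatrix(values, resolution=regions.resolution)


def size_factors_median_ratio(counts: EnrichmentMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_s = median over all-positive regions of count(i,s) / geomean_i(count),
    the normalization used for both the variability and the differential layers.
    """
    values = counts.values if isinstance(counts, EnrichmentMatrix) else counts
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    arr = values.to_numpy(dtype=float)
    pos = (arr > 0).all(axis=1)
    if not pos.any():
        raise ValueError(
            "no region with all-positive counts; consider a pseudo-reference fallback"
        )
    sub = arr[pos]
    geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    factors = np.median(sub / geo, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=values.columns, name="size_factor")


def normalize_log2(
    counts: EnrichmentMatrix, size_factors: pd.Series, pseudocount: float = 1.0
) -> EnrichmentMatrix:
    """log2(count / size_factor + pseudocount) per cell."""
    sf = size_factors.reindex(counts.values.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    values = np.log2(counts.values / sf + pseudocount)
    return EnrichmentMatrix(
        values, resolution=counts.resolution, normalized=True, size_factors=sf
    )


def aggregate_to_broad(
    nucleosome: EnrichmentMatrix, parent_map: dict[str, str]
) -> EnrichmentMatrix:
    """Sum constituent subpeak counts into their parent broad peaks."""
    orphans = [rid for rid in nucleosome.values.index if rid not in parent_map]
    if orphans:
        raise ValueError(f"subpeaks without parent: {orphans[:5]}")
    parents = pd.Series({rid: parent_map[rid] for rid in nucleosome.values.index})
    agg = nucleosome.values.groupby(parents).sum()
    # preserve first-appearance order of parents
    order = parents.drop_duplicates().to_numpy()
    agg = agg.loc[order]
    return EnrichmentMatrix(agg, resolution="broad")


def tss_metaprofile(
    fragment_paths: dict[str, object],
    tss: list[TssRecord],
    meta: SampleMeta,
    half_window: int = 2000,
    bin_size: int = 50,
    min_mapq: int = 10,
) -> pd.DataFrame:
    """Strand-oriented fragment density around TSSs, pooled within groups.

    Each sample's bin counts are normalized by that sample's total fragments
    within ±half_window of any TSS, then averaged within experimental groups.
    Returns a DataFrame indexed by bin-center offset with one column per group.
    """
    if (2 * half_window) % bin_size != 0:
        raise ValueError("bin_size must divide 2 * half_window")
    n_bins = 2 * half_window // bin_size
    tss_by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t)
    chrom_pos = {
        c: np.array(sorted(t.tss for t in recs)) for c, recs in tss_by_chrom.items()
    }
    chrom_strand = {}
    for c, recs in tss_by_chrom.items():
        recs_sorted = sorted(recs, key=lambda r: r.tss)
        chrom_strand[c] = np.array([1 if r.strand == "+" else -1 for r in recs_sorted])

    per_sample = {}
    for sample_id, path in fragment_paths.items():
        frags = read_fragments(path)
        frags = frags[frags["mapq"] >= min_mapq]
        hist = np.zeros(n_bins, dtype=float)
        for chrom, sub in frags.groupby("chrom", sort=False):
            pos = chrom_pos.get(chrom)
            if pos is None or pos.size == 0:
                continue
            mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
            nearest = np.clip(np.searchsorted(pos, mids), 0, pos.size - 1)
            left = np.clip(nearest - 1, 0, pos.size - 1)
            pick = np.where(
                np.abs(pos[nearest] - mids) <= np.abs(pos[left] - mids), nearest, left
            )
            dist = (mids - pos[pick]) * chrom_strand[chrom][pick]
            dist = dist[(dist >= -half_window) & (dist < half_window)]
            if dist.size:
                hist += np.bincount(
                    ((dist + half_window) // bin_size).astype(int), minlength=n_bins
                )
        total = hist.sum()
        per_sample[sample_id] = hist / total if total > 0 else hist
    centers = np.arange(n_bins) * bin_size - half_window + bin_size // 2
    prof = pd.DataFrame(per_sample, index=centers)
    out = {}
    for group in meta.df["group"].unique():
        members = [s for s in meta.samples_in(group) if s in prof.columns]
        if not members:
            raise ValueError(f"no fragment files for group {group!r}")
        out[group] = prof[members].mean(axis=1)
    return pd.DataFrame(out)
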