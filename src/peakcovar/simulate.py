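"""Synthetic study generator with ground truth.

Emulates the structure of a 12-sample (3 groups x 4) promoter histone-mark
ChIP-seq study on a synthetic chromosome: a gene annotation with a
configurable share of divergent (bidirectional-promoter) gene pairs, broad
promoter peaks composed of nucleosome-sized subpeaks, NB-distributed counts
driven by a single latent sample factor loading two anti-correlated region
clusters, a small set of modestly up-enriched regions in the MS group,
flat input coverage with planted biased loci, per-sample fragment files,
and qPCR Ct tables for fold-enrichment and ddCt analysis.

Every stochastic call derives from the mandatory seed; a fixed seed gives
byte-identical outputs. Ground truth for every planted structure is
returned so each pipeline stage can be scored against it.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EnrichmentMatrix, GenomicInterval, PeakSet, SampleMeta, TssRecord
from .genomic_io import GeneAnnotation

_FRAG_HALF = 73  # nucleosome-protected fragment ~147 bp


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int
    n_genes: int = 10_000
    bidirectional_fraction: float = 0.30
    n_broad_peaks: int = 10_000
    subpeaks_per_broad: tuple[int, int] = (2, 10)
    samples: tuple[tuple[str, int], ...] = (("CTRL", 4), ("HD", 4), ("MS", 4))
    depth: int = 1_000_000
    dispersion: float = 0.05
    factor_sd: float = 0.5
    n_cluster_regions: int = 360
    loading: float = 2.0
    n_de_regions: int = 45
    de_log2fc: float = 0.4
    input_bias_regions: int = 10
    input_bias_log2: float = 2.0
    input_depth: int = 200_000
    low_mapq_fraction: float = 0.0
    background_fraction: float = 0.10
    subpeak_concentration: float = 5.0
    promoter_peak_fraction: float = 0.9
    n_blacklist: int = 5
    ct_noise_sd: float = 0.15
    qpcr_true_fc: dict = field(default_factory=lambda: {"Ddias": 1.43, "Pip4k2a": 1.32})
    qpcr_n: tuple[tuple[str, int], ...] = (("CTRL", 11), ("HD", 10), ("MS", 6))
    qpcr_null_targets: int = 8
    true_fe: float = 32.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not 0.0 <= self.bidirectional_fraction <= 1.0:
            raise ValueError("bidirectional_fraction must be in [0, 1]")
        if not 0.0 <= self.low_mapq_fraction <= 1.0:
            raise ValueError("low_mapq_fraction must be in [0, 1]")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        lo, hi = self.subpeaks_per_broad
        if not (1 <= lo <= hi):
            raise ValueError("invalid subpeaks_per_broad range")
        for name in ("n_broad_peaks", "depth", "input_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0 or self.factor_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    def sample_meta(self) -> SampleMeta:
        rows = []
        litters = ["L1", "L2", "L3"]
        for group, n in self.samples:
            for i in range(n):
                rows.append(
                    {
                        "sample_id": f"{group}_{i + 1}",
                        "group": group,
                        "litter": litters[i % len(litters)],
                    }
                )
        return SampleMeta(pd.DataFrame(rows).set_index("sample_id"))


@dataclass
class GroundTruth:
    """Everything planted by the generator, for scoring pipeline output."""

    cluster_members: dict[str, str]  # region -> A or B
    de_regions: dict[str, float]  # region -> true log2fc (MS vs CTRL)
    biased_input_regions: list[str]
    true_size_factors: pd.Series
    true_sample_factor_scores: pd.Series
    qpcr_true_fc: dict[str, float]
    region_counts_broad: pd.DataFrame | None = None
    region_counts_nucleosome: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "cluster_members": self.cluster_members,
            "de_regions": self.de_regions,
            "biased_input_regions": self.biased_input_regions,
            "true_size_factors": self.true_size_factors.to_dict(),
            "true_sample_factor_scores": self.true_sample_factor_scores.to_dict(),
            "qpcr_true_fc": self.qpcr_true_fc,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class SimulatedAnnotation:
    """Synthetic gene model plus peak architecture and blacklist."""

    annotation: GeneAnnotation
    blacklist: list[GenomicInterval]
    broad_peaks: PeakSet
    subpeaks: PeakSet
    chrom_sizes: dict[str, int]

    def write_gtf(self, path) -> None:
        lines = []
        genes = self.annotation.genes
        for gid in genes.index:
            row = genes.loc[gid]
            attrs = f'gene_id "{gid}"; gene_name "{row.gene_name}";'
            lines.append(
                "\t".join(
                    [
                        row.chrom, "sim", "gene",
                        str(int(row.start) + 1), str(int(row.end)),
                        ".", row.strand, ".", attrs,
                    ]
                )
            )
            for _, ex in self.annotation.exons[
                self.annotation.exons["gene_id"] == gid
            ].iterrows():
                lines.append(
                    "\t".join(
                        [
                            row.chrom, "sim", "exon",
                            str(int(ex.start) + 1), str(int(ex.end)),
                            ".", row.strand, ".", attrs,
                        ]
                    )
                )
        Path(path).write_text("\n".join(lines) + "\n")

    def write_blacklist(self, path) -> None:
        Path(path).write_text(
            "".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in self.blacklist)
        )


def simulate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Lay out genes (with divergent pairs), peaks, subpeaks and a blacklist.

    Genes are placed left to right on one synthetic chromosome with >= 5 kb
    spacing between transcription units. A ``bidirectional_fraction`` of
    genes form divergent pairs with TSS separation <= 1 kb; each such pair
    shares one broad promoter peak. Broad peaks are tiled by adjacent
    nucleosome-sized subpeaks. A few blacklist intervals are planted in
    intergenic gaps.
    """
    rng = np.random.default_rng([config.seed, 1])
    chrom = "chr1"
    # bidirectional_fraction is the share of PROMOTER UNITS that are divergent
    # pairs, so the flagged fraction of promoter peaks matches it directly
    n_units = int(round(config.n_genes / (1.0 + config.bidirectional_fraction)))
    n_pairs = int(round(config.bidirectional_fraction * n_units))
    n_single = max(n_units - n_pairs, 0)
    units = ["pair"] * n_pairs + ["single"] * n_single
    rng.shuffle(units)

    genes: list[tuple[str, str, int, int, str]] = []  # gid, chrom, start, end, strand
    exon_rows = []
    tss_units: list[list[TssRecord]] = []  # promoter units (pair shares one)
    gaps: list[tuple[int, int]] = []
    pos = 10_000
    gidx = 0

    def add_gene(start: int, end: int, strand: str) -> TssRecord:
        nonlocal gidx
        gidx += 1
        gid = f"G{gidx:05d}"
        genes.append((gid, chrom, start, end, strand))
        exon_len = min(300, (end - start) // 3)
        exon_rows.append((chrom, start, start + exon_len, gid))
        exon_rows.append((chrom, end - exon_len, end, gid))
        tss = start if strand == "+" else end - 1
        return TssRecord(gid, gid, tss, strand, chrom)

    for unit in units:
        gap = int(rng.integers(5_000, 8_000))
        gaps.append((pos, pos + gap))
        pos += gap
        if unit == "single":
            length = int(rng.integers(1_000, 3_000))
            strand = "+" if rng.random() < 0.5 else "-"
            rec = add_gene(pos, pos + length, strand)
            tss_units.append([rec])
            pos += length
        else:
            len_a = int(rng.integers(1_000, 3_000))
            len_b = int(rng.integers(1_000, 3_000))
            sep = int(rng.integers(100, 900))
            rec_a = add_gene(pos, pos + len_a, "-")  # TSS at right end
            rec_b = add_gene(pos + len_a + sep, pos + len_a + sep + len_b, "+")
            tss_units.append([rec_a, rec_b])
            pos += len_a + sep + len_b
    genome_size = pos + 20_000

    gene_df = pd.DataFrame(
        [(g[0], g[1], g[2], g[3], g[4], g[0]) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand", "gene_name"],
    ).set_index("gene_id")
    exon_df = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "gene_id"])
    tss_records = sorted(
        (t for unit in tss_units for t in unit), key=lambda r: (r.chrom, r.tss, r.gene_id)
    )
    annotation = GeneAnnotation(genes=gene_df, exons=exon_df, tss=tss_records)

    # broad peaks: mostly centered on promoter units, the rest in intergenic gaps
    n_promoter_peaks = min(
        int(round(config.promoter_peak_fraction * config.n_broad_peaks)), len(tss_units)
    )
    n_decoys = config.n_broad_peaks - n_promoter_peaks
    unit_idx = rng.choice(len(tss_units), size=n_promoter_peaks, replace=False)
    lo, hi = config.subpeaks_per_broad
    peak_rows, sub_rows, parent_map = [], [], {}
    pidx = 0

    def add_broad(center: int, k: int) -> None:
        nonlocal pidx
        pidx += 1
        pid = f"P{pidx:05d}"
        width = k * 150 + int(rng.integers(0, 100))
        start = max(0, center - width // 2)
        end = start + width
        q = 10.0 ** float(-rng.uniform(3, 8))
        peak_rows.append((pid, chrom, start, end, ".", 100.0, q))
        sub_start = start
        for s in range(k):
            sid = f"{pid}_s{s + 1}"
            sub_rows.append((sid, chrom, sub_start, sub_start + 147, ".", 100.0, q))
            parent_map[sid] = pid
            sub_start += 150

    for ui in sorted(unit_idx):
        unit = tss_units[ui]
        center = int(round(np.mean([t.tss for t in unit])))
        add_broad(center, int(rng.integers(lo, hi + 1)))
    decoy_gaps = rng.choice(len(gaps), size=min(n_decoys, len(gaps)), replace=False)
    for gi in sorted(decoy_gaps):
        g0, g1 = gaps[gi]
        add_broad((g0 + g1) // 2 + 1_700, int(rng.integers(lo, hi + 1)))

    broad_df = pd.DataFrame(
        peak_rows, columns=["peak_id", "chrom", "start", "end", "strand", "score", "q_value"]
    ).set_index("peak_id")
    sub_df = pd.DataFrame(
        sub_rows, columns=["peak_id", "chrom", "start", "end", "strand", "score", "q_value"]
    ).set_index("peak_id")
    broad_peaks = PeakSet(broad_df, resolution="broad")
    subpeaks = PeakSet(sub_df, resolution="nucleosome", subpeak_parent=parent_map)

    # blacklist in untouched intergenic gaps
    blacklist = []
    used = set(decoy_gaps)
    free = [i for i in range(len(gaps)) if i not in used]
    for gi in rng.choice(free, size=min(config.n_blacklist, len(free)), replace=False):
        g0, _ = gaps[gi]
        blacklist.append(GenomicInterval(chrom, g0 + 100, g0 + 1_100))
    blacklist.sort(key=lambda iv: iv.start)

    return SimulatedAnnotation(
        annotation=annotation,
        blacklist=blacklist,
        broad_peaks=broad_peaks,
        subpeaks=subpeaks,
        chrom_sizes={chrom: genome_size},
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB with variance mu + alpha*mu^2 via gamma-Poisson mixing."""
    if alpha <= 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def simulate_counts(
    config: SimulationConfig, sim: SimulatedAnnotation
) -> tuple[EnrichmentMatrix, EnrichmentMatrix, EnrichmentMatrix, GroundTruth]:
    """Draw (nucleosome, broad, input) count matrices plus ground truth.

    Broad-peak means follow log2 mu_is = b_i + lambda_i f_s + delta_i [s in MS]
    + log2 c_s with f_s ~ N(0, factor_sd), lambda_i = +loading on cluster A,
    -loading on cluster B, delta_i = de_log2fc on DE regions; counts are NB
    with the configured dispersion. Subpeak counts split each broad count by
    a Dirichlet-multinomial (sample-specific shape noise at fixed totals).
    Input coverage is flat per base except at the planted biased regions,
    where the MS-group input is multiplied by 2^input_bias_log2.
    """
    rng = np.random.default_rng([config.seed, 2])
    meta = config.sample_meta()
    samples = meta.sample_ids
    n_s = len(samples)
    broad = sim.broad_peaks
    region_ids = broad.ids
    n_r = len(region_ids)

    # planted structure: cluster and DE region sets are disjoint
    need = 2 * config.n_cluster_regions + config.n_de_regions
    if need > n_r:
        raise ValueError("not enough regions for the requested planted structure")
    chosen = rng.choice(n_r, size=need, replace=False)
    cluster_a = [region_ids[i] for i in chosen[: config.n_cluster_regions]]
    cluster_b = [
        region_ids[i]
        for i in chosen[config.n_cluster_regions : 2 * config.n_cluster_regions]
    ]
    de_ids = [region_ids[i] for i in chosen[2 * config.n_cluster_regions :]]

    lam = np.zeros(n_r)
    idx = {rid: i for i, rid in enumerate(region_ids)}
    for rid in cluster_a:
        lam[idx[rid]] = config.loading
    for rid in cluster_b:
        lam[idx[rid]] = -config.loading
    delta = np.zeros(n_r)
    for rid in de_ids:
        delta[idx[rid]] = config.de_log2fc

    b = rng.normal(0.0, 1.0, size=n_r)
    rel = 2.0**b
    rel /= rel.sum()
    f = rng.normal(0.0, config.factor_sd, size=n_s)
    log_c = rng.normal(0.0, 0.15, size=n_s)
    log_c -= log_c.mean()  # geometric mean 1
    c = 2.0**log_c
    is_ms = np.array([meta.group_of(s) == "MS" for s in samples], dtype=float)

    log2_mu = (
        np.log2(config.depth * rel)[:, None]
        + lam[:, None] * f[None, :]
        + delta[:, None] * is_ms[None, :]
        + np.log2(c)[None, :]
    )
    mu = 2.0**log2_mu
    broad_counts = _nb_draw(rng, mu, config.dispersion).astype(np.int64)
    broad_mat = EnrichmentMatrix(
        pd.DataFrame(broad_counts, index=region_ids, columns=samples), resolution="broad"
    )

    # Dirichlet-multinomial subpeak split: fixed base proportions per region,
    # sample-specific Dirichlet draw drives shape variability at fixed totals
    parent_map = sim.subpeaks.subpeak_parent
    children: dict[str, list[str]] = {}
    for sid in sim.subpeaks.ids:
        children.setdefault(parent_map[sid], []).append(sid)
    sub_ids, sub_counts = [], []
    for rid in region_ids:
        kids = children[rid]
        k = len(kids)
        base = rng.dirichlet(np.full(k, 5.0))
        shape = config.subpeak_concentration * k * base
        row_counts = np.zeros((k, n_s), dtype=np.int64)
        for j in range(n_s):
            w = rng.dirichlet(shape)
            row_counts[:, j] = rng.multinomial(broad_counts[idx[rid], j], w)
        sub_ids.extend(kids)
        sub_counts.append(row_counts)
    nuc_mat = EnrichmentMatrix(
        pd.DataFrame(np.vstack(sub_counts), index=sub_ids, columns=samples),
        resolution="nucleosome",
    )

    # input coverage: flat per base, biased loci inflated in the MS group
    biased = [region_ids[i] for i in rng.choice(n_r, size=config.input_bias_regions, replace=False)]
    lengths = (broad.df["end"] - broad.df["start"]).to_numpy(dtype=float)
    input_rel = lengths / lengths.sum()
    input_mu = np.tile((config.input_depth * input_rel)[:, None], (1, n_s))
    for rid in biased:
        input_mu[idx[rid], is_ms.astype(bool)] *= 2.0**config.input_bias_log2
    input_counts = rng.poisson(input_mu).astype(np.int64)
    input_mat = EnrichmentMatrix(
        pd.DataFrame(input_counts, index=region_ids, columns=samples), resolution="broad"
    )

    truth = GroundTruth(
        cluster_members={**{r: "A" for r in cluster_a}, **{r: "B" for r in cluster_b}},
        de_regions={r: config.de_log2fc for r in de_ids},
        biased_input_regions=sorted(biased),
        true_size_factors=pd.Series(c, index=samples, name="size_factor"),
        true_sample_factor_scores=pd.Series(f, index=samples, name="factor"),
        qpcr_true_fc=dict(config.qpcr_true_fc),
        region_counts_broad=broad_mat.values,
        region_counts_nucleosome=nuc_mat.values,
    )
    return nuc_mat, broad_mat, input_mat, truth


def _merged_intervals(peak_sets: list[PeakSet], chrom: str) -> tuple[np.ndarray, np.ndarray]:
    spans = []
    for ps in peak_sets:
        sub = ps.df[ps.df["chrom"] == chrom]
        spans.append(sub[["start", "end"]].to_numpy())
    arr = np.vstack(spans)
    arr = arr[np.argsort(arr[:, 0])]
    merged = []
    for s, e in arr:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    m = np.asarray(merged)
    return m[:, 0], m[:, 1]


def simulate_fragments(
    counts: EnrichmentMatrix,
    regions: PeakSet,
    config: SimulationConfig,
    outdir,
    chrom_sizes: dict[str, int] | None = None,
    exclude: list[PeakSet] | None = None,
) -> dict[str, Path]:
    """Write per-sample BED6 fragment files realizing the planted counts.

    Each region/sample cell emits exactly its count of ~147-bp fragments with
    midpoints uniform inside the region; a ``low_mapq_fraction`` of fragments
    receives mapq < 10 (and is lost to MAPQ-filtered counting), the rest
    mapq in [10, 42]. When ``chrom_sizes`` is given and ``background_fraction``
    is positive, unbound background fragments are scattered uniformly over the
    genome OUTSIDE the ``exclude`` peak sets (default: the counting regions),
    so region counts remain exactly recoverable.
    """
    rng = np.random.default_rng([config.seed, 3])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rdf = regions.df
    starts = rdf["start"].to_numpy()
    ends = rdf["end"].to_numpy()
    chroms = rdf["chrom"].to_numpy()
    exclude_sets = exclude if exclude is not None else [regions]
    paths: dict[str, Path] = {}
    for sample_id in counts.values.columns:
        col = counts.values[sample_id].to_numpy()
        total = int(col.sum())
        region_of = np.repeat(np.arange(len(rdf)), col)
        u = rng.random(total)
        mids = (starts[region_of] + u * (ends[region_of] - starts[region_of])).astype(np.int64)
        mid_chroms = chroms[region_of]
        if chrom_sizes is not None and config.background_fraction > 0:
            n_bg = int(round(config.background_fraction * total))
            bg_mids, bg_chroms = [], []
            for chrom, size in sorted(chrom_sizes.items()):
                n_c = n_bg  # single-chromosome genomes in practice
                ex_s, ex_e = _merged_intervals(exclude_sets, chrom)
                got = np.empty(0, dtype=np.int64)
                while got.size < n_c:
                    cand = rng.integers(0, size, size=2 * n_c)
                    idx = np.searchsorted(ex_s, cand, side="right") - 1
                    inside = (idx >= 0) & (cand < ex_e[np.clip(idx, 0, len(ex_e) - 1)])
                    got = np.concatenate([got, cand[~inside]])
                got = got[:n_c]
                bg_mids.append(got)
                bg_chroms.append(np.full(n_c, chrom, dtype=object))
            mids = np.concatenate([mids, *bg_mids])
            mid_chroms = np.concatenate([mid_chroms, *bg_chroms])
            total = mids.size
        low = rng.random(total) < config.low_mapq_fraction
        mapq = np.where(
            low, rng.integers(0, 10, size=total), rng.integers(10, 43, size=total)
        )
        frag_start = np.maximum(mids - _FRAG_HALF, 0)
        frag_end = mids + _FRAG_HALF + 1
        df = pd.DataFrame(
            {
                "chrom": mid_chroms,
                "start": frag_start,
                "end": frag_end,
                "name": [f"frag_{i}" for i in range(total)],
                "mapq": mapq,
                "strand": ".",
            }
        ).sort_values(["chrom", "start"], kind="mergesort")
        path = outdir / f"{sample_id}.fragments.bed"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths[sample_id] = path
    return paths


def simulate_qpcr(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, SampleMeta, pd.DataFrame]:
    """Ct tables for the expression (ddCt) and ChIP-QC (FE) layers.

    Returns ``(ct_expression, qpcr_meta, ct_fe)``. Expression Cts follow
    Ct = baseline - log2(expression) + noise with a per-sample RNA-input
    offset common to all genes (cancelling in dCt), planted fold-changes on
    the MS group, stable housekeepers, and duplicate technical replicates.
    The FE table emits IP/input Ct quartets at the positive/negative control
    loci realizing ``true_fe``.
    """
    rng = np.random.default_rng([config.seed, 4])
    rows_meta = []
    for group, n in config.qpcr_n:
        for i in range(n):
            rows_meta.append({"sample_id": f"q{group}_{i + 1}", "group": group})
    qmeta = SampleMeta(pd.DataFrame(rows_meta).set_index("sample_id"))

    targets = list(truth.qpcr_true_fc) + [
        f"Null{i + 1}" for i in range(config.qpcr_null_targets)
    ]
    housekeepers = ["Hprt1", "Rpl16s"]
    baselines = {g: 22.0 + 2.0 * i for i, g in enumerate(targets)}
    baselines.update({"Hprt1": 19.0, "Rpl16s": 17.0})

    ct_rows = []
    for sid in qmeta.sample_ids:
        group = qmeta.group_of(sid)
        offset = rng.normal(0.0, 0.2)
        for gene in targets + housekeepers:
            log2_expr = 0.0
            if gene in truth.qpcr_true_fc and group == "MS":
                log2_expr = np.log2(truth.qpcr_true_fc[gene])
            base_ct = baselines[gene] + offset - log2_expr
            for rep in (1, 2):
                ct_rows.append(
                    {
                        "sample_id": sid,
                        "target": gene,
                        "fraction": "cDNA",
                        "replicate": rep,
                        "ct": base_ct + rng.normal(0.0, config.ct_noise_sd),
                    }
                )
    ct_expr = pd.DataFrame(ct_rows)

    fe_rows = []
    dct_pos = np.log2(config.true_fe)  # with dCt_neg = 0
    chip_meta = config.sample_meta()
    for sid in chip_meta.sample_ids:
        quartet = {
            ("Rpl30", "IP"): 24.0 - dct_pos / 2,
            ("Rpl30", "input"): 24.0 + dct_pos / 2,
            ("Oosp3", "IP"): 27.0,
            ("Oosp3", "input"): 27.0,
        }
        for (locus, frac), base in quartet.items():
            for rep in (1, 2):
                fe_rows.append(
                    {
                        "sample_id": sid,
                        "target": locus,
                        "fraction": frac,
                        "replicate": rep,
                        "ct": base + rng.normal(0.0, config.ct_noise_sd),
                    }
                )
    ct_fe = pd.DataFrame(fe_rows)
    return ct_expr, qmeta, ct_fe


@dataclass
class SimulatedStudy:
    """Bundle of all generated artefacts for one seed."""

    config: SimulationConfig
    annotation: SimulatedAnnotation
    meta: SampleMeta
    nucleosome_counts: EnrichmentMatrix
    broad_counts: EnrichmentMatrix
    input_counts: EnrichmentMatrix
    truth: GroundTruth
    ct_expression: pd.DataFrame
    qpcr_meta: SampleMeta
    ct_fe: pd.DataFrame
    fragment_paths: dict[str, Path] | None = None


def simulate_study(config: SimulationConfig, fragments_dir=None) -> SimulatedStudy:
    """Run the full generator; optionally write fragment BEDs."""
    sim = simulate_annotation(config)
    nuc, broad, inp, truth = simulate_counts(config, sim)
    ct_expr, qmeta, ct_fe = simulate_qpcr(config, truth)
    frag_paths = None
    if fragments_dir is not None:
        frag_paths = simulate_fragments(
            nuc,
            sim.subpeaks,
            config,
            fragments_dir,
            chrom_sizes=sim.chrom_sizes,
            exclude=[sim.broad_peaks, sim.subpeaks],
        )
    return SimulatedStudy(
        config=config,
        annotation=sim,
        meta=config.sample_meta(),
        nucleosome_counts=nuc,
        broad_counts=broad,
        input_counts=inp,
        truth=truth,
        ct_expression=ct_expr,
        qpcr_meta=qmeta,
        ct_fe=ct_fe,
        fragment_paths=frag_paths,
    )
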