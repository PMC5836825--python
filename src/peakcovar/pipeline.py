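"""End-to-end orchestration: simulate -> annotate -> count -> covary -> DE -> qPCR.

No new computation lives here; the pipeline wires the module operations
together, echoes every threshold into the run log, and writes a
machine-readable ``summary.json`` plus a human-readable report.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import covariation as cov
from . import diffenrich as de
from . import enrichment as enr
from . import genomic_io as gio
from . import qpcr
from .simulate import SimulationConfig, simulate_study


@dataclass
class RunConfig:
    """All stage thresholds in one place; unknown keys are rejected."""

    seed: int = 0
    min_mapq: int = 10
    promoter_flank: int = 1000
    top_k: int = 1000
    r_pos: float = 0.8
    r_neg: float = 0.8
    alpha: float = 0.01
    fdr: float = 0.10
    bias_log2_max: float = 1.0
    window: int = 150
    global_fold: float = 5.0
    fe_gate: float = 25.0
    m_max: float = 0.5
    cv_max: float = 0.25
    run_windows: bool = True
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def thresholds(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("sim")
        return d


#: scaled-down study used by ``peakcovar run --demo`` (sizes chosen to keep a
#: laptop run in seconds while preserving every planted structure)
DEMO_SIM = dict(
    n_genes=1200,
    n_broad_peaks=900,
    subpeaks_per_broad=(2, 6),
    depth=150_000,
    n_cluster_regions=40,
    n_de_regions=45,
    input_bias_regions=5,
)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage on a simulated study and write the report bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"thresholds": config.thresholds()}

    sim_cfg = SimulationConfig(seed=config.seed, **config.sim)
    study = simulate_study(
        sim_cfg, fragments_dir=outdir / "fragments" if config.run_windows else None
    )
    sim = study.annotation
    summary["simulate"] = {
        "n_genes": len(sim.annotation.genes),
        "n_broad_peaks": len(sim.broad_peaks),
        "n_subpeaks": len(sim.subpeaks),
        "n_blacklist": len(sim.blacklist),
    }

    # --- annotate ---------------------------------------------------------
    peaks = gio.subtract_blacklist(sim.broad_peaks, sim.blacklist)
    peaks = gio.assign_peaks(peaks, sim.annotation.tss, flank=config.promoter_flank)
    labels, proportions = gio.classify_context(
        peaks, sim.annotation, flank=config.promoter_flank
    )
    peaks.context = labels
    gio.write_annotated_table(peaks, outdir / "annotated_peaks.tsv")
    promoter_peaks = [p for p, c in labels.items() if c == "promoter"]
    summary["annotate"] = {
        "n_after_blacklist": len(peaks),
        "promoter_fraction": round(float(proportions["promoter"]), 6),
        "bidirectional_fraction": round(
            float(
                sum(peaks.bidirectional.get(p, False) for p in promoter_peaks)
                / max(len(promoter_peaks), 1)
            ),
            6,
        ),
    }

    # --- counts & normalization ------------------------------------------
    broad = study.broad_counts
    kept = [r for r in broad.region_ids if r in set(peaks.ids)]
    broad = de.EnrichmentMatrix(broad.values.loc[kept], resolution="broad")
    sf = enr.size_factors_median_ratio(broad)
    log2m = enr.normalize_log2(broad, sf)
    broad.to_tsv(outdir / "broad_counts.tsv")
    summary["counts"] = {
        "n_regions": len(broad.values),
        "n_samples": broad.values.shape[1],
        "size_factors": {k: round(float(v), 6) for k, v in sf.items()},
    }

    # --- covariation ------------------------------------------------------
    model = cov.CovariationAnalysis(log2m, study.meta)
    result = model.fit(
        top_k=min(config.top_k, len(log2m.values)),
        r_pos=config.r_pos,
        r_neg=config.r_neg,
        alpha=config.alpha,
    )
    result.to_frame().to_csv(outdir / "covariation_subset.tsv", sep="\t")
    if result.selected_ids:
        cov.export_heatmap_matrix(log2m, result, outdir / "covariation_heatmap.tsv")
    summary["covariation"] = {
        "subset_size": len(result.selected_ids),
        "cluster_sizes": [len(result.cluster_a), len(result.cluster_b)],
        "pc1_full": round(float(result.pc_variance_full[0]), 6),
        "pc1_subset": (
            round(float(result.pc_variance_subset[0]), 6)
            if result.pc_variance_subset.size
            else None
        ),
        "factor_association": {
            k: round(float(v), 6) for k, v in result.factor_association.items()
        },
    }

    # --- differential enrichment (peaks) ----------------------------------
    input_counts = de.EnrichmentMatrix(
        study.input_counts.values.loc[kept], resolution="broad"
    )
    de_results = de.de_peak_workflow(
        broad,
        study.meta,
        peaks,
        input_counts,
        fdr=config.fdr,
        bias_log2_max=config.bias_log2_max,
    )
    summary["de"] = {}
    for contrast, res in de_results.items():
        tag = f"{contrast[0]}_vs_{contrast[1]}"
        res.table.join(res.calls).to_csv(outdir / f"de_{tag}.tsv", sep="\t")
        final = res.calls["final"]
        bidir = (
            round(float(res.calls.loc[final, "bidirectional"].mean()), 6)
            if final.any()
            else None
        )
        summary["de"][tag] = {
            "n_fdr": int(res.calls["passes_fdr"].sum()),
            "n_final": int(final.sum()),
            "bidirectional_fraction_final": bidir,
        }

    # --- window workflow ---------------------------------------------------
    if config.run_windows and study.fragment_paths:
        wres = de.window_workflow(
            study.fragment_paths,
            study.meta,
            sim.chrom_sizes,
            contrast=("MS", "CTRL"),
            window=config.window,
            global_fold=config.global_fold,
            fdr=config.fdr,
            min_mapq=config.min_mapq,
        )
        wres.regions.to_csv(outdir / "window_regions.tsv", sep="\t", index=False)
        summary["windows"] = {
            "n_retained_windows": len(wres.windows),
            "n_regions": len(wres.regions),
            "n_significant_regions": int(len(wres.significant_regions())),
        }

    # --- qPCR --------------------------------------------------------------
    fe = qpcr.fold_enrichment(study.ct_fe, "Rpl30", "Oosp3", gate=config.fe_gate)
    fe.to_csv(outdir / "fold_enrichment.tsv", sep="\t")
    m_vals, cv_val = qpcr.genorm_stability(study.ct_expression, ["Hprt1", "Rpl16s"])
    targets = list(study.truth.qpcr_true_fc)
    expr = qpcr.ddct_expression(
        study.ct_expression,
        targets,
        ["Hprt1", "Rpl16s"],
        study.qpcr_meta,
        m_max=config.m_max,
        cv_max=config.cv_max,
    )
    expr.to_csv(outdir / "relative_expression.tsv", sep="\t", index=False)
    fcs = qpcr.group_fold_changes(expr)
    qpcr_summary = {
        "fe_pass": int(fe["passes"].sum()),
        "fe_total": len(fe),
        "housekeeper_M": {k: round(float(v), 6) for k, v in m_vals.items()},
        "housekeeper_CV": round(float(cv_val), 6),
        "group_fold_changes": {},
        "anova": {},
    }
    for gene in targets:
        row = fcs[(fcs["gene"] == gene) & (fcs["group"] == "MS")]
        qpcr_summary["group_fold_changes"][gene] = round(float(row["fold_change"].iloc[0]), 6)
        sub = expr[expr["gene"] == gene].set_index("sample_id")
        st = qpcr.group_stats(sub["rel_expr"], study.qpcr_meta)
        qpcr_summary["anova"][gene] = {
            "F": round(st["F"], 6),
            "p": round(st["p"], 6),
            "lsd_MS_vs_CTRL": round(st["lsd"].get(("CTRL", "MS"), st["lsd"].get(("MS", "CTRL"))), 6),
        }
    summary["qpcr"] = qpcr_summary

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "report.txt").write_text(_render_report(summary))
    return summary


def _render_report(summary: dict) -> str:
    lines = ["peakcovar run report", "=" * 40, ""]
    lines.append("Thresholds:")
    for k, v in sorted(summary["thresholds"].items()):
        lines.append(f"  {k} = {v}")
    for stage in ("simulate", "annotate", "counts", "covariation", "de", "windows", "qpcr"):
        if stage not in summary:
            continue
        lines += ["", f"[{stage}]"]
        lines.append(json.dumps(summary[stage], indent=2, sort_keys=True))
    return "\n".join(lines) + "\n"
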