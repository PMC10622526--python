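"""End-to-end LOH analysis pipeline and report generation.

The pipeline mirrors the published analysis order: read per-cell genotypes,
re-call them through the filtering thresholds, reduce the panel to germline
dbSNP SNPs (anchor whitelisted), partition cells by the anchor genotype,
test every window of k consecutive within-arm SNPs, then every chromosome
arm, each with its own Bonferroni family; finally annotate confounded SNPs
and compute the haplotype-bias table for significant regions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .filtering import FilterThresholds, refine_matrix, select_germline_snvs
from .io import ArmTable, GenotypeMatrix, read_cell_vcf, read_matrix_dir
from .loh import (
    Bin,
    CellPartition,
    LohResult,
    bonferroni,
    flag_confounded_snps,
    haplotype_bias,
    loh_test,
    make_arm_bins,
    make_snp_bins,
    partition_by_anchor,
    per_snp_het_proportion,
    results_table,
)

logger = logging.getLogger("snloh")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    input_path: str | None = None  # VCF file or TSV-quartet directory
    anchor: str | None = None  # variant key or rsID
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    bin_k: int = 4
    bin_mode: str = "sliding"
    alpha: float = 0.05
    min_cells: int = 5
    snv_only: bool = True
    dbsnp_ids: list[str] | None = None
    cytoband_path: str | None = None
    out_dir: str = "snloh_out"
    seed: int = 0


@dataclass
class PipelineReport:
    """Everything run_pipeline computes, plus where it was written."""

    window_results: list[LohResult]
    arm_results: list[LohResult]
    partition: CellPartition
    per_snp: pd.DataFrame
    flags: pd.DataFrame
    haplotype: pd.DataFrame
    significant_arms: list[str]
    out_paths: dict[str, str]


def load_matrix(cfg: RunConfig) -> GenotypeMatrix:
    if cfg.input_path is None:
        raise ValueError("RunConfig.input_path is not set")
    if os.path.isdir(cfg.input_path):
        return read_matrix_dir(cfg.input_path)
    return read_cell_vcf(cfg.input_path)


def analyze_matrix(
    matrix: GenotypeMatrix, cfg: RunConfig, arms: ArmTable | None = None
) -> PipelineReport:
    """Run the LOH analysis on an already-loaded matrix (no file output)."""
    arms = arms or (
        ArmTable.from_cytoband(cfg.cytoband_path) if cfg.cytoband_path else ArmTable()
    )
    refined = refine_matrix(matrix, cfg.thresholds)
    if cfg.dbsnp_ids is not None:
        from .io import annotate_dbsnp

        refined = annotate_dbsnp(refined, cfg.dbsnp_ids)
        for v, orig in zip(refined.variants, matrix.variants):
            v.is_anchor = orig.is_anchor
    selected = select_germline_snvs(refined, cfg.thresholds, snv_only=cfg.snv_only)
    if cfg.anchor is None:
        raise ValueError("RunConfig.anchor is not set")
    partition = partition_by_anchor(selected, cfg.anchor)
    logger.info(
        "partition: %d GoF, %d WT, %d excluded",
        len(partition.gof_cells),
        len(partition.wt_cells),
        len(partition.excluded_cells),
    )

    # drop the anchor itself from the heterozygosity panel: its genotype
    # defines the groups, so keeping it would be circular
    germline_idx = [i for i, v in enumerate(selected.variants) if not v.is_anchor]
    germline = selected.subset(variant_idx=germline_idx)

    window_bins = make_snp_bins(germline, arms, k=cfg.bin_k, mode=cfg.bin_mode)
    window_results = bonferroni(
        [loh_test(germline, partition, b, cfg.min_cells) for b in window_bins],
        alpha=cfg.alpha,
    )
    arm_bins = make_arm_bins(germline, arms)
    arm_results = bonferroni(
        [loh_test(germline, partition, b, cfg.min_cells) for b in arm_bins],
        alpha=cfg.alpha,
    )

    significant_bins: list[Bin] = [
        r.bin for r in window_results + arm_results if r.significant
    ]
    significant_arms = [r.bin.label for r in arm_results if r.significant]
    per_snp = per_snp_het_proportion(germline, partition)
    flags = flag_confounded_snps(germline, significant_bins, partition)
    hap_frames = []
    for r in arm_results:
        if r.significant:
            df = haplotype_bias(germline, partition, r.bin.snp_indices)
            df.insert(0, "arm", r.bin.label)
            hap_frames.append(df)
    haplotype = (
        pd.concat(hap_frames, ignore_index=True)
        if hap_frames
        else pd.DataFrame(columns=["arm", "variant", "ratio_gof", "n_hom_gof", "ratio_wt", "n_hom_wt"])
    )
    return PipelineReport(
        window_results=window_results,
        arm_results=arm_results,
        partition=partition,
        per_snp=per_snp,
        flags=flags,
        haplotype=haplotype,
        significant_arms=significant_arms,
        out_paths={},
    )


def run_pipeline(cfg: RunConfig) -> PipelineReport:
    """Load input, run the analysis and write the TSV report bundle."""
    matrix = load_matrix(cfg)
    report = analyze_matrix(matrix, cfg)
    os.makedirs(cfg.out_dir, exist_ok=True)
    paths = {
        "windows": os.path.join(cfg.out_dir, "loh_windows.tsv"),
        "arms": os.path.join(cfg.out_dir, "loh_arms.tsv"),
        "per_snp": os.path.join(cfg.out_dir, "per_snp_het.tsv"),
        "flags": os.path.join(cfg.out_dir, "confounded_snps.tsv"),
        "haplotype": os.path.join(cfg.out_dir, "haplotype_bias.tsv"),
        "run_info": os.path.join(cfg.out_dir, "run_info.json"),
    }
    results_table(report.window_results).to_csv(paths["windows"], sep="\t", index=False)
    results_table(report.arm_results).to_csv(paths["arms"], sep="\t", index=False)
    report.per_snp.to_csv(paths["per_snp"], sep="\t", index=False)
    report.flags.to_csv(paths["flags"], sep="\t", index=False)
    report.haplotype.to_csv(paths["haplotype"], sep="\t", index=False)
    info = {
        "snloh_version": __version__,
        "config": dataclasses.asdict(cfg),
        "n_gof": len(report.partition.gof_cells),
        "n_wt": len(report.partition.wt_cells),
        "n_excluded": len(report.partition.excluded_cells),
        "significant_arms": report.significant_arms,
    }
    with open(paths["run_info"], "w") as fh:
        json.dump(info, fh, indent=2)
    report.out_paths = paths
    logger.info("report written to %s", cfg.out_dir)
    return report


def render_report(report: PipelineReport, out_dir: str, plots: bool = True) -> str:
    """Human-readable summary (and optional bar charts) of a pipeline run.

    Writes summary.txt and, when matplotlib is importable, one grouped
    GoF-vs-WT heterozygosity bar chart per significant arm.
    """
    os.makedirs(out_dir, exist_ok=True)
    lines = [
        f"snloh {__version__} LOH report",
        "",
        f"cells: {len(report.partition.gof_cells)} GoF / "
        f"{len(report.partition.wt_cells)} WT / "
        f"{len(report.partition.excluded_cells)} excluded",
        "",
    ]
    if report.significant_arms:
        lines.append("significant LOH evidence (arm-level, Bonferroni):")
        for r in report.arm_results:
            if r.significant:
                lines.append(
                    f"  {r.bin.label}: median Prop_het GoF={r.median_gof:.3f} "
                    f"WT={r.median_wt:.3f}, p_adj={r.p_adj:.3g}"
                )
    else:
        lines.append("no LOH evidence in any chromosomal arm")
    n_sig_windows = sum(bool(r.significant) for r in report.window_results)
    lines.append(f"significant SNP-window bins: {n_sig_windows}")
    if not report.flags.empty:
        lines.append("")
        lines.append("confounded-SNP flags (annotation only):")
        for _, row in report.flags.iterrows():
            reasons = [
                name
                for name in ("overlaps_indel", "multi_alt_het", "near_indel")
                if row[name]
            ]
            lines.append(f"  {row['variant']}: {', '.join(reasons) or 'none'}")
    text = "\n".join(lines) + "\n"
    summary_path = os.path.join(out_dir, "summary.txt")
    with open(summary_path, "w") as fh:
        fh.write(text)

    if plots and report.significant_arms:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except Exception:  # pragma: no cover - matplotlib is a hard dep
            logger.warning("plotting unavailable; text-only report")
            return summary_path
        for r in report.arm_results:
            if not r.significant:
                continue
            arm = r.bin.label
            snps = report.per_snp.iloc[list(r.bin.snp_indices)]
            fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(snps)), 3.5))
            x = range(len(snps))
            ax.bar([i - 0.2 for i in x], snps["prop_gof"], width=0.4, label="GoF")
            ax.bar([i + 0.2 for i in x], snps["prop_wt"], width=0.4, label="WT")
            ax.set_ylim(0, 1)
            ax.set_ylabel("proportion heterozygous")
            ax.set_title(f"arm {arm}")
            ax.set_xticks(list(x))
            ax.set_xticklabels(snps["variant"], rotation=90, fontsize=5)
            ax.legend()
            fig.tight_layout()
            fig.savefig(os.path.join(out_dir, f"arm_{arm}.png"), dpi=150)
            plt.close(fig)
    return summary_path
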