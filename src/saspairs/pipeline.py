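"""End-to-end orchestration: annotation -> overlaps -> landscape -> correlation.

``run_pipeline`` executes the stages in order, writes every result table
(TSV + BED), and produces a plain-text report whose every number is
recomputable from the emitted tables.  In synthetic mode the input files
are first generated and written, then read back through the ordinary
readers so the full I/O path is exercised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation_io as aio
from . import correlation as corr
from . import landscape as ls
from . import overlap as ov
from .simulate import SyntheticConfig, write_synthetic_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, parameters and mode of one pipeline run."""

    out_dir: str | Path = "saspairs_out"
    gff: str | Path | None = None
    expression: str | Path | None = None
    metadata: str | Path | None = None
    chrom_lengths: str | Path | None = None
    min_samples: int = 26
    threshold: float = 0.0
    alpha: float = 0.05
    feature_type: str = "gene"
    biotype_key: str = "gene_biotype"
    synthetic: SyntheticConfig | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            if "overlap_frac_bounds" in syn:
                syn["overlap_frac_bounds"] = tuple(syn["overlap_frac_bounds"])
            if syn.get("planted_rho") is not None:
                syn["planted_rho"] = [tuple(t) for t in syn["planted_rho"]]
            raw["synthetic"] = SyntheticConfig(**syn)
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_samples < 0:
            raise ValueError("min_samples must be non-negative")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.synthetic is None:
            if self.gff is None:
                raise FileNotFoundError("no GFF3 input and no synthetic config")
            for p in (self.gff, self.expression, self.metadata, self.chrom_lengths):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")


def _fmt_stats(s: dict | None) -> str:
    if s is None:
        return "(no pairs)"
    return f"median {s['median']:g}, min {s['min']:g}, max {s['max']:g}"


def run_pipeline(config: PipelineConfig) -> tuple[str, dict[str, Path]]:
    """Run all stages; returns the text report and the written file paths."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        if config.synthetic.seed != config.seed:
            config.synthetic.seed = config.seed
        inputs = write_synthetic_dataset(config.synthetic, out_dir / "inputs")
        config.gff = inputs["gff"]
        config.expression = inputs["expression"]
        config.metadata = inputs["samples"]
        config.chrom_lengths = inputs["chrom_lengths"]

    genes, rejected = aio.read_gff(
        config.gff, feature_type=config.feature_type, biotype_key=config.biotype_key
    )
    logger.info("annotation: %d stranded genes, %d unstranded rejected", len(genes), len(rejected))
    chrom_table = (
        aio.read_chrom_table(config.chrom_lengths) if config.chrom_lengths else None
    )

    pairs = ov.find_opposite_strand_overlaps(genes)
    pair_table = ov.pairs_to_table(pairs)
    length_summary = ls.summarize_lengths(pairs)
    ratio_table = ls.summarize_ratios(pairs)
    biotype_table = ls.biotype_pair_table(pairs)
    tables: dict[str, pd.DataFrame] = {
        "ratio_summary": ratio_table,
        "biotype_table": biotype_table,
    }
    chrom_df = None
    if chrom_table is not None:
        chrom_df = ls.chromosome_distribution(pairs, genes, chrom_table)
        tables["chromosome_table"] = chrom_df

    lines: list[str] = []
    lines.append("sense-antisense overlap landscape report")
    lines.append("=" * 40)
    lines.append(f"annotated genes (stranded): {len(genes)}")
    lines.append(f"unstranded features rejected: {len(rejected)}")
    n_pairs = length_summary["n_pairs"]
    involved = {p.sense.gene_id for p in pairs} | {p.antisense.gene_id for p in pairs}
    lines.append(f"overlapping pairs: {n_pairs}")
    lines.append(f"distinct genes in pairs: {len(involved)}")
    for f in ov.FORMS:
        cnt = length_summary["per_form_counts"][f]
        frac = 100.0 * cnt / n_pairs if n_pairs else 0.0
        lines.append(f"  form {f}: {cnt} ({frac:.1f}%)")
    lines.append(f"overlap length (bp): {_fmt_stats(length_summary['overall'])}")
    for f in ov.FORMS:
        lines.append(f"  form {f} length: {_fmt_stats(length_summary['per_form'][f])}")
    lines.append(f"pairs with 1-bp overlap: {length_summary['n_1bp']}")
    if chrom_df is not None:
        lines.append("per-chromosome pairs (chrom: n, per Mb, % of pairs):")
        for row in chrom_df.itertuples(index=False):
            lines.append(
                f"  {row.chrom}: {row.n_pairs}, {row.n_pairs_per_Mb:.3f}/Mb, "
                f"{row.pct_of_all_pairs:.1f}%"
            )
    if not biotype_table.empty:
        lines.append("biotype pairs (label: total, %):")
        for row in biotype_table.itertuples(index=False):
            lines.append(f"  {row.biotype_pair}: {row.total}, {row.pct:.1f}%")

    if config.expression is not None:
        expr = aio.read_expression(config.expression, config.metadata)
        retained, filter_table = corr.filter_expressed_pairs(
            pairs, expr, min_samples=config.min_samples, threshold=config.threshold
        )
        tables["filter_table"] = filter_table
        lines.append(
            f"expression filter (>= {config.min_samples} expressed strand-samples): "
            f"{len(retained)} of {len(pairs)} pairs retained"
        )
        results, summary, corr_table = corr.correlate_all(
            retained,
            expr,
            alpha=config.alpha,
            min_samples=config.min_samples,
            threshold=config.threshold,
        )
        tables["correlation_table"] = corr_table
        skew_median, density = corr.strand_skew(retained, expr)
        tables["density_matrix"] = density
        heat = corr.heatmap_matrix(retained, expr)
        heat_path = out_dir / "heatmap_matrix.tsv"
        heat.to_csv(heat_path, sep="\t", lineterminator="\n")
        if summary is not None:
            tables["correlation_summary"] = pd.DataFrame(
                [
                    {
                        "n_tested": summary.n_tested,
                        "mean_rho": summary.mean_rho,
                        "sd_rho": summary.sd_rho,
                        "median_rho": summary.median_rho,
                        "n_sig_pos": summary.n_sig_pos,
                        "n_sig_neg": summary.n_sig_neg,
                        "skew_median": skew_median,
                    }
                ]
            )
            lines.append(f"pairs tested for correlation: {summary.n_tested}")
            lines.append(
                f"Spearman rho: mean {summary.mean_rho:.4f} +/- {summary.sd_rho:.4f}, "
                f"median {summary.median_rho:.4f}"
            )
            lines.append(
                f"significant (BH-adjusted p < {config.alpha:g}): "
                f"{summary.n_sig_pos} positive, {summary.n_sig_neg} negative"
            )
            lines.append(f"antisense/sense expression skew (median): {skew_median:.4f}")
        else:
            lines.append("no testable pairs after filtering")

    paths = aio.write_results(tables, out_dir, pair_table=pair_table)
    if config.expression is not None:
        paths["heatmap_matrix"] = out_dir / "heatmap_matrix.tsv"
    report = "\n".join(lines) + "\n"
    report_path = out_dir / "report.txt"
    report_path.write_text(report)
    paths["report"] = report_path
    return report, paths
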