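"""Synthetic annotation and expression generator with planted ground truth.

Emulates the statistical structure the analysis assumes, so every stage is
testable without any download: a multi-chromosome gene annotation with
planted opposite-strand overlaps of all four forms in controlled
proportions and realistic biotype frequencies, and a stage-structured
per-strand FPKM matrix with planted Spearman correlation and dropout.

Planted correlations use a Gaussian copula: latent bivariate-normal samples
with Pearson parameter r = 2*sin(pi*rho_s/6) have Spearman correlation
rho_s, and rho_s survives the monotone log-normal map to the FPKM scale
exactly in expectation.  Dropout (zeroing with a configured probability) is
applied after the correlation structure, modeling detection failure rather
than biological zeros.

Defaults mirror the study design the pipeline targets: 16 biological
samples over four gestational stages (45 days, 4/6/10 months), split into
sense and antisense strand libraries (32 strand-samples); a form mix
dominated by head-to-head pairs (~70% D, ~25% embedded, ~5% tail-to-tail);
a gene-biotype mix of ~70% mRNA and ~22% lncRNA; and per-pair target
correlations centered on 0.29 with spread 0.21.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from .annotation_io import (
    STAGES,
    AnnotationError,
    ExpressionMatrix,
    GeneRecord,
    write_chrom_table,
    write_expression,
    write_gff,
)
from .overlap import FORMS, biotype_pair_label

DEFAULT_FORM_MIX = {"A": 0.06, "B": 0.19, "C": 0.05, "D": 0.70}
DEFAULT_BIOTYPE_FREQS = {
    "mRNA": 0.70,
    "lncRNA": 0.22,
    "miRNA": 0.02,
    "tRNA": 0.01,
    "snRNA": 0.01,
    "miscRNA": 0.01,
    "other": 0.03,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``planted_rho`` optionally pins target Spearman correlations to specific
    pair indices; unlisted pairs then get rho 0.  When it is ``None`` every
    pair draws its target from a clipped normal with mean ``rho_mean`` and
    sd ``rho_sd``.  ``stage_shift_sd`` adds a per-stage expression shift
    shared by both members of a pair; it defaults to 0 because a shared
    shift is common signal that inflates the realized rank correlation above
    its planted value (see docs).
    """

    seed: int = 0
    n_chroms: int = 5
    chrom_lengths: list[int] | None = None  # default: 2 Mb each
    n_genes: int = 600
    n_planted_pairs: int = 150
    form_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FORM_MIX))
    biotype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_FREQS)
    )
    gene_length_meanlog: float = math.log(2000.0)  # median gene span 2 kb
    gene_length_sdlog: float = 1.0
    min_gene_len: int = 200
    overlap_frac_bounds: tuple[float, float] = (0.05, 0.95)
    n_biosamples: int = 16
    fpkm_meanlog: float = 1.5  # median FPKM ~4.5
    fpkm_sdlog: float = 1.0
    planted_rho: list[tuple[int, float]] | None = None
    rho_mean: float = 0.29
    rho_sd: float = 0.21
    rho_clip: float = 0.95
    stage_shift_sd: float = 0.0
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.chrom_lengths is None:
            self.chrom_lengths = [2_000_000] * self.n_chroms
        if len(self.chrom_lengths) != self.n_chroms:
            raise ValueError("chrom_lengths must have n_chroms entries")
        for name, probs in (("form_mix", self.form_mix), ("biotype_freqs", self.biotype_freqs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        if self.n_genes < 2 * self.n_planted_pairs:
            raise ValueError("n_genes must cover 2 genes per planted pair")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.planted_rho is not None:
            for _, rho in self.planted_rho:
                if abs(rho) > 1.0:
                    raise ValueError(f"target Spearman rho out of range: {rho}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SyntheticTruth:
    """Planted ground truth: one record per planted pair, plus dropout mask."""

    pairs: pd.DataFrame  # sense_id, antisense_id, chrom, form, ov_start, ov_end, ...
    dropout: pd.DataFrame | None = None  # gene x strand-sample boolean mask


def _draw_length(rng: np.random.Generator, cfg: SyntheticConfig) -> int:
    L = int(round(rng.lognormal(cfg.gene_length_meanlog, cfg.gene_length_sdlog)))
    return max(cfg.min_gene_len, L)


def _pair_coords(
    rng: np.random.Generator, cfg: SyntheticConfig, form: str, chrom_len: int
) -> tuple[int, int, int, int]:
    """Coordinates (s1, e1, s2, e2) realizing ``form`` exactly.

    The sense gene is [s1,e1] on '+', the antisense gene [s2,e2] on '-'.
    Partial overlaps (C/D) draw the overlap as a fraction of the shorter
    gene from ``overlap_frac_bounds``; embeddings (A/B) draw the embedded
    gene's length as that fraction of the container.
    """
    lo, hi = cfg.overlap_frac_bounds
    u = rng.uniform(lo, hi)
    L1 = _draw_length(rng, cfg)
    if form == "A":
        L2 = min(L1, max(1, int(round(u * L1))))
        margin = 10
        s1 = int(rng.integers(margin + 1, chrom_len - L1 - margin))
        e1 = s1 + L1 - 1
        off = int(rng.integers(0, L1 - L2 + 1))
        s2, e2 = s1 + off, s1 + off + L2 - 1
    elif form == "B":
        ext = max(2, int(round(L1 * (1.0 / u - 1.0))))
        a = int(rng.integers(1, ext))
        b = max(1, ext - a)
        s1 = int(rng.integers(a + 2, chrom_len - L1 - b - 2))
        e1 = s1 + L1 - 1
        s2, e2 = s1 - a, e1 + b
    else:
        L2 = _draw_length(rng, cfg)
        shorter = min(L1, L2)
        if shorter < 2:
            L2 = max(L2, 2)
            shorter = min(L1, L2)
        ov = min(shorter - 1, max(1, int(round(u * shorter))))
        if form == "C":
            # antisense shifted right: overlap covers + 3' end (e1) and - 3' end (s2)
            span = L1 + L2 - ov
            s1 = int(rng.integers(11, chrom_len - span - 10))
            e1 = s1 + L1 - 1
            s2 = e1 - ov + 1
            e2 = s2 + L2 - 1
        else:
            # D: antisense shifted left: overlap covers + 5' end (s1) and - 5' end (e2)
            span = L1 + L2 - ov
            s2 = int(rng.integers(11, chrom_len - span - 10))
            e2 = s2 + L2 - 1
            s1 = e2 - ov + 1
            e1 = s1 + L1 - 1
    return s1, e1, s2, e2


def generate_annotation(cfg: SyntheticConfig) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Generate the annotation with planted pairs; deterministic given seed.

    Each planted pair's antisense coordinates are constructed to realize the
    drawn form exactly; remaining (filler) genes are placed so they overlap
    nothing, so the detected pair set equals the planted set.  Raises when a
    pair cannot be placed without collision after bounded retries.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom_names = cfg.chrom_names
    lengths = np.asarray(cfg.chrom_lengths, dtype=float)
    chrom_probs = lengths / lengths.sum()
    occupied = {c: IntervalTree() for c in chrom_names}

    forms = list(FORMS)
    form_p = np.array([cfg.form_mix[f] for f in forms])
    biotypes = list(cfg.biotype_freqs)
    biotype_p = np.array([cfg.biotype_freqs[b] for b in biotypes])

    if cfg.planted_rho is None:
        rhos = np.clip(
            rng.normal(cfg.rho_mean, cfg.rho_sd, size=cfg.n_planted_pairs),
            -cfg.rho_clip,
            cfg.rho_clip,
        )
    else:
        rhos = np.zeros(cfg.n_planted_pairs)
        for idx, rho in cfg.planted_rho:
            rhos[idx] = rho

    genes: list[GeneRecord] = []
    truth_rows = []
    for i in range(cfg.n_planted_pairs):
        form = forms[int(rng.choice(len(forms), p=form_p))]
        for attempt in range(200):
            ci = int(rng.choice(len(chrom_names), p=chrom_probs))
            chrom, clen = chrom_names[ci], cfg.chrom_lengths[ci]
            try:
                s1, e1, s2, e2 = _pair_coords(rng, cfg, form, clen)
            except ValueError:  # drawn gene too long for this chromosome
                continue
            lo, hi = min(s1, s2), max(e1, e2)
            if lo < 1 or hi > clen:
                continue
            if not occupied[chrom].overlap(lo, hi + 1):
                occupied[chrom].addi(lo, hi + 1)
                break
        else:
            raise AnnotationError(
                f"could not place planted pair {i} after 200 attempts; "
                "use longer chromosomes or fewer genes"
            )
        b_s = biotypes[int(rng.choice(len(biotypes), p=biotype_p))]
        b_a = biotypes[int(rng.choice(len(biotypes), p=biotype_p))]
        sid, aid = f"P{i:04d}S", f"P{i:04d}A"
        genes.append(GeneRecord(sid, chrom, s1, e1, "+", b_s))
        genes.append(GeneRecord(aid, chrom, s2, e2, "-", b_a))
        truth_rows.append(
            {
                "sense_id": sid,
                "antisense_id": aid,
                "chrom": chrom,
                "form": form,
                "ov_start": max(s1, s2),
                "ov_end": min(e1, e2),
                "biotype_pair": biotype_pair_label(b_s, b_a),
                "rho_target": float(rhos[i]),
            }
        )

    n_fill = cfg.n_genes - 2 * cfg.n_planted_pairs
    for i in range(n_fill):
        strand = "+" if rng.random() < 0.5 else "-"
        for attempt in range(200):
            ci = int(rng.choice(len(chrom_names), p=chrom_probs))
            chrom, clen = chrom_names[ci], cfg.chrom_lengths[ci]
            L = _draw_length(rng, cfg)
            if L + 20 >= clen:
                continue
            s = int(rng.integers(11, clen - L - 10))
            e = s + L - 1
            if not occupied[chrom].overlap(s, e + 1):
                occupied[chrom].addi(s, e + 1)
                break
        else:
            raise AnnotationError(
                f"could not place filler gene {i} after 200 attempts; "
                "use longer chromosomes or fewer genes"
            )
        bt = biotypes[int(rng.choice(len(biotypes), p=biotype_p))]
        genes.append(GeneRecord(f"F{i:04d}", chrom, s, e, strand, bt))

    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    truth = SyntheticTruth(pairs=pd.DataFrame(truth_rows))
    return genes, truth


def spearman_to_pearson_latent(rho_s: float) -> float:
    """Latent Pearson r giving Spearman rho_s under a Gaussian copula."""
    if abs(rho_s) > 1.0:
        raise ValueError(f"target Spearman rho out of range: {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_expression(
    genes: Sequence[GeneRecord], truth: SyntheticTruth, cfg: SyntheticConfig
) -> ExpressionMatrix:
    """Generate the per-strand FPKM matrix with planted rank correlation.

    Each gene is quantified on its own strand's libraries; its values in the
    opposite strand's libraries are zero (strand-phased quantification sees
    no signal there).  For each planted pair, 16 latent bivariate-normal
    draws with Pearson parameter 2*sin(pi*rho_s/6) are pushed through the
    log-normal FPKM transform; other genes are independent.  Dropout zeroes
    own-strand values with the configured probability; the mask is stored on
    the truth object.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_biosamples
    per_stage = [n // len(STAGES) + (1 if i < n % len(STAGES) else 0) for i in range(len(STAGES))]
    bios, stages = [], []
    k = 0
    for stage, cnt in zip(STAGES, per_stage):
        for _ in range(cnt):
            bios.append(f"b{k + 1:02d}")
            stages.append(stage)
            k += 1

    sense_cols = [f"{b}.sense" for b in bios]
    anti_cols = [f"{b}.antisense" for b in bios]
    meta = pd.DataFrame(
        {
            "sample_id": sense_cols + anti_cols,
            "stage": stages + stages,
            "strand_label": ["sense"] * n + ["antisense"] * n,
            "biosample": bios + bios,
        }
    ).set_index("sample_id")

    gene_ids = [g.gene_id for g in genes]
    strand_of = {g.gene_id: g.strand for g in genes}
    values = pd.DataFrame(
        0.0, index=pd.Index(gene_ids, name="gene_id"), columns=sense_cols + anti_cols
    )

    stage_idx = np.array([STAGES.index(s) for s in stages])

    def to_fpkm(z: np.ndarray, shifts: np.ndarray) -> np.ndarray:
        return np.exp(cfg.fpkm_meanlog + cfg.fpkm_sdlog * (z + shifts[stage_idx]))

    planted_genes: set[str] = set()
    for row in truth.pairs.itertuples(index=False):
        r = spearman_to_pearson_latent(row.rho_target)
        z1 = rng.standard_normal(n)
        z2 = r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
        shifts = (
            rng.normal(0.0, cfg.stage_shift_sd, size=len(STAGES))
            if cfg.stage_shift_sd > 0
            else np.zeros(len(STAGES))
        )
        values.loc[row.sense_id, sense_cols] = to_fpkm(z1, shifts)
        values.loc[row.antisense_id, anti_cols] = to_fpkm(z2, shifts)
        planted_genes.update((row.sense_id, row.antisense_id))

    zero_shifts = np.zeros(len(STAGES))
    for gid in gene_ids:
        if gid in planted_genes:
            continue
        cols = sense_cols if strand_of[gid] == "+" else anti_cols
        values.loc[gid, cols] = to_fpkm(rng.standard_normal(n), zero_shifts)

    # dropout: zero own-strand cells with the configured probability
    own = np.zeros(values.shape, dtype=bool)
    col_pos = {c: j for j, c in enumerate(values.columns)}
    for i, gid in enumerate(gene_ids):
        cols = sense_cols if strand_of[gid] == "+" else anti_cols
        for c in cols:
            own[i, col_pos[c]] = True
    mask = own & (rng.random(values.shape) < cfg.dropout_rate)
    arr = values.to_numpy()
    arr[mask] = 0.0
    values.iloc[:, :] = arr
    truth.dropout = pd.DataFrame(mask, index=values.index, columns=values.columns)

    return ExpressionMatrix(values=values, sample_meta=meta)


def write_synthetic_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a full synthetic dataset to ``out_dir``.

    Emits the GFF3 annotation, expression matrix TSV, sample-metadata TSV,
    chromosome-length TSV, planted-truth TSV, and the config as YAML.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes, truth = generate_annotation(cfg)
    expr = generate_expression(genes, truth, cfg)
    paths = {
        "gff": write_gff(genes, out_dir / "annotation.gff3"),
        "chrom_lengths": write_chrom_table(
            dict(zip(cfg.chrom_names, cfg.chrom_lengths)), out_dir / "chrom_lengths.tsv"
        ),
    }
    m, s = write_expression(expr, out_dir / "expression.tsv", out_dir / "samples.tsv")
    paths["expression"], paths["samples"] = m, s
    truth_path = out_dir / "truth.tsv"
    truth.pairs.to_csv(truth_path, sep="\t", index=False, lineterminator="\n")
    paths["truth"] = truth_path
    cfg_path = out_dir / "config.yaml"
    cfg_dict = asdict(cfg)
    cfg_dict["overlap_frac_bounds"] = list(cfg.overlap_frac_bounds)
    if cfg_dict.get("planted_rho") is not None:
        cfg_dict["planted_rho"] = [list(t) for t in cfg_dict["planted_rho"]]
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths
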