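"""Expression correlation of sense-antisense pairs across gestation.

Given the detected pairs and a per-strand FPKM matrix over the gestational
time course, this module (i) filters pairs by expression support (the
26-of-32 rule: sense-gene values above threshold in the sense strand-samples
plus antisense-gene values in the antisense strand-samples), (ii) computes
per-pair Spearman correlation across biological samples with
Benjamini-Hochberg FDR adjustment, (iii) summarizes the correlation
landscape, (iv) computes the antisense/sense expression-skew statistic, and
(v) exports density- and heatmap-matrix data on the log10(FPKM+1) scale.

Spearman rho is the Pearson correlation of mid-ranks (average ranks for
ties); p-values use the t-approximation with n-2 degrees of freedom, the
convention of mainstream statistics packages and adequate at n = 16.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import STAGES, ExpressionMatrix
from .overlap import OverlapPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation of one pair's sense vs antisense expression."""

    pair: OverlapPair
    rho: float
    p_raw: float
    p_adj: float
    n_expressed: int  # strand-samples above threshold (of 32)
    n_obs: int  # paired observations used (of 16)
    significant: bool
    constant: bool = False  # zero rank variance; excluded from BH


@dataclass(frozen=True)
class CorrelationSummary:
    mean_rho: float
    sd_rho: float
    median_rho: float
    n_tested: int
    n_sig_pos: int
    n_sig_neg: int


def align_strand_samples(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pair each sense strand-sample with its antisense counterpart.

    If the metadata carries a ``biosample`` column, strand-samples sharing a
    biosample are paired directly.  Otherwise sense and antisense sample ids
    are sorted within each gestational stage and paired positionally — a
    deterministic convention that assumes consistent naming within stages.
    Rows are ordered by stage (chronological) then pairing key.
    """
    meta = expr.sample_meta.loc[expr.samples]
    rows = []
    if "biosample" in meta.columns and meta["biosample"].notna().all():
        for bio, grp in meta.groupby("biosample", sort=True):
            sense = grp.index[grp["strand_label"] == "sense"]
            anti = grp.index[grp["strand_label"] == "antisense"]
            if len(sense) != 1 or len(anti) != 1:
                raise ValueError(
                    f"biosample {bio!r} needs exactly one sense and one antisense "
                    f"strand-sample, got {len(sense)} and {len(anti)}"
                )
            rows.append(
                {
                    "biosample": bio,
                    "stage": grp["stage"].iloc[0],
                    "sense_sample": sense[0],
                    "antisense_sample": anti[0],
                }
            )
    else:
        for stage in STAGES:
            grp = meta[meta["stage"] == stage]
            sense = sorted(grp.index[grp["strand_label"] == "sense"])
            anti = sorted(grp.index[grp["strand_label"] == "antisense"])
            if len(sense) != len(anti):
                raise ValueError(
                    f"stage {stage!r}: {len(sense)} sense vs {len(anti)} antisense "
                    "strand-samples; cannot align without a biosample column"
                )
            for s, a in zip(sense, anti):
                rows.append(
                    {"biosample": s, "stage": stage, "sense_sample": s, "antisense_sample": a}
                )
    df = pd.DataFrame(rows, columns=["biosample", "stage", "sense_sample", "antisense_sample"])
    df["stage"] = pd.Categorical(df["stage"], categories=STAGES, ordered=True)
    return df.sort_values(["stage", "biosample"], kind="stable").reset_index(drop=True)


def filter_expressed_pairs(
    pairs: list[OverlapPair],
    expr: ExpressionMatrix,
    min_samples: int = 26,
    threshold: float = 0.0,
) -> tuple[list[OverlapPair], pd.DataFrame]:
    """Keep pairs expressed in at least ``min_samples`` strand-samples.

    The sense gene is counted over the sense strand-samples and the
    antisense gene over the antisense strand-samples (16 + 16 in the default
    design); a pair is retained when the two above-threshold counts sum to
    at least ``min_samples``.  "Expressed" means FPKM strictly above
    ``threshold`` (default 0).  Pairs whose genes are absent from the matrix
    are dropped with a logged reason, never an exception.

    Returns the retained pairs and a per-pair table of both counts and the
    retention decision.
    """
    sense_cols = expr.samples_for("sense")
    anti_cols = expr.samples_for("antisense")
    retained: list[OverlapPair] = []
    rows = []
    for p in pairs:
        if p.sense.gene_id not in expr.values.index or p.antisense.gene_id not in expr.values.index:
            logger.warning(
                "pair %s|%s dropped: gene absent from expression matrix",
                p.sense.gene_id,
                p.antisense.gene_id,
            )
            continue
        n_sense = int((expr.values.loc[p.sense.gene_id, sense_cols] > threshold).sum())
        n_anti = int((expr.values.loc[p.antisense.gene_id, anti_cols] > threshold).sum())
        keep = n_sense + n_anti >= min_samples
        rows.append(
            {
                "sense_id": p.sense.gene_id,
                "antisense_id": p.antisense.gene_id,
                "n_expressed_sense": n_sense,
                "n_expressed_antisense": n_anti,
                "n_expressed_total": n_sense + n_anti,
                "retained": keep,
            }
        )
        if keep:
            retained.append(p)
    table = pd.DataFrame(
        rows,
        columns=[
            "sense_id", "antisense_id", "n_expressed_sense",
            "n_expressed_antisense", "n_expressed_total", "retained",
        ],
    )
    logger.info(
        "expression filter (>=%d of %d strand-samples): %d of %d pairs retained",
        min_samples, len(sense_cols) + len(anti_cols), len(retained), len(pairs),
    )
    return retained, table


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Returns ``(nan, nan)`` when either vector has zero rank variance (rho is
    undefined for a constant vector).  |rho| = 1 yields the smallest
    representable positive p rather than 0, so downstream FDR adjustment
    stays within (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    res = stats.spearmanr(x, y)
    rho, p = float(res.statistic), float(res.pvalue)
    if p == 0.0:
        p = float(np.nextafter(0.0, 1.0))
    return rho, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    The standard step-up: sort ascending, q_(i) = min_{j>=i} m*p_(j)/j,
    mapped back to the input order; invariant under permutation of inputs.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_all(
    pairs: list[OverlapPair],
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    min_samples: int = 26,
    threshold: float = 0.0,
) -> tuple[list[CorrelationResult], CorrelationSummary | None, pd.DataFrame]:
    """Spearman-correlate every (already filtered) pair, with BH adjustment.

    Sense and antisense values are aligned by biological sample (same fetus,
    opposite strand-phased libraries).  BH runs over exactly the testable
    set; constant pairs are flagged and excluded from it.  Returns per-pair
    results, a landscape summary (mean +/- sd and median rho, significant
    positive/negative counts), and a results table sorted by rho descending.
    """
    align = align_strand_samples(expr)
    sense_cols = list(align["sense_sample"])
    anti_cols = list(align["antisense_sample"])
    sense_count_cols = expr.samples_for("sense")
    anti_count_cols = expr.samples_for("antisense")

    testable: list[tuple[OverlapPair, float, float, int]] = []
    constants: list[tuple[OverlapPair, int]] = []
    for p in pairs:
        x = expr.values.loc[p.sense.gene_id, sense_cols].to_numpy(dtype=float)
        y = expr.values.loc[p.antisense.gene_id, anti_cols].to_numpy(dtype=float)
        n_expressed = int(
            (expr.values.loc[p.sense.gene_id, sense_count_cols] > threshold).sum()
            + (expr.values.loc[p.antisense.gene_id, anti_count_cols] > threshold).sum()
        )
        rho, p_raw = spearman(x, y)
        if np.isnan(rho):
            constants.append((p, n_expressed))
        else:
            testable.append((p, rho, p_raw, n_expressed))

    results: list[CorrelationResult] = []
    if testable:
        p_adj = bh_adjust([t[2] for t in testable])
        for (pair, rho, p_raw, n_expr), q in zip(testable, p_adj):
            results.append(
                CorrelationResult(
                    pair=pair,
                    rho=rho,
                    p_raw=p_raw,
                    p_adj=float(q),
                    n_expressed=n_expr,
                    n_obs=len(align),
                    significant=bool(q < alpha),
                )
            )
    else:
        logger.warning("no testable pairs: correlation summary is empty")
    for pair, n_expr in constants:
        results.append(
            CorrelationResult(
                pair=pair,
                rho=float("nan"),
                p_raw=float("nan"),
                p_adj=float("nan"),
                n_expressed=n_expr,
                n_obs=len(align),
                significant=False,
                constant=True,
            )
        )

    tested = [r for r in results if not r.constant]
    summary = None
    if tested:
        rhos = np.array([r.rho for r in tested])
        summary = CorrelationSummary(
            mean_rho=float(rhos.mean()),
            sd_rho=float(rhos.std(ddof=1)) if rhos.size > 1 else 0.0,
            median_rho=float(np.median(rhos)),
            n_tested=len(tested),
            n_sig_pos=sum(1 for r in tested if r.significant and r.rho > 0),
            n_sig_neg=sum(1 for r in tested if r.significant and r.rho < 0),
        )

    table = pd.DataFrame(
        [
            {
                "sense_id": r.pair.sense.gene_id,
                "antisense_id": r.pair.antisense.gene_id,
                "rho": r.rho,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "n_expressed": r.n_expressed,
                "n_obs": r.n_obs,
                "significant": r.significant,
                "constant": r.constant,
            }
            for r in results
        ],
        columns=[
            "sense_id", "antisense_id", "rho", "p_raw", "p_adj",
            "n_expressed", "n_obs", "significant", "constant",
        ],
    )
    table = table.sort_values("rho", ascending=False, na_position="last").reset_index(drop=True)
    return results, summary, table


def strand_skew(
    pairs: list[OverlapPair], expr: ExpressionMatrix
) -> tuple[float, pd.DataFrame]:
    """Antisense/sense expression skew and the density-plot export.

    Over every (pair, biological sample) cell where both the sense and the
    antisense FPKM are positive, the ratio antisense/sense is formed and its
    median returned (NaN sentinel when no doubly-expressed cell exists).
    The export holds the same cells as log10(FPKM+1) sense/antisense column
    pairs for density plotting.
    """
    align = align_strand_samples(expr)
    ratios: list[float] = []
    rows = []
    for p in pairs:
        xs = expr.values.loc[p.sense.gene_id, list(align["sense_sample"])].to_numpy(dtype=float)
        ys = expr.values.loc[p.antisense.gene_id, list(align["antisense_sample"])].to_numpy(
            dtype=float
        )
        for bio, x, y in zip(align["biosample"], xs, ys):
            rows.append(
                {
                    "sense_id": p.sense.gene_id,
                    "antisense_id": p.antisense.gene_id,
                    "biosample": bio,
                    "log10_sense": float(np.log10(x + 1.0)),
                    "log10_antisense": float(np.log10(y + 1.0)),
                }
            )
            if x > 0 and y > 0:
                ratios.append(y / x)
    density = pd.DataFrame(
        rows,
        columns=["sense_id", "antisense_id", "biosample", "log10_sense", "log10_antisense"],
    )
    skew_median = float(np.median(ratios)) if ratios else float("nan")
    return skew_median, density


def heatmap_matrix(pairs: list[OverlapPair], expr: ExpressionMatrix) -> pd.DataFrame:
    """Pair x strand-sample matrix of log10(FPKM+1) for heatmap rendering.

    Rows are pairs (indexed ``senseID|antisenseID``); columns are ordered by
    gestational stage then biological replicate, with the sense-strand value
    followed by the antisense-strand value for each replicate.
    """
    align = align_strand_samples(expr)
    columns: list[str] = []
    data: dict[str, np.ndarray] = {}
    for row in align.itertuples(index=False):
        for col, which in (
            (row.sense_sample, "sense"),
            (row.antisense_sample, "antisense"),
        ):
            label = f"{row.stage}|{row.biosample}|{which}"
            columns.append(label)
            data[label] = (col, which)
    index = [f"{p.sense.gene_id}|{p.antisense.gene_id}" for p in pairs]
    mat = pd.DataFrame(index=index, columns=columns, dtype=float)
    for p, idx in zip(pairs, index):
        for label, (col, which) in data.items():
            gene = p.sense.gene_id if which == "sense" else p.antisense.gene_id
            mat.loc[idx, label] = np.log10(float(expr.values.loc[gene, col]) + 1.0)
    mat.index.name = "pair"
    return mat
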