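"""Landscape summaries of the overlap pair set.

Covers the descriptive side of the analysis: the overlap-length
distribution, per-form overlap/gene-length ratio summaries, per-chromosome
pair counts with two normalizations (pairs per Mb of chromosome and pairs
per annotated gene), and the biotype-pair x form contingency table.

Medians use the standard convention (midpoint of the two central order
statistics for even n).  Percentages are stored at full precision; rounding
is left to presentation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AnnotationError, GeneRecord
from .overlap import FORMS, OverlapPair


def _stats(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    return {"median": float(np.median(arr)), "min": float(arr.min()), "max": float(arr.max())}


def summarize_lengths(pairs: Sequence[OverlapPair]) -> dict:
    """Overlap-length stats overall and per form, plus the 1-bp pair count.

    Returns a dict with keys ``n_pairs``, ``per_form_counts``, ``overall``
    (median/min/max bp), ``per_form`` (form -> stats, ``None`` for forms with
    no pairs) and ``n_1bp``.  An empty pair list yields an empty-summary
    sentinel (n_pairs 0, overall None) rather than an exception.
    """
    if not pairs:
        return {
            "n_pairs": 0,
            "per_form_counts": {f: 0 for f in FORMS},
            "overall": None,
            "per_form": {f: None for f in FORMS},
            "n_1bp": 0,
        }
    lengths = [p.ov_len for p in pairs]
    per_form: dict[str, dict | None] = {}
    counts: dict[str, int] = {}
    for f in FORMS:
        sub = [p.ov_len for p in pairs if p.form == f]
        counts[f] = len(sub)
        per_form[f] = _stats(sub) if sub else None
    return {
        "n_pairs": len(pairs),
        "per_form_counts": counts,
        "overall": _stats(lengths),
        "per_form": per_form,
        "n_1bp": sum(1 for l in lengths if l == 1),
    }


def summarize_ratios(pairs: Sequence[OverlapPair]) -> pd.DataFrame:
    """Overlap/gene-length percentage summary in the classic four-row layout.

    One row per form A-D plus an ``overall`` row; columns are median/min/max
    of the sense-side and antisense-side percentages.  By the embedding
    definitions, form A has the antisense column pinned at 100 and form B
    the sense column.  Forms with no pairs get NaN rows.
    """
    rows = []
    for f in FORMS:
        sub = [p for p in pairs if p.form == f]
        row: dict = {"form": f, "n": len(sub)}
        if sub:
            for side in ("sense", "antisense"):
                s = _stats([getattr(p, f"ratio_{side}") for p in sub])
                for k, v in s.items():
                    row[f"{side}_{k}"] = v
        rows.append(row)
    row: dict = {"form": "overall", "n": len(pairs)}
    if pairs:
        for side in ("sense", "antisense"):
            s = _stats([getattr(p, f"ratio_{side}") for p in pairs])
            for k, v in s.items():
                row[f"{side}_{k}"] = v
    rows.append(row)
    columns = ["form", "n"] + [
        f"{side}_{k}" for side in ("sense", "antisense") for k in ("median", "min", "max")
    ]
    return pd.DataFrame(rows, columns=columns)


def chromosome_distribution(
    pairs: Sequence[OverlapPair],
    genes: Sequence[GeneRecord],
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-chromosome pair counts with length and gene-count normalizations.

    For each chromosome carrying annotated genes: the raw pair count, pairs
    per Mb of chromosome, percent of all pairs, the annotated-gene count,
    pairs per annotated gene x 100, the count of distinct genes involved in
    pairs, and per-form counts.  Chromosomes with genes but no pairs appear
    with zeros.  Every referenced chromosome must be present in
    ``chrom_lengths``.
    """
    chroms = sorted({g.chrom for g in genes} | {p.chrom for p in pairs})
    missing = [c for c in chroms if c not in chrom_lengths]
    if missing:
        raise AnnotationError(f"chromosomes missing from length table: {missing}")
    n_total = len(pairs)
    rows = []
    for chrom in chroms:
        sub = [p for p in pairs if p.chrom == chrom]
        n_genes = sum(1 for g in genes if g.chrom == chrom)
        involved = {p.sense.gene_id for p in sub} | {p.antisense.gene_id for p in sub}
        row = {
            "chrom": chrom,
            "length_bp": chrom_lengths[chrom],
            "n_pairs": len(sub),
            "n_pairs_per_Mb": len(sub) / (chrom_lengths[chrom] / 1e6),
            "pct_of_all_pairs": 100.0 * len(sub) / n_total if n_total else 0.0,
            "n_annotated_genes": n_genes,
            "pairs_per_annotated_gene_pct": 100.0 * len(sub) / n_genes if n_genes else 0.0,
            "n_genes_in_pairs": len(involved),
        }
        for f in FORMS:
            row[f"n_{f}"] = sum(1 for p in sub if p.form == f)
        rows.append(row)
    return pd.DataFrame(rows)


def biotype_pair_table(pairs: Sequence[OverlapPair]) -> pd.DataFrame:
    """Biotype-pair x form contingency table with overall percentages.

    The biotype-pair label is unordered (strand assignment ignored).  Rows
    are sorted by total count descending; ``pct`` is the row total as a
    percentage of all pairs, so the column sums to 100.
    """
    rows: dict[str, dict] = {}
    for p in pairs:
        row = rows.setdefault(
            p.biotype_pair, {"biotype_pair": p.biotype_pair, **{f: 0 for f in FORMS}}
        )
        row[p.form] += 1
    df = pd.DataFrame(
        list(rows.values()), columns=["biotype_pair", *FORMS]
    )
    if df.empty:
        df["total"] = pd.Series(dtype=int)
        df["pct"] = pd.Series(dtype=float)
        return df
    df["total"] = df[list(FORMS)].sum(axis=1)
    df["pct"] = 100.0 * df["total"] / df["total"].sum()
    return df.sort_values(["total", "biotype_pair"], ascending=[False, True]).reset_index(
        drop=True
    )
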