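"""Detection and classification of opposite-strand overlapping gene pairs.

A sense-antisense (SAS) pair is a ``+``-strand gene and a ``-``-strand gene
on the same chromosome whose spans share at least 1 bp.  Each pair falls
into exactly one of four forms:

* **A** — the antisense gene is fully embedded in the sense gene;
* **B** — the sense gene is fully embedded in the antisense gene;
* **C** — tail-to-tail: a partial overlap covering both genes' 3' ends;
* **D** — head-to-head: a partial overlap covering both genes' 5' ends.

"Sense" here is positional: the ``+``-strand member of the pair.  Genes are
treated as single spans (annotation gene rows); exon structure is not
modeled.  No minimum overlap is applied — 1-bp overlaps are genuine pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import AnnotationError, GeneRecord

logger = logging.getLogger(__name__)

FORMS = ("A", "B", "C", "D")


class OverlapError(ValueError):
    """Invalid input to overlap classification."""


def biotype_pair_label(b1: str, b2: str) -> str:
    """Unordered biotype-pair label; mRNA listed first, otherwise alphabetical.

    Both strand assignments of the same biotype combination map to one
    label: mRNA(+)/lncRNA(-) and lncRNA(+)/mRNA(-) are both "mRNA:lncRNA".
    """
    if b1 == b2:
        return f"{b1}:{b2}"
    if "mRNA" in (b1, b2):
        other = b2 if b1 == "mRNA" else b1
        return f"mRNA:{other}"
    lo, hi = sorted((b1, b2), key=str.lower)
    return f"{lo}:{hi}"


@dataclass(frozen=True)
class OverlapPair:
    """One sense(+)/antisense(-) overlapping gene pair.

    ``ov_start``/``ov_end`` are 1-based inclusive; ``ratio_sense`` and
    ``ratio_antisense`` are the overlap length as a percentage of each
    gene's span length.
    """

    sense: GeneRecord
    antisense: GeneRecord
    chrom: str
    ov_start: int
    ov_end: int
    ov_len: int
    form: str
    ratio_sense: float
    ratio_antisense: float
    biotype_pair: str


def _check_pair_preconditions(sense: GeneRecord, antisense: GeneRecord) -> None:
    if sense.strand != "+" or antisense.strand != "-":
        raise OverlapError(
            "classification needs a '+' sense gene and a '-' antisense gene; "
            f"got {sense.strand!r} and {antisense.strand!r} "
            "(same-strand overlap is outside the sense-antisense definition)"
        )
    if sense.chrom != antisense.chrom:
        raise OverlapError(
            f"genes on different chromosomes: {sense.chrom!r} vs {antisense.chrom!r}"
        )
    if sense.start > antisense.end or antisense.start > sense.end:
        raise OverlapError(
            f"intervals do not intersect: [{sense.start},{sense.end}] vs "
            f"[{antisense.start},{antisense.end}]"
        )


def classify_overlap(sense: GeneRecord, antisense: GeneRecord) -> str:
    """Classify an intersecting (+,-) gene pair into form A, B, C or D.

    With sense span S=[s1,e1] and antisense span T=[s2,e2]:
    T inside S -> A; S inside T -> B (identical spans tie-break to A);
    otherwise the overlap is partial and contains either both 5' ends
    (s1 > s2, since the '-' gene's 5' end is its right coordinate) -> D,
    or both 3' ends (s2 > s1) -> C.
    """
    _check_pair_preconditions(sense, antisense)
    s1, e1 = sense.start, sense.end
    s2, e2 = antisense.start, antisense.end
    if s2 >= s1 and e2 <= e1:
        return "A"
    if s1 >= s2 and e1 <= e2:
        return "B"
    if s1 > s2:
        return "D"
    return "C"


def make_pair(sense: GeneRecord, antisense: GeneRecord) -> OverlapPair:
    """Build the full pair record (overlap interval, form, ratios)."""
    form = classify_overlap(sense, antisense)
    ov_start = max(sense.start, antisense.start)
    ov_end = min(sense.end, antisense.end)
    ov_len = ov_end - ov_start + 1
    return OverlapPair(
        sense=sense,
        antisense=antisense,
        chrom=sense.chrom,
        ov_start=ov_start,
        ov_end=ov_end,
        ov_len=ov_len,
        form=form,
        ratio_sense=100.0 * ov_len / sense.length,
        ratio_antisense=100.0 * ov_len / antisense.length,
        biotype_pair=biotype_pair_label(sense.biotype, antisense.biotype),
    )


def pair_metrics(pair: OverlapPair) -> tuple[int, float, float]:
    """Recompute (ov_len, ratio_sense %, ratio_antisense %) from coordinates."""
    ov_len = pair.ov_end - pair.ov_start + 1
    return (
        ov_len,
        100.0 * ov_len / pair.sense.length,
        100.0 * ov_len / pair.antisense.length,
    )


def _count_same_strand_overlaps(genes: Sequence[GeneRecord]) -> int:
    """Diagnostic count of same-strand overlapping pairs (sorted sweep)."""
    n = 0
    for strand in ("+", "-"):
        subset = sorted(
            (g for g in genes if g.strand == strand), key=lambda g: (g.chrom, g.start)
        )
        active: list[GeneRecord] = []
        last_chrom = None
        for g in subset:
            if g.chrom != last_chrom:
                active, last_chrom = [], g.chrom
            active = [a for a in active if a.end >= g.start]
            n += len(active)
            active.append(g)
    return n


def find_opposite_strand_overlaps(genes: Sequence[GeneRecord]) -> list[OverlapPair]:
    """Find every opposite-strand overlapping pair in an annotation.

    Uses a per-chromosome interval index over the '-'-strand genes queried
    with each '+'-strand gene, so a gene overlapping k opposite-strand genes
    yields k pairs.  Output is sorted by
    (chrom, ov_start, ov_end, sense_id, antisense_id).

    Same-strand overlaps are counted and logged for diagnostics but never
    paired: the method is defined on opposite strands only.
    """
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)

    same = _count_same_strand_overlaps(genes)
    if same:
        logger.info("ignoring %d same-strand overlapping pairs (diagnostic only)", same)

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.strand == "-":
            trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    pairs: list[OverlapPair] = []
    for g in genes:
        if g.strand != "+":
            continue
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(g.start, g.end + 1):
            pairs.append(make_pair(g, iv.data))
    pairs.sort(
        key=lambda p: (p.chrom, p.ov_start, p.ov_end, p.sense.gene_id, p.antisense.gene_id)
    )
    return pairs


def pairs_to_table(pairs: Iterable[OverlapPair]) -> pd.DataFrame:
    """Flatten pairs into the tabular layout used by the writers."""
    rows = [
        {
            "chrom": p.chrom,
            "sense_id": p.sense.gene_id,
            "antisense_id": p.antisense.gene_id,
            "sense_start": p.sense.start,
            "sense_end": p.sense.end,
            "antisense_start": p.antisense.start,
            "antisense_end": p.antisense.end,
            "ov_start": p.ov_start,
            "ov_end": p.ov_end,
            "ov_len": p.ov_len,
            "form": p.form,
            "ratio_sense": p.ratio_sense,
            "ratio_antisense": p.ratio_antisense,
            "biotype_pair": p.biotype_pair,
        }
        for p in pairs
    ]
    columns = [
        "chrom", "sense_id", "antisense_id", "sense_start", "sense_end",
        "antisense_start", "antisense_end", "ov_start", "ov_end", "ov_len",
        "form", "ratio_sense", "ratio_antisense", "biotype_pair",
    ]
    return pd.DataFrame(rows, columns=columns)
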