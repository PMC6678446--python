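"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: pair
detection is verified against a quadratic all-pairs scan, classification
against direct 5'/3'-containment predicates, Spearman against an explicit
mid-rank-then-Pearson computation, and Benjamini-Hochberg against the
textbook step-up recursion.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from saspairs import GeneRecord, SyntheticConfig, generate_annotation, generate_expression

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_gene(
    gene_id: str,
    start: int,
    end: int,
    strand: str,
    chrom: str = "chr1",
    biotype: str = "mRNA",
) -> GeneRecord:
    return GeneRecord(gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
                      biotype=biotype)


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_pair_set(genes) -> set[tuple[str, str]]:
    """Quadratic all-pairs scan for opposite-strand overlaps."""
    out = set()
    for g in genes:
        for h in genes:
            if (
                g.strand == "+"
                and h.strand == "-"
                and g.chrom == h.chrom
                and g.start <= h.end
                and h.start <= g.end
            ):
                out.add((g.gene_id, h.gene_id))
    return out


def oracle_classify(s1: int, e1: int, s2: int, e2: int) -> str:
    """Predicate-based form oracle for a (+)[s1,e1] / (-)[s2,e2] overlap.

    Written directly from the biological definitions: embedding by span
    containment (identical spans count as the antisense-embedded case);
    otherwise head-to-head when the shared interval contains both 5' ends
    (s1 for the '+' gene, e2 for the '-' gene), tail-to-tail when it
    contains both 3' ends (e1 and s2).
    """
    ov_lo, ov_hi = max(s1, s2), min(e1, e2)
    assert ov_lo <= ov_hi, "oracle called on non-intersecting spans"
    contains = lambda x: ov_lo <= x <= ov_hi
    if s1 <= s2 and e2 <= e1:
        return "A"
    if s2 <= s1 and e1 <= e2:
        return "B"
    if contains(s1) and contains(e2):
        return "D"
    assert contains(e1) and contains(s2)
    return "C"


def midrank_spearman(x, y) -> float:
    """Rank-then-Pearson Spearman oracle with explicit mid-ranks for ties."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def stepup_bh(p) -> np.ndarray:
    """Textbook BH step-up: q_(i) = min_{j>=i} m p_(j)/j, back to input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q[order[i]] = running
    return q


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-gene / 50-pair synthetic cohort with expression, session-shared."""
    cfg = SyntheticConfig(seed=11, n_genes=200, n_planted_pairs=50)
    genes, truth = generate_annotation(cfg)
    expr = generate_expression(genes, truth, cfg)
    return cfg, genes, truth, expr
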