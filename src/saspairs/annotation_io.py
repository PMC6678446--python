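"""Readers and writers for the formats the pipeline touches.

The pipeline consumes a gene-level GFF3 annotation, a two-column
chromosome-length table, and per-strand FPKM expression matrices with a
sample-metadata sidecar; it emits TSV result tables and a BED6 track of
overlap intervals.  Coordinates are 1-based inclusive internally (the GFF3
convention); conversion to BED's 0-based half-open intervals is isolated to
the BED writer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: Normalized biotype vocabulary.  Foreign annotations are mapped onto these
#: eight labels; anything unrecognized becomes "other" with a warning.
BIOTYPES = ("mRNA", "lncRNA", "miRNA", "tRNA", "snRNA", "miscRNA", "other")

_BIOTYPE_ALIASES = {
    "mrna": "mRNA",
    "protein_coding": "mRNA",
    "protein-coding": "mRNA",
    "lncrna": "lncRNA",
    "lnc_rna": "lncRNA",
    "lnc-rna": "lncRNA",
    "lincrna": "lncRNA",
    "mirna": "miRNA",
    "trna": "tRNA",
    "snrna": "snRNA",
    "miscrna": "miscRNA",
    "misc_rna": "miscRNA",
    "misc-rna": "miscRNA",
    "other": "other",
}

#: Gestational stages, in chronological order (45 days, 4/6/10 months).
STAGES = ("45d", "4mo", "6mo", "10mo")
STRAND_LABELS = ("sense", "antisense")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class ExpressionError(ValueError):
    """Malformed or inconsistent expression input."""


def normalize_biotype(raw: str) -> str:
    """Map an annotation's biotype string onto the normalized vocabulary."""
    key = raw.strip().lower()
    if key in _BIOTYPE_ALIASES:
        return _BIOTYPE_ALIASES[key]
    logger.warning("unknown biotype %r mapped to 'other'", raw)
    return "other"


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: a single stranded span on a chromosome.

    Coordinates are 1-based inclusive.  ``strand`` is ``+`` or ``-``;
    unstranded features are rejected before construction because the
    sense/antisense pairing is strand-defined.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "other"
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise AnnotationError(
                f"gene {self.gene_id!r}: invalid span [{self.start}, {self.end}] "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.biotype not in BIOTYPES:
            raise AnnotationError(
                f"gene {self.gene_id!r}: biotype {self.biotype!r} not in {BIOTYPES}"
            )

    @property
    def length(self) -> int:
        """Gene span length in bp (end - start + 1)."""
        return self.end - self.start + 1


def _check_unique_ids(genes: Iterable[GeneRecord]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)


def read_gff(
    path: str | Path,
    feature_type: str = "gene",
    biotype_key: str = "gene_biotype",
) -> tuple[list[GeneRecord], list[GeneRecord | str]]:
    """Read gene records from a GFF3 file.

    Parameters
    ----------
    path:
        GFF3 file; only rows whose feature column equals ``feature_type``
        are considered.
    feature_type:
        Feature column value selecting gene rows (default ``"gene"``).
    biotype_key:
        Attribute key holding the biotype (default ``"gene_biotype"``,
        fallback ``"biotype"``).

    Returns
    -------
    (records, rejected):
        ``records`` are stranded genes; ``rejected`` holds raw GFF lines for
        features of the requested type whose strand is ``.`` or ``?`` —
        reported, never silently dropped.
    """
    records: list[GeneRecord] = []
    rejected: list[str] = []
    ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise AnnotationError(f"{path}:{lineno}: malformed GFF3 line: {exc}") from exc
            if feat.featuretype != feature_type:
                continue
            try:
                start, end = int(feat.start), int(feat.end)
            except (TypeError, ValueError) as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed coordinates "
                    f"({feat.start!r}, {feat.end!r})"
                ) from exc
            if feat.strand not in ("+", "-"):
                rejected.append(line)
                continue
            attrs = feat.attributes
            gene_id = (attrs.get("ID") or attrs.get("gene_id") or [None])[0]
            if gene_id is None:
                raise AnnotationError(f"{path}:{lineno}: feature has no ID/gene_id attribute")
            if gene_id in ids:
                raise AnnotationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            ids.add(gene_id)
            raw_biotype = (attrs.get(biotype_key) or attrs.get("biotype") or ["other"])[0]
            name = (attrs.get("Name") or [""])[0]
            try:
                rec = GeneRecord(
                    gene_id=gene_id,
                    chrom=feat.seqid,
                    start=start,
                    end=end,
                    strand=feat.strand,
                    biotype=normalize_biotype(raw_biotype),
                    name=name,
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records, rejected


def write_gff(genes: Sequence[GeneRecord], path: str | Path) -> Path:
    """Write gene records as a GFF3 file (one ``gene`` row per record)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};gene_biotype={g.biotype}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write(
                f"{g.chrom}\tsaspairs\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Chromosome-length table


def read_chrom_table(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of chromosome name and length in bp."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise AnnotationError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            chrom, raw_len = fields
            try:
                length = int(raw_len)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer length {raw_len!r}") from exc
            if length <= 0:
                raise AnnotationError(f"{path}:{lineno}: non-positive length for {chrom!r}")
            if chrom in table:
                raise AnnotationError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            table[chrom] = length
    return table


def write_chrom_table(table: Mapping[str, int], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, length in table.items():
            fh.write(f"{chrom}\t{length}\n")
    return path


# ---------------------------------------------------------------------------
# Expression matrix


@dataclass
class ExpressionMatrix:
    """Gene x strand-sample FPKM matrix with per-sample metadata.

    ``values`` is a DataFrame indexed by gene_id with one column per
    strand-sample.  ``sample_meta`` is indexed by sample_id with columns
    ``stage`` (one of STAGES), ``strand_label`` (sense/antisense) and an
    optional ``biosample`` column naming the biological sample a
    strand-sample derives from.  The study design is 16 biological samples
    split into sense and antisense strands (32 strand-samples), but any
    balanced design is accepted.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float, copy=False)
        if vals.size and (not np.all(np.isfinite(vals)) or (vals < 0).any()):
            bad = np.argwhere(~np.isfinite(vals) | (vals < 0))[0]
            raise ExpressionError(
                f"non-finite or negative FPKM at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if self.values.index.duplicated().any():
            raise ExpressionError("duplicate gene_id in expression matrix")
        if self.values.columns.duplicated().any():
            raise ExpressionError("duplicate sample_id in expression matrix")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ExpressionError(f"samples missing from metadata: {missing}")
        for col in ("stage", "strand_label"):
            if col not in self.sample_meta.columns:
                raise ExpressionError(f"metadata lacks required column {col!r}")
            if self.sample_meta[col].isna().any():
                raise ExpressionError(f"metadata column {col!r} has missing entries")
        bad_stage = set(self.sample_meta["stage"]) - set(STAGES)
        if bad_stage:
            raise ExpressionError(f"unknown stage labels {sorted(bad_stage)}; allowed: {STAGES}")
        bad_strand = set(self.sample_meta["strand_label"]) - set(STRAND_LABELS)
        if bad_strand:
            raise ExpressionError(f"unknown strand labels {sorted(bad_strand)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, strand_label: str) -> list[str]:
        """Sample ids carrying the given strand label, in matrix column order."""
        meta = self.sample_meta.loc[self.values.columns]
        return list(meta.index[meta["strand_label"] == strand_label])


def read_expression(matrix_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read an FPKM matrix (TSV, first column gene_id) and its metadata sidecar."""
    # round_trip parsing keeps values bit-identical across write/read cycles
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    for col in raw.columns:
        if not np.issubdtype(raw[col].dtype, np.number):
            converted = pd.to_numeric(raw[col], errors="coerce")
            gene = raw.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ExpressionError(
                f"non-numeric FPKM at gene {gene!r}, sample {col!r} in {matrix_path}"
            )
    values = raw.astype(float)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ExpressionError(f"{meta_path}: metadata needs a sample_id column")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values=values, sample_meta=meta)


def write_expression(
    em: ExpressionMatrix, matrix_path: str | Path, meta_path: str | Path
) -> tuple[Path, Path]:
    """Write the FPKM matrix and metadata sidecar as TSV."""
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    em.values.to_csv(matrix_path, sep="\t", index_label="gene_id", lineterminator="\n")
    em.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id", lineterminator="\n")
    return matrix_path, meta_path


# ---------------------------------------------------------------------------
# Result writers


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    pair_table: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write named result tables as TSV; the pair table also as BED6.

    The BED track holds one line per pair covering the overlap interval,
    converted from 1-based inclusive to 0-based half-open (start-1, end).
    name = ``senseID|antisenseID|form``; score = overlap length capped at
    1000; strand = ``+`` (the interval itself is strandless; both strands
    transcribe it).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise OSError(f"not a writable directory: {out_dir}")
    paths: dict[str, Path] = {}
    for tname, df in tables.items():
        p = out_dir / f"{tname}.tsv"
        df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        paths[tname] = p
    if pair_table is not None:
        p = out_dir / "pairs.tsv"
        pair_table.to_csv(p, sep="\t", index=False, lineterminator="\n")
        paths["pairs"] = p
        bed = out_dir / "pairs.bed"
        with open(bed, "w") as fh:
            for row in pair_table.itertuples(index=False):
                name = f"{row.sense_id}|{row.antisense_id}|{row.form}"
                score = min(int(row.ov_len), 1000)
                fh.write(
                    f"{row.chrom}\t{row.ov_start - 1}\t{row.ov_end}\t{name}\t{score}\t+\n"
                )
        paths["pairs_bed"] = bed
    return paths


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED6 overlap intervals back as 1-based inclusive tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, start, end, name = line.split("\t")[:4]
            out.append((chrom, int(start) + 1, int(end), name))
    return out
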