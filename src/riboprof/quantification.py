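"""Gene-level read counting with intersection-nonempty semantics.

For each read, every aligned base is annotated with the set of gene ids
whose features of the requested type cover it.  Empty per-base sets are
discarded, the remaining sets are intersected, and the read is counted for
the single gene left in the intersection — or tallied as ``no_feature``
(all bases uncovered) or ``ambiguous`` (more than one gene survives).
Sets contain gene ids, not transcript ids, so a read overlapping several
isoforms of one gene still counts once for that gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import GenomeAnnotation

FEATURE_TYPES = ("CDS", "exon", "five_prime_utr", "three_prime_utr")

SPECIAL_ROWS = ("__no_feature", "__ambiguous", "__too_low_qual")


def _feature_index(
    annotation: GenomeAnnotation, feature_type: str
) -> dict[str, IntervalTree]:
    if feature_type not in FEATURE_TYPES:
        raise ValueError(
            f"unknown feature_type '{feature_type}'; "
            f"available: {', '.join(FEATURE_TYPES)}"
        )
    trees: dict[str, IntervalTree] = {}
    for rec in (r for r in annotation.records if r.feature == feature_type):
        s, e = rec.interval
        trees.setdefault(rec.seqname, IntervalTree()).addi(
            s, e, (rec.gene_id, rec.strand)
        )
    return trees


def _read_gene_set(
    aln, tree: IntervalTree | None, stranded: str
) -> set[str] | None:
    """Intersection-nonempty gene set for one read; None means no_feature."""
    result: set[str] | None = None
    any_base = False
    for bs, be in aln.blocks:
        hits = tree.overlap(bs, be) if tree is not None else ()
        usable = []
        for iv in hits:
            gene, strand = iv.data
            if stranded == "yes" and strand != aln.strand:
                continue
            if stranded == "reverse" and strand == aln.strand:
                continue
            usable.append(iv)
        for pos in range(bs, be):
            base_set = {
                iv.data[0] for iv in usable if iv.begin <= pos < iv.end
            }
            if not base_set:
                continue
            any_base = True
            result = base_set if result is None else (result & base_set)
    if not any_base:
        return None
    return result


@dataclass
class CountColumn:
    sample: str
    counts: dict[str, int]
    no_feature: int = 0
    ambiguous: int = 0
    too_low_qual: int = 0
    reads_processed: int = 0


def count_reads(
    alignments,
    annotation: GenomeAnnotation,
    feature_type: str = "CDS",
    stranded: str = "no",
    mapq_min: int = 0,
    sample: str = "sample",
) -> CountColumn:
    """Count primary alignments per gene under intersection-nonempty."""
    trees = _feature_index(annotation, feature_type)
    col = CountColumn(sample=sample, counts={})
    for aln in alignments:
        if aln.is_secondary or aln.is_supplementary:
            continue
        col.reads_processed += 1
        if mapq_min > 0 and aln.mapq < mapq_min:
            col.too_low_qual += 1
            continue
        genes = _read_gene_set(aln, trees.get(aln.chrom), stranded)
        if genes is None or len(genes) == 0:
            col.no_feature += 1
        elif len(genes) == 1:
            gene = next(iter(genes))
            col.counts[gene] = col.counts.get(gene, 0) + 1
        else:
            col.ambiguous += 1
    return col


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def feature_lengths(
    annotation: GenomeAnnotation, feature_type: str = "CDS"
) -> pd.Series:
    """Per-gene union length (nt) of ``feature_type`` intervals.

    Overlapping isoform features are collapsed, so the length is the union
    across isoforms, not the sum.
    """
    per_gene: dict[str, list[tuple[int, int]]] = {}
    for rec in (r for r in annotation.records if r.feature == feature_type):
        per_gene.setdefault(rec.gene_id, []).append(rec.interval)
    genes = [g for g in annotation.genes if g in per_gene]
    return pd.Series(
        {g: _union_length(per_gene[g]) for g in genes}, name="length",
        dtype=np.int64,
    )


@dataclass
class CountMatrix:
    """Genes x samples integer counts with HTSeq-style special counters."""

    counts: pd.DataFrame  # genes x samples, int
    feature_lengths: pd.Series  # per-gene nt
    specials: pd.DataFrame  # SPECIAL_ROWS x samples
    feature_type: str = "CDS"

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def reads_processed(self, sample: str) -> int:
        return int(self.counts[sample].sum() + self.specials[sample].sum())

    def to_tsv(self, path) -> None:
        table = pd.concat([self.counts, self.specials])
        table.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, lengths: pd.Series | None = None) -> "CountMatrix":
        table = pd.read_csv(path, sep="\t", index_col=0)
        is_special = table.index.str.startswith("__")
        counts = table.loc[~is_special].astype(np.int64)
        specials = table.loc[is_special].astype(np.int64)
        specials = specials.reindex(list(SPECIAL_ROWS), fill_value=0)
        if lengths is None:
            lengths = pd.Series(0, index=counts.index, name="length")
        return cls(counts, lengths.reindex(counts.index), specials)


def assemble_matrix(
    columns: list[CountColumn],
    annotation: GenomeAnnotation,
    feature_type: str = "CDS",
) -> CountMatrix:
    """Stack per-sample count columns into a matrix in annotation gene order."""
    lengths = feature_lengths(annotation, feature_type)
    genes = list(lengths.index)
    known = set(genes)
    for col in columns:
        stray = set(col.counts) - known
        if stray:
            raise ValueError(
                f"sample {col.sample}: counts for genes absent from the "
                f"annotation's {feature_type} features: {sorted(stray)[:10]}"
            )
    counts = pd.DataFrame(
        {
            col.sample: [col.counts.get(g, 0) for g in genes]
            for col in columns
        },
        index=genes,
        dtype=np.int64,
    )
    specials = pd.DataFrame(
        {
            col.sample: [col.no_feature, col.ambiguous, col.too_low_qual]
            for col in columns
        },
        index=list(SPECIAL_ROWS),
        dtype=np.int64,
    )
    return CountMatrix(counts, lengths, specials, feature_type)
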