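"""PCR-duplicate marking and the duplication-vs-expression QC summary.

Reads sharing (chromosome, strand, 5'-most aligned position, aligned
length, and UMI when available) are treated as one PCR duplicate group;
the highest-MAPQ member (ties broken by read id) is the representative and
the rest are flagged.  The per-gene table of duplication rate against
expression lets a user spot libraries whose apparent depth is mostly
re-amplification of few molecules.  Duplicates are *flagged*, not removed:
duplicate-aware quantification is usually overly stringent for footprint
libraries, where distinct molecules legitimately share coordinates.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .alignment_model import AlignmentRecord
from .annotation_io import GenomeAnnotation
from .quantification import _feature_index, _read_gene_set, feature_lengths


def duplicate_key(aln: AlignmentRecord, use_umi: bool):
    key = (aln.chrom, aln.strand, aln.five_prime_genomic(), aln.read_length)
    if use_umi:
        key += (aln.umi,)
    return key


def mark_duplicates(
    alignments: list[AlignmentRecord], use_umi: bool = False
) -> list[AlignmentRecord]:
    """Return records with ``is_duplicate`` set on non-representatives."""
    groups: dict[tuple, list[int]] = {}
    for i, aln in enumerate(alignments):
        groups.setdefault(duplicate_key(aln, use_umi), []).append(i)
    flagged = list(alignments)
    for members in groups.values():
        if len(members) == 1:
            flagged[members[0]] = replace(flagged[members[0]],
                                          is_duplicate=False)
            continue
        rep = min(members, key=lambda i: (-alignments[i].mapq,
                                          alignments[i].read_id))
        for i in members:
            flagged[i] = replace(alignments[i], is_duplicate=(i != rep))
    return flagged


def complexity_profile(
    alignments: list[AlignmentRecord],
    annotation: GenomeAnnotation,
    feature_type: str = "exon",
    stranded: str = "no",
) -> pd.DataFrame:
    """Per-gene duplication rate and expression from duplicate-marked reads.

    Columns: reads_total, reads_unique, duplication_rate (1 - unique/total)
    and expression (reads per kb of feature length).  Genes with zero
    assigned reads are excluded.
    """
    trees = _feature_index(annotation, feature_type)
    lengths = feature_lengths(annotation, feature_type)
    totals: dict[str, int] = {}
    uniques: dict[str, int] = {}
    for aln in alignments:
        genes = _read_gene_set(aln, trees.get(aln.chrom), stranded)
        if genes is None or len(genes) != 1:
            continue
        gene = next(iter(genes))
        totals[gene] = totals.get(gene, 0) + 1
        if not aln.is_duplicate:
            uniques[gene] = uniques.get(gene, 0) + 1
    rows = []
    for gene, total in sorted(totals.items()):
        unique = uniques.get(gene, 0)
        length = int(lengths.get(gene, 0))
        rows.append(
            {
                "gene": gene,
                "reads_total": total,
                "reads_unique": unique,
                "duplication_rate": 1.0 - unique / total,
                "expression": total / (length / 1000.0) if length else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "reads_total", "reads_unique",
                 "duplication_rate", "expression"],
    ).set_index("gene") if rows else pd.DataFrame(
        columns=["reads_total", "reads_unique", "duplication_rate",
                 "expression"]
    )
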