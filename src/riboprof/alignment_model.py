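"""SAM alignments as block lists, and genomic coverage extraction.

CIGAR conventions: M/=/X and D consume reference and are counted as
covered (a deletion is bridged by the read); N splits aligned blocks
(introns are not covered); I and S consume query only.  ``read_length`` is
the aligned query length, i.e. soft clips excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam

logger = logging.getLogger(__name__)

# cigar op codes: M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_REF_COVERED = {0, 2, 7, 8}
_QUERY_OPS = {0, 1, 4, 7, 8}


@dataclass
class AlignmentRecord:
    """One aligned read reduced to what the profile modules need."""

    read_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    read_length: int
    mapq: int = 0
    umi: str | None = None
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def five_prime_genomic(self) -> int:
        """Genomic position of the read's 5' end (strand-aware)."""
        if self.strand == "+":
            return self.blocks[0][0]
        return self.blocks[-1][1] - 1


def blocks_from_cigar(pos: int, cigartuples) -> list[tuple[int, int]]:
    """Walk a CIGAR from 0-based ``pos`` into covered genomic blocks."""
    blocks: list[tuple[int, int]] = []
    cursor = pos
    block_start = None
    for op, length in cigartuples:
        if op in _REF_COVERED:
            if block_start is None:
                block_start = cursor
            cursor += length
        elif op == 3:  # N: close the current block, jump the intron
            if block_start is not None:
                blocks.append((block_start, cursor))
                block_start = None
            cursor += length
    if block_start is not None:
        blocks.append((block_start, cursor))
    return blocks


def _umi_from_name(name: str) -> str | None:
    if "_" not in name:
        return None
    return name.rsplit("_", 1)[1] or None


@dataclass
class SamParseStats:
    yielded: int = 0
    filtered: int = 0
    malformed: int = 0
    malformed_reads: list[str] = field(default_factory=list)


_CIGAR_TOKEN = __import__("re").compile(r"(\d+)([MIDNSHP=X])")


def _prefilter_sam_text(path, stats: SamParseStats | None):
    """Drop text-SAM lines whose CIGAR/SEQ lengths disagree.

    htslib aborts the whole file on such lines; filtering first preserves
    the per-record skip-and-count contract.
    """
    import tempfile

    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".sam", delete=False
    )
    with open(path) as fh, tmp:
        for line in fh:
            if not line.startswith("@"):
                fields = line.rstrip("\n").split("\t")
                if len(fields) >= 10 and fields[5] != "*" and fields[9] != "*":
                    qlen = sum(
                        int(n)
                        for n, op in _CIGAR_TOKEN.findall(fields[5])
                        if op in "MIS=X"
                    )
                    if qlen != len(fields[9]):
                        logger.warning(
                            "read %s: CIGAR/sequence length mismatch, skipped",
                            fields[0],
                        )
                        if stats:
                            stats.malformed += 1
                            stats.malformed_reads.append(fields[0])
                        continue
            tmp.write(line)
    return tmp.name


def parse_sam(
    path,
    include_filtered: bool = False,
    mapq_min: int = 0,
    parse_umi: bool = False,
    stats: SamParseStats | None = None,
):
    """Stream :class:`AlignmentRecord` from a SAM (or BAM) file.

    Unmapped, secondary, and supplementary records are excluded unless
    ``include_filtered`` is set.  Records whose CIGAR query length
    disagrees with the stored sequence are skipped and counted.
    """
    import os

    source = str(path)
    cleanup = None
    if source.endswith(".sam"):
        source = cleanup = _prefilter_sam_text(path, stats)
    try:
        yield from _iter_alignments(
            source, include_filtered, mapq_min, parse_umi, stats
        )
    finally:
        if cleanup:
            os.unlink(cleanup)


def _iter_alignments(path, include_filtered, mapq_min, parse_umi, stats):
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                if stats:
                    stats.filtered += 1
                continue
            if (aln.is_secondary or aln.is_supplementary) and not include_filtered:
                if stats:
                    stats.filtered += 1
                continue
            if aln.mapping_quality < mapq_min:
                if stats:
                    stats.filtered += 1
                continue
            cig = aln.cigartuples or []
            query_len = sum(n for op, n in cig if op in _QUERY_OPS)
            seq = aln.query_sequence
            if seq is not None and query_len != len(seq):
                logger.warning(
                    "read %s: CIGAR/sequence length mismatch, skipped",
                    aln.query_name,
                )
                if stats:
                    stats.malformed += 1
                    stats.malformed_reads.append(aln.query_name)
                continue
            blocks = blocks_from_cigar(aln.reference_start, cig)
            if not blocks:
                if stats:
                    stats.malformed += 1
                continue
            aligned_len = sum(n for op, n in cig if op in {0, 1, 7, 8})
            rec = AlignmentRecord(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                strand="-" if aln.is_reverse else "+",
                blocks=blocks,
                read_length=aligned_len,
                mapq=aln.mapping_quality,
                umi=_umi_from_name(aln.query_name) if parse_umi else None,
                is_secondary=aln.is_secondary,
                is_supplementary=aln.is_supplementary,
                is_duplicate=aln.is_duplicate,
            )
            if stats:
                stats.yielded += 1
            yield rec


@dataclass
class CoverageTrack:
    """Per-position read counts over genomic or collapsed exon space."""

    space: str  # "genomic" | "exonic"
    reference: str
    start: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def genomic_coverage(
    alignments, chrom: str, interval: tuple[int, int]
) -> CoverageTrack:
    """Per-base block coverage of ``interval`` (0-based half-open)."""
    start, end = interval
    if end <= start:
        raise ValueError(f"empty interval [{start},{end})")
    counts = np.zeros(end - start, dtype=np.int64)
    for aln in alignments:
        if aln.chrom != chrom:
            continue
        for bs, be in aln.blocks:
            lo, hi = max(bs, start), min(be, end)
            if lo < hi:
                counts[lo - start : hi - start] += 1
    return CoverageTrack("genomic", chrom, start, counts)


def write_sam(records, sq_lengths: dict[str, int], path) -> None:
    """Write AlignmentRecords to a coordinate-sorted text SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in sq_lengths.items()],
    }
    order = {name: i for i, name in enumerate(sq_lengths)}
    records = sorted(records, key=lambda r: (order[r.chrom], r.start))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            a.reference_name = rec.chrom
            a.reference_start = rec.start
            a.mapping_quality = rec.mapq
            a.flag = 16 if rec.strand == "-" else 0
            cig = []
            prev_end = None
            for bs, be in rec.blocks:
                if prev_end is not None:
                    cig.append((3, bs - prev_end))
                cig.append((0, be - bs))
                prev_end = be
            a.cigartuples = cig
            fh.write(a)
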