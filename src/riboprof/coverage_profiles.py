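"""Metagene, intron-collapsed gene coverage, and codon-phasing profiles.

All three profiles work in *exon space*: introns are collapsed so that a
transcript of exonic length L occupies positions 0..L-1 with 0 at its 5'
end.  The metagene profile normalizes each transcript's positional signal
to sum to one before averaging, so highly expressed transcripts carry no
extra weight ("super-expressor" damping).  Codon phasing estimates the
per-read-length P-site offset from footprints near annotated start codons
and reports the reading-frame distribution of inferred P-sites.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .alignment_model import AlignmentRecord, CoverageTrack
from .annotation_io import GenomeAnnotation, TranscriptModel

logger = logging.getLogger(__name__)


@dataclass
class ExonCoordinateMap:
    """Bijection between genomic positions and exon-space positions.

    Exon-space position 0 is the transcript's 5' end: the lowest genomic
    exonic coordinate on the + strand, the highest on the - strand.
    """

    transcript_id: str
    strand: str
    genomic: np.ndarray  # genomic position of each exon-space position

    def __post_init__(self):
        self._to_exonic = {int(g): i for i, g in enumerate(self.genomic)}

    @property
    def length(self) -> int:
        return len(self.genomic)

    def exonic_to_genomic(self, i: int) -> int:
        return int(self.genomic[i])

    def genomic_to_exonic(self, g: int) -> int | None:
        return self._to_exonic.get(g)


def build_exon_map(model: TranscriptModel) -> ExonCoordinateMap:
    if not model.exons:
        raise ValueError(f"{model.transcript_id}: no exons")
    positions = np.concatenate(
        [np.arange(s, e) for s, e in model.exons]
    )
    if model.strand == "-":
        positions = positions[::-1]
    return ExonCoordinateMap(model.transcript_id, model.strand, positions)


def _cds_exonic_bounds(
    model: TranscriptModel, emap: ExonCoordinateMap
) -> tuple[int, int] | None:
    """CDS [start, end) in exon-space coordinates, or None without CDS."""
    if not model.cds_segments:
        return None
    exonic = [
        emap.genomic_to_exonic(g)
        for s, e in model.cds_segments
        for g in (s, e - 1)
    ]
    exonic = [x for x in exonic if x is not None]
    return (min(exonic), max(exonic) + 1)


def gene_coverage(
    alignments, model: TranscriptModel
) -> tuple[CoverageTrack, dict]:
    """Per-base coverage over collapsed exon space, plus feature marks.

    Feature marks (exon-space coordinates of the CDS start/end) let a
    caller draw the CDS box under the profile and spot 5' UTR footprint
    clusters, e.g. translated uORFs.
    """
    emap = build_exon_map(model)
    counts = np.zeros(emap.length, dtype=np.int64)
    for aln in alignments:
        if aln.chrom != model.chrom:
            continue
        for bs, be in aln.blocks:
            for g in range(bs, be):
                i = emap.genomic_to_exonic(g)
                if i is not None:
                    counts[i] += 1
    features: dict = {"exonic_length": emap.length}
    bounds = _cds_exonic_bounds(model, emap)
    if bounds:
        features["cds_start"] = bounds[0]
        features["cds_end"] = bounds[1]
    track = CoverageTrack("exonic", model.transcript_id, 0, counts)
    return track, features


@dataclass
class MetageneProfile:
    """Equal-weight average of per-transcript normalized coverage."""

    bins: np.ndarray
    n_transcripts: int
    n_excluded: int = 0
    label: str | None = None


def read_five_prime_exonic(
    aln: AlignmentRecord, emap: ExonCoordinateMap
) -> int | None:
    """The read's 5'-most position that lies in the transcript's exons."""
    positions = [
        i
        for bs, be in aln.blocks
        for g in range(bs, be)
        if (i := emap.genomic_to_exonic(g)) is not None
    ]
    if not positions:
        return None
    return min(positions)


def _reads_by_chrom(alignments) -> dict[str, list[AlignmentRecord]]:
    by_chrom: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for aln in alignments:
        by_chrom[aln.chrom].append(aln)
    return by_chrom


def metagene(
    alignments,
    annotation: GenomeAnnotation,
    bins: int = 100,
    cds_only: bool = False,
    min_coverage: int = 10,
) -> MetageneProfile:
    """Aggregate per-transcript 5'-end positional signal into meta-bins.

    Each read contributes its 5'-most exonic position; a transcript's
    positional counts are binned into ``bins`` equal-width bins over its
    (CDS or exonic) length, normalized to sum to 1, and averaged with
    equal weight over transcripts with at least ``min_coverage`` reads.
    """
    by_chrom = _reads_by_chrom(alignments)
    acc = np.zeros(bins, dtype=float)
    n_used = 0
    n_excluded = 0
    for model in annotation.transcripts.values():
        emap = build_exon_map(model)
        lo, hi = 0, emap.length
        if cds_only:
            bounds = _cds_exonic_bounds(model, emap)
            if bounds is None:
                continue
            lo, hi = bounds
        span = hi - lo
        if span <= 0:
            continue
        counts = np.zeros(bins, dtype=float)
        n_reads = 0
        for aln in by_chrom.get(model.chrom, ()):
            pos = read_five_prime_exonic(aln, emap)
            if pos is None or not (lo <= pos < hi):
                continue
            counts[int(bins * (pos - lo) / span)] += 1
            n_reads += 1
        if n_reads < min_coverage:
            if n_reads > 0:
                n_excluded += 1
            continue
        acc += counts / counts.sum()
        n_used += 1
    if n_used == 0:
        logger.warning("metagene: no transcript passed min_coverage=%d",
                       min_coverage)
        return MetageneProfile(np.zeros(bins), 0, n_excluded)
    return MetageneProfile(acc / n_used, n_used, n_excluded)


@dataclass
class PhasingProfile:
    """P-site frame distribution and start-relative P-site histogram."""

    frame_counts: np.ndarray  # counts for frames 0,1,2 within CDS
    start_relative_histogram: dict[int, int]  # offset -50..+150
    offsets: dict[int, int]  # read length -> applied P-site offset
    n_reads_used: int = 0
    fallback_used: bool = False

    @property
    def frame_fractions(self) -> np.ndarray:
        total = self.frame_counts.sum()
        return self.frame_counts / total if total else self.frame_counts


HIST_WINDOW = (-50, 150)


def phasing(
    alignments,
    annotation: GenomeAnnotation,
    offset_mode: str = "auto",
    fixed_offset: int = 16,
) -> PhasingProfile:
    """Estimate P-site offsets and codon phasing from footprint 5' ends.

    In ``auto`` mode the offset for each read length is the modal distance
    between footprint 5' ends and annotated start codons, taken over reads
    whose 5' end falls within 50 nt upstream of a start.  P-site =
    5' end + offset in transcript orientation; the frame is relative to
    the CDS start in coding space.
    """
    if offset_mode not in ("auto", "fixed"):
        raise ValueError(f"unknown offset_mode: {offset_mode}")
    by_chrom = _reads_by_chrom(alignments)
    # (read length, 5'-end position relative to CDS start, CDS length)
    rel_positions: list[tuple[int, int, int]] = []
    for model in annotation.transcripts.values():
        if not model.cds_segments:
            continue
        emap = build_exon_map(model)
        bounds = _cds_exonic_bounds(model, emap)
        if bounds is None:
            continue
        cds_start, cds_end = bounds
        for aln in by_chrom.get(model.chrom, ()):
            pos = read_five_prime_exonic(aln, emap)
            if pos is None:
                continue
            rel_positions.append(
                (aln.read_length, pos - cds_start, cds_end - cds_start)
            )

    offsets: dict[int, int] = {}
    fallback = False
    default_offset = fixed_offset
    if offset_mode == "auto":
        near_start: dict[int, Counter] = defaultdict(Counter)
        pooled: Counter = Counter()
        for length, rel, _ in rel_positions:
            if -50 <= rel <= 0:
                near_start[length][-rel] += 1
                pooled[-rel] += 1
        if not near_start:
            logger.warning(
                "phasing: no reads near start codons; using fixed offset %d",
                fixed_offset,
            )
            fallback = True
        else:
            for length, counter in near_start.items():
                # modal distance; deterministic tie-break on smaller offset
                best = max(sorted(counter), key=lambda d: counter[d])
                offsets[length] = best
            # lengths without start-proximal reads inherit the pooled mode
            default_offset = max(sorted(pooled), key=lambda d: pooled[d])
    if offset_mode == "fixed" or fallback:
        offsets = defaultdict(lambda: fixed_offset)

    frame_counts = np.zeros(3, dtype=np.int64)
    histogram: dict[int, int] = {}
    n_used = 0
    for length, rel, cds_len in rel_positions:
        offset = (
            offsets[length]
            if isinstance(offsets, defaultdict) or length in offsets
            else default_offset
        )
        psite = rel + offset  # relative to CDS start in coding space
        if HIST_WINDOW[0] <= psite <= HIST_WINDOW[1]:
            histogram[psite] = histogram.get(psite, 0) + 1
        if 0 <= psite < cds_len:
            frame_counts[psite % 3] += 1
            n_used += 1
    applied = dict(offsets) if not isinstance(offsets, defaultdict) else {}
    return PhasingProfile(
        frame_counts=frame_counts,
        start_relative_histogram=dict(sorted(histogram.items())),
        offsets=applied,
        n_reads_used=n_used,
        fallback_used=fallback,
    )
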