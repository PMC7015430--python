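"""Reference curation: CDS truncation, coding masking, canonical selection.

Ribosome footprints pile up at the ends of coding regions because
initiation and termination are slow relative to elongation; quantifying
over those bases inflates translation-efficiency noise.  The curation step
therefore removes a fixed amount of coding sequence from each end of every
transcript's CDS — by convention 45 nt from the 5' end and 15 nt from the
3' end — *in coding space*: because the CDS is split across exons, trimming
recurses across CDS segments, deleting whole terminal segments when they
are shorter than the amount left to trim.

Exon and UTR records are not modified: truncation redefines quantification
space, not the transcript structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .annotation_io import (
    GenomeAnnotation,
    GtfRecord,
    TranscriptModel,
    parse_gtf,
    write_gtf,
)

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass(frozen=True)
class TruncationSpec:
    """How much coding sequence to remove from each end.

    trim5/trim3 are in nucleotides of coding space, oriented with the
    transcript (5' = lowest genomic coordinate on +, highest on -).
    Transcripts whose CDS would be left shorter than ``min_remaining``
    (one codon by default) are skipped and flagged instead of truncated.
    """

    trim5: int = 45
    trim3: int = 15
    min_remaining: int = 3

    def __post_init__(self):
        if self.trim5 < 0 or self.trim3 < 0:
            raise ValueError("trim amounts must be non-negative")
        if self.min_remaining < 3 or self.min_remaining % 3:
            raise ValueError("min_remaining must be >= 3 and divisible by 3")


def _trim_left(segments: list[Interval], n: int) -> list[Interval]:
    """Remove the first ``n`` bases in ascending genomic order."""
    out: list[Interval] = []
    remaining = n
    for s, e in segments:
        length = e - s
        if remaining >= length:
            remaining -= length
            continue
        out.append((s + remaining, e))
        remaining = 0
    return out


def _trim_right(segments: list[Interval], n: int) -> list[Interval]:
    """Remove the last ``n`` bases in ascending genomic order."""
    out: list[Interval] = []
    remaining = n
    for s, e in reversed(segments):
        length = e - s
        if remaining >= length:
            remaining -= length
            continue
        out.append((s, e - remaining))
        remaining = 0
    out.reverse()
    return out


def truncate_segments(
    segments: list[Interval], strand: str, trim5: int, trim3: int
) -> list[Interval]:
    """Interval-arithmetic truncation of CDS segments in coding orientation."""
    if strand == "+":
        return _trim_right(_trim_left(segments, trim5), trim3)
    return _trim_left(_trim_right(segments, trim5), trim3)


def _recompute_frames(records: list[GtfRecord], strand: str, first_frame: int):
    """Assign Ensembl frames along CDS records in coding order."""
    cds = [r for r in records if r.feature == "CDS"]
    cds.sort(key=lambda r: r.start, reverse=(strand == "-"))
    frame = first_frame
    for rec in cds:
        rec.frame = str(frame)
        seg_len = rec.end - rec.start + 1
        frame = (3 - ((seg_len - frame) % 3)) % 3


def truncate_cds(
    model: TranscriptModel, spec: TruncationSpec = TruncationSpec()
) -> TranscriptModel:
    """Truncate a transcript's CDS per ``spec``; exons are untouched.

    Returns a new model.  If there is no CDS, or the CDS is too short to
    leave ``min_remaining`` coding nucleotides, the model is returned
    unmodified apart from a flag.
    """
    if not model.cds_segments:
        out = replace(model, flags=set(model.flags) | {"no_cds"})
        logger.warning("%s: no CDS, truncation is a no-op", model.transcript_id)
        return out
    total = model.cds_length
    if total <= spec.trim5 + spec.trim3 + spec.min_remaining:
        return replace(model, flags=set(model.flags) | {"truncation_skipped"})

    new_segments = truncate_segments(
        model.cds_segments, model.strand, spec.trim5, spec.trim3
    )
    covered: list[Interval] = new_segments

    def overlap(iv: Interval) -> Interval | None:
        s, e = iv
        for cs, ce in covered:
            lo, hi = max(s, cs), min(e, ce)
            if lo < hi:
                return (lo, hi)
        return None

    new_records: list[GtfRecord] = []
    for rec in model.source_records:
        if rec.feature == "CDS":
            piece = overlap(rec.interval)
            if piece is None:
                continue
            new = rec.copy()
            new.start, new.end = piece[0] + 1, piece[1]
            new_records.append(new)
        elif rec.feature == "start_codon" and spec.trim5 >= 3:
            continue
        else:
            new_records.append(rec.copy())

    first_frame = (3 - (spec.trim5 % 3)) % 3
    _recompute_frames(new_records, model.strand, first_frame)

    return replace(
        model,
        cds_segments=new_segments,
        source_records=new_records,
        flags=set(model.flags) | {"truncated"},
    )


def filter_protein_coding(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Retain only protein-coding gene records (masks rRNA and friends)."""

    def is_coding(rec: GtfRecord) -> bool:
        biotype = (
            rec.attributes.get("transcript_biotype")
            or rec.attributes.get("gene_biotype")
        )
        return biotype == "protein_coding"

    kept = [r for r in annotation.records if is_coding(r)]
    removed = len(annotation.records) - len(kept)
    logger.info("protein-coding filter removed %d records", removed)
    out = GenomeAnnotation.from_records(kept, annotation.header_lines)
    if not out.genes:
        logger.warning("no protein-coding genes remain after filtering")
    return out


def _canonical_sort_key(model: TranscriptModel):
    return (
        0 if model.canonical_tag else 1,
        -model.cds_length,
        -model.exonic_length,
        model.transcript_id,
    )


def select_canonical(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Keep one transcript per gene.

    Preference order: the ``Ensembl_canonical`` tag, then longest CDS,
    longest exonic length, and finally lexicographically smallest
    transcript id, so the choice is deterministic even on untagged input.
    """
    keep_tids: set[str] = set()
    for tids in annotation.genes.values():
        models = [annotation.transcripts[t] for t in tids]
        if not models:
            continue
        keep_tids.add(min(models, key=_canonical_sort_key).transcript_id)
    kept = [
        r
        for r in annotation.records
        if r.transcript_id is None or r.transcript_id in keep_tids
    ]
    return GenomeAnnotation.from_records(kept, annotation.header_lines)


def truncate_annotation(
    annotation: GenomeAnnotation, spec: TruncationSpec = TruncationSpec()
) -> tuple[GenomeAnnotation, dict]:
    """Apply :func:`truncate_cds` to every transcript; rebuild the records.

    Record order of the input is preserved; replacement CDS records take
    the position of the record they were derived from.
    """
    replacement: dict[int, list[GtfRecord]] = {}
    skipped, truncated = [], []
    for tid, model in annotation.transcripts.items():
        new_model = truncate_cds(model, spec)
        if "truncated" not in new_model.flags:
            if "truncation_skipped" in new_model.flags:
                skipped.append(tid)
            continue
        truncated.append(tid)
        old_by_pos = {}
        for old in model.source_records:
            replacement[id(old)] = []
            old_by_pos[(old.feature, old.start)] = old
        # Re-attach each rewritten record to its originating source record.
        for new in new_model.source_records:
            origin = None
            if new.feature == "CDS":
                for old in model.source_records:
                    if old.feature == "CDS" and (
                        old.start <= new.start and new.end <= old.end
                    ):
                        origin = old
                        break
            else:
                origin = old_by_pos.get((new.feature, new.start))
            if origin is not None:
                replacement[id(origin)].append(new)
    new_records: list[GtfRecord] = []
    for rec in annotation.records:
        if id(rec) in replacement:
            new_records.extend(replacement[id(rec)])
        else:
            new_records.append(rec)
    out = GenomeAnnotation.from_records(new_records, annotation.header_lines)
    report = {"truncated": truncated, "skipped": skipped}
    return out, report


@dataclass
class CurationReport:
    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, records_in: int, records_out: int, **extra):
        self.steps.append(
            {"step": name, "records_in": records_in,
             "records_out": records_out, **extra}
        )

    def serialize(self) -> str:
        lines = ["# reference curation report"]
        for s in self.steps:
            extras = {
                k: v for k, v in s.items()
                if k not in ("step", "records_in", "records_out")
            }
            lines.append(
                f"{s['step']}: {s['records_in']} -> {s['records_out']} records"
                + (f" {extras}" if extras else "")
            )
        return "\n".join(lines) + "\n"


def curate_reference(
    gtf_in,
    gtf_out,
    spec: TruncationSpec = TruncationSpec(),
    protein_coding: bool = True,
    canonical: bool = False,
    truncate: bool = True,
) -> CurationReport:
    """Run the full curation pipeline: mask, select, truncate, write."""
    annotation = parse_gtf(gtf_in)
    report = CurationReport()
    if protein_coding:
        n_in = len(annotation.records)
        annotation = filter_protein_coding(annotation)
        report.add("protein_coding", n_in, len(annotation.records))
    if canonical:
        n_in = len(annotation.records)
        annotation = select_canonical(annotation)
        report.add("canonical", n_in, len(annotation.records))
    if truncate:
        n_in = len(annotation.records)
        annotation, trunc_report = truncate_annotation(annotation, spec)
        report.add(
            "truncate", n_in, len(annotation.records),
            n_truncated=len(trunc_report["truncated"]),
            n_skipped=len(trunc_report["skipped"]),
            skipped=sorted(trunc_report["skipped"]),
        )
    write_gtf(annotation, gtf_out)
    return report
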