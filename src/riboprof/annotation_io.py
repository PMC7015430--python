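"""GTF and FASTA input/output and the annotation object model.

Coordinate conventions
----------------------
GTF files are 1-based with inclusive ends.  ``GtfRecord`` stores the file
coordinates verbatim so that writing reproduces the input byte for byte.
Everything assembled from records (``TranscriptModel`` exons and CDS
segments) uses 0-based half-open intervals; the conversion happens here, at
the I/O boundary, and nowhere else.

The attribute column follows the Ensembl dialect (``key "value"; ``).
Duplicate keys (e.g. multiple ``tag`` entries) are preserved in order, as is
per-key quoting, so a parse/serialize round trip is the identity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

GTF_FEATURES = {
    "gene",
    "transcript",
    "exon",
    "CDS",
    "five_prime_utr",
    "three_prime_utr",
    "start_codon",
    "stop_codon",
}

_ATTR_RE = re.compile(r'\s*(\S+)\s+(?:"([^"]*)"|([^;]+?))\s*;')


class GtfValidationError(ValueError):
    """Raised when a GTF line violates the format contract."""


class Attributes:
    """Ordered multi-map for the GTF attribute column.

    Ensembl GTFs repeat keys (``tag "basic"; tag "Ensembl_canonical";``),
    so a plain dict is not enough.  Items are ``(key, value, quoted)``.
    """

    __slots__ = ("items",)

    def __init__(self, items=None):
        self.items: list[tuple[str, str, bool]] = list(items or [])

    @classmethod
    def parse(cls, text: str) -> "Attributes":
        items = []
        for m in _ATTR_RE.finditer(text):
            key = m.group(1)
            if m.group(2) is not None:
                items.append((key, m.group(2), True))
            else:
                items.append((key, m.group(3).strip(), False))
        return cls(items)

    def get(self, key: str, default=None):
        for k, v, _ in self.items:
            if k == key:
                return v
        return default

    def get_all(self, key: str) -> list[str]:
        return [v for k, v, _ in self.items if k == key]

    def set(self, key: str, value: str, quoted: bool = True) -> None:
        for i, (k, _, q) in enumerate(self.items):
            if k == key:
                self.items[i] = (k, value, q)
                return
        self.items.append((key, value, quoted))

    def __contains__(self, key: str) -> bool:
        return any(k == key for k, _, _ in self.items)

    def copy(self) -> "Attributes":
        return Attributes(self.items)

    def serialize(self) -> str:
        parts = []
        for k, v, quoted in self.items:
            parts.append(f'{k} "{v}";' if quoted else f"{k} {v};")
        return " ".join(parts)

    def __eq__(self, other):
        return isinstance(other, Attributes) and self.items == other.items

    def __repr__(self):
        return f"Attributes({self.items!r})"


@dataclass
class GtfRecord:
    """One GTF feature line, with file (1-based inclusive) coordinates."""

    seqname: str
    source: str
    feature: str
    start: int
    end: int
    score: str
    strand: str
    frame: str
    attributes: Attributes
    line_number: int = 0

    @property
    def gene_id(self):
        return self.attributes.get("gene_id")

    @property
    def transcript_id(self):
        return self.attributes.get("transcript_id")

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open genomic interval."""
        return (self.start - 1, self.end)

    def copy(self) -> "GtfRecord":
        return GtfRecord(
            self.seqname, self.source, self.feature, self.start, self.end,
            self.score, self.strand, self.frame, self.attributes.copy(),
            self.line_number,
        )

    def serialize(self) -> str:
        return "\t".join(
            (
                self.seqname, self.source, self.feature,
                str(self.start), str(self.end),
                self.score, self.strand, self.frame,
                self.attributes.serialize(),
            )
        )


@dataclass
class TranscriptModel:
    """A transcript's exon and CDS structure in 0-based half-open intervals.

    ``exons`` and ``cds_segments`` are sorted ascending by genomic start and
    pairwise disjoint; every CDS segment lies inside an exon.  The Ensembl
    convention applies: CDS excludes the stop codon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    biotype: str | None
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]]
    canonical_tag: bool = False
    source_records: list[GtfRecord] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def validate(self) -> None:
        for segs in (self.exons, self.cds_segments):
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise GtfValidationError(
                        f"{self.transcript_id}: overlapping/unsorted intervals"
                    )
        exonic = set()
        for s, e in self.exons:
            exonic.update(range(s, e))
        for s, e in self.cds_segments:
            if not all(p in exonic for p in range(s, e)):
                raise GtfValidationError(
                    f"{self.transcript_id}: CDS segment [{s},{e}) escapes exons"
                )


@dataclass
class GenomeAnnotation:
    """Record list plus the transcript/gene maps assembled from it."""

    records: list[GtfRecord]
    transcripts: dict[str, TranscriptModel]
    genes: dict[str, list[str]]
    header_lines: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def from_records(cls, records, header_lines=None) -> "GenomeAnnotation":
        ann = cls(list(records), {}, {}, list(header_lines or []))
        ann._assemble()
        return ann

    def _assemble(self) -> None:
        transcripts: dict[str, TranscriptModel] = {}
        genes: dict[str, list[str]] = {}
        per_tid: dict[str, list[GtfRecord]] = {}
        for rec in self.records:
            if rec.feature == "gene":
                genes.setdefault(rec.gene_id, [])
                continue
            tid = rec.transcript_id
            if tid is None:
                continue
            if rec.strand not in ("+", "-"):
                msg = (f"line {rec.line_number}: strand '{rec.strand}' record "
                       f"excluded from transcript assembly")
                logger.warning(msg)
                self.warnings.append(msg)
                continue
            per_tid.setdefault(tid, []).append(rec)
        for tid, recs in per_tid.items():
            exons = sorted(r.interval for r in recs if r.feature == "exon")
            cds = sorted(r.interval for r in recs if r.feature == "CDS")
            first = recs[0]
            biotype = None
            canonical = False
            for r in recs:
                biotype = (
                    biotype
                    or r.attributes.get("transcript_biotype")
                    or r.attributes.get("gene_biotype")
                )
                if "Ensembl_canonical" in r.attributes.get_all("tag"):
                    canonical = True
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=first.gene_id,
                chrom=first.seqname,
                strand=first.strand,
                biotype=biotype,
                exons=exons,
                cds_segments=cds,
                canonical_tag=canonical,
                source_records=recs,
            )
            model.validate()
            transcripts[tid] = model
            genes.setdefault(first.gene_id, [])
            if tid not in genes[first.gene_id]:
                genes[first.gene_id].append(tid)
        self.transcripts = transcripts
        self.genes = genes


_REQUIRE_TRANSCRIPT_ID = GTF_FEATURES - {"gene"}


def parse_gtf_line(line: str, line_number: int) -> GtfRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise GtfValidationError(
            f"line {line_number}: expected 9 tab-delimited columns, "
            f"got {len(fields)}"
        )
    seqname, source, feature, start, end, score, strand, frame, attrs = fields
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise GtfValidationError(
            f"line {line_number}: non-integer coordinates"
        ) from exc
    if end_i < start_i:
        raise GtfValidationError(
            f"line {line_number}: end ({end_i}) < start ({start_i})"
        )
    rec = GtfRecord(
        seqname, source, feature, start_i, end_i, score, strand, frame,
        Attributes.parse(attrs), line_number,
    )
    if rec.gene_id is None:
        raise GtfValidationError(f"line {line_number}: missing gene_id")
    if feature in _REQUIRE_TRANSCRIPT_ID and rec.transcript_id is None:
        raise GtfValidationError(
            f"line {line_number}: feature '{feature}' missing transcript_id"
        )
    return rec


def parse_gtf(path) -> GenomeAnnotation:
    """Parse an Ensembl-dialect GTF into a :class:`GenomeAnnotation`."""
    records: list[GtfRecord] = []
    header: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#"):
                header.append(line.rstrip("\n"))
                continue
            if not line.strip():
                continue
            records.append(parse_gtf_line(line, i))
    return GenomeAnnotation.from_records(records, header_lines=header)


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Serialize an annotation; ``parse_gtf(write_gtf(a))`` round-trips."""
    with open(path, "w") as fh:
        for line in annotation.header_lines:
            fh.write(line + "\n")
        for rec in annotation.records:
            fh.write(rec.serialize() + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA into ``{name: uppercase sequence}``.

    The name is the first whitespace-delimited header token; duplicate
    names are an error.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise GtfValidationError(f"duplicate FASTA sequence name: {rec.id}")
        sequences[rec.id] = str(rec.seq).upper()
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
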