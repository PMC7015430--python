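import numpy as np
import pytest

from conftest import random_cds_model, truncate_brute_force
from riboprof.annotation_io import TranscriptModel, parse_gtf
from riboprof.gtf_curation import (
    TruncationSpec,
    curate_reference,
    filter_protein_coding,
    select_canonical,
    truncate_cds,
)


def plus_model(exons, cds=None):
    return TranscriptModel(
        "t", "g", "chr1", "+", "protein_coding", exons, cds or list(exons)
    )


class TestTruncateCds:
    def test_single_segment_defaults(self):
        # 300 nt CDS at 1-based [101,400]: 45 off the 5' side, 15 off the 3'
        model = plus_model([(100, 400)])
        out = truncate_cds(model)
        assert out.cds_segments == [(145, 385)]  # 1-based [146,385]
        assert out.cds_length == 240

    def test_zero_trim_is_identity(self):
        model = plus_model([(100, 400)])
        out = truncate_cds(model, TruncationSpec(trim5=0, trim3=0))
        assert out.cds_segments == model.cds_segments

    def test_recursion_deletes_short_terminal_segment(self):
        # 30 nt first segment < trim5: removed whole, remainder from next
        model = plus_model([(100, 130), (200, 400)])
        out = truncate_cds(model, TruncationSpec(trim5=45, trim3=15))
        assert out.cds_segments == [(215, 385)]  # 1-based [216,385]

    def test_minus_strand_trims_high_coordinate_end(self):
        model = TranscriptModel(
            "t", "g", "chr1", "-", "protein_coding",
            [(100, 400)], [(100, 400)],
        )
        out = truncate_cds(model)
        assert out.cds_segments == [(115, 355)]

    def test_short_cds_skipped_and_flagged(self):
        model = plus_model([(100, 150)])  # 50 <= 45 + 15 + 3
        out = truncate_cds(model)
        assert out.cds_segments == model.cds_segments
        assert "truncation_skipped" in out.flags

    def test_no_cds_is_flagged_noop(self):
        model = plus_model([(100, 400)], cds=[])
        model.cds_segments = []
        out = truncate_cds(model)
        assert "no_cds" in out.flags

    def test_exons_never_modified(self):
        model = plus_model([(100, 130), (200, 400)])
        out = truncate_cds(model)
        assert out.exons == model.exons


def test_truncation_matches_brute_force_oracle_both_strands():
    rng = np.random.default_rng(2024)
    spec = TruncationSpec()
    checked = 0
    while checked < 200:
        model = random_cds_model(rng)
        if model.cds_length <= spec.trim5 + spec.trim3 + spec.min_remaining:
            continue
        out = truncate_cds(model, spec)
        expected = truncate_brute_force(model, spec.trim5, spec.trim3)
        assert out.cds_segments == expected, (model.strand, model.cds_segments)
        assert out.cds_length == model.cds_length - 60
        # containment: no new coordinates invented
        original = {p for s, e in model.cds_segments for p in range(s, e)}
        assert all(
            p in original for s, e in out.cds_segments for p in range(s, e)
        )
        checked += 1


def test_strand_symmetry_of_truncation():
    rng = np.random.default_rng(99)
    spec = TruncationSpec()
    for _ in range(50):
        model = random_cds_model(rng)
        if model.cds_length <= 63:
            continue
        mirror_origin = 10_000
        mirrored_exons = sorted(
            (mirror_origin - e, mirror_origin - s) for s, e in model.exons
        )
        flipped = TranscriptModel(
            "t", "g", "chr1", "-" if model.strand == "+" else "+",
            model.biotype, mirrored_exons, list(mirrored_exons),
        )
        out = truncate_cds(model, spec)
        out_flipped = truncate_cds(flipped, spec)
        remapped = sorted(
            (mirror_origin - e, mirror_origin - s)
            for s, e in out_flipped.cds_segments
        )
        assert remapped == out.cds_segments


class TestFilters:
    def test_protein_coding_filter_drops_rrna(self, small_reference_dir):
        ann = parse_gtf(small_reference_dir / "annotation.gtf")
        filtered = filter_protein_coding(ann)
        assert len(filtered.genes) == 5
        assert all(
            m.biotype == "protein_coding"
            for m in filtered.transcripts.values()
        )

    def test_protein_coding_filter_idempotent(self, small_reference_dir):
        ann = parse_gtf(small_reference_dir / "annotation.gtf")
        once = filter_protein_coding(ann)
        twice = filter_protein_coding(once)
        assert [r.serialize() for r in twice.records] == [
            r.serialize() for r in once.records
        ]

    def test_no_coding_genes_leaves_empty_annotation(self, tmp_path):
        path = tmp_path / "rrna.gtf"
        path.write_text(
            'chr1\ts\tgene\t1\t100\t.\t+\t.\tgene_id "G"; gene_biotype "rRNA";\n'
        )
        filtered = filter_protein_coding(parse_gtf(path))
        assert not filtered.genes

    def test_canonical_tag_wins(self, tmp_path):
        path = tmp_path / "two.gtf"
        lines = []
        # T1 untagged but longer CDS; T2 tagged -> T2 kept
        for tid, cds_end, tag in (("T1", 400, ""), ("T2", 250, ' tag "Ensembl_canonical";')):
            lines.append(
                f'chr1\ts\ttranscript\t100\t400\t.\t+\t.\tgene_id "G"; '
                f'transcript_id "{tid}";{tag}'
            )
            lines.append(
                f'chr1\ts\texon\t100\t400\t.\t+\t.\tgene_id "G"; '
                f'transcript_id "{tid}";'
            )
            lines.append(
                f'chr1\ts\tCDS\t100\t{cds_end}\t.\t+\t0\tgene_id "G"; '
                f'transcript_id "{tid}";'
            )
        path.write_text("\n".join(lines) + "\n")
        selected = select_canonical(parse_gtf(path))
        assert list(selected.transcripts) == ["T2"]

    def test_untagged_longest_cds_wins_and_idempotent(self, tmp_path):
        path = tmp_path / "two.gtf"
        lines = []
        for tid, cds_end in (("T1", 400), ("T2", 250)):  # 300 vs 150 nt CDS
            lines.append(
                f'chr1\ts\texon\t100\t400\t.\t+\t.\tgene_id "G"; '
                f'transcript_id "{tid}";'
            )
            lines.append(
                f'chr1\ts\tCDS\t101\t{cds_end}\t.\t+\t0\tgene_id "G"; '
                f'transcript_id "{tid}";'
            )
        path.write_text("\n".join(lines) + "\n")
        once = select_canonical(parse_gtf(path))
        assert list(once.transcripts) == ["T1"]
        twice = select_canonical(once)
        assert [r.serialize() for r in twice.records] == [
            r.serialize() for r in once.records
        ]


class TestCurateReference:
    def test_full_pipeline_reduces_coding_length_by_60(
        self, small_reference, small_reference_dir, tmp_path
    ):
        out = tmp_path / "curated.gtf"
        curate_reference(
            small_reference_dir / "annotation.gtf", out,
            protein_coding=True, canonical=True, truncate=True,
        )
        curated = parse_gtf(out)
        original = parse_gtf(small_reference_dir / "annotation.gtf")
        assert curated.transcripts  # something survived
        for tid, model in curated.transcripts.items():
            old = original.transcripts[tid]
            if old.cds_length > 63:
                assert model.cds_length == old.cds_length - 60
                assert model.exons == old.exons
                # start codons dropped, stop codons kept
                feats = {r.feature for r in model.source_records}
                assert "start_codon" not in feats
                assert "stop_codon" in feats

    def test_all_flags_off_round_trips_bytes(
        self, small_reference_dir, tmp_path
    ):
        out = tmp_path / "copy.gtf"
        curate_reference(
            small_reference_dir / "annotation.gtf", out,
            protein_coding=False, canonical=False, truncate=False,
        )
        src = (small_reference_dir / "annotation.gtf").read_text()
        assert out.read_text() == src

    def test_short_cds_reported_skipped(self, tmp_path):
        path = tmp_path / "short.gtf"
        path.write_text(
            'chr1\ts\tgene\t1\t200\t.\t+\t.\tgene_id "G"; gene_biotype "protein_coding";\n'
            'chr1\ts\ttranscript\t1\t200\t.\t+\t.\tgene_id "G"; transcript_id "T"; transcript_biotype "protein_coding";\n'
            'chr1\ts\texon\t1\t200\t.\t+\t.\tgene_id "G"; transcript_id "T"; transcript_biotype "protein_coding";\n'
            'chr1\ts\tCDS\t51\t100\t.\t+\t0\tgene_id "G"; transcript_id "T"; transcript_biotype "protein_coding";\n'
        )
        out = tmp_path / "out.gtf"
        report = curate_reference(path, out)
        trunc_step = [s for s in report.steps if s["step"] == "truncate"][0]
        assert trunc_step["skipped"] == ["T"]
        assert parse_gtf(out).transcripts["T"].cds_length == 50


def test_frame_recomputed_for_non_codon_trim():
    model = plus_model([(100, 130), (200, 400)])
    from riboprof.annotation_io import Attributes, GtfRecord

    model.source_records = [
        GtfRecord("chr1", "s", "CDS", 101, 130, ".", "+", "0",
                  Attributes([("gene_id", "g", True),
                              ("transcript_id", "t", True)])),
        GtfRecord("chr1", "s", "CDS", 201, 400, ".", "+", "0",
                  Attributes([("gene_id", "g", True),
                              ("transcript_id", "t", True)])),
    ]
    out = truncate_cds(model, TruncationSpec(trim5=4, trim3=3))
    cds = [r for r in out.source_records if r.feature == "CDS"]
    # first retained base is 4 nt into coding space: frame (3 - 4 % 3) % 3 = 2
    assert cds[0].frame == "2"
    seg_len = cds[0].end - cds[0].start + 1
    assert cds[1].frame == str((3 - ((seg_len - 2) % 3)) % 3)


def test_invalid_truncation_spec_rejected():
    with pytest.raises(ValueError):
        TruncationSpec(trim5=-1)
    with pytest.raises(ValueError):
        TruncationSpec(min_remaining=4)
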