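import numpy as np
import pytest
from scipy import stats as sps

from conftest import random_cds_model
from riboprof.alignment_model import AlignmentRecord
from riboprof.annotation_io import GenomeAnnotation, TranscriptModel
from riboprof.coverage_profiles import (
    build_exon_map,
    gene_coverage,
    metagene,
    phasing,
    read_five_prime_exonic,
)
from riboprof.synthetic_fixtures import (
    SimulationConfig,
    make_reference,
    simulate_reads,
)


def model_of(exons, strand="+", cds=None):
    return TranscriptModel(
        "t", "g", "chr1", strand, "protein_coding", exons, cds or []
    )


class TestExonMap:
    def test_single_exon_identity(self):
        emap = build_exon_map(model_of([(0, 100)]))
        assert emap.genomic_to_exonic(42) == 42
        assert emap.exonic_to_genomic(42) == 42

    def test_two_exons_concatenate(self):
        emap = build_exon_map(model_of([(0, 10), (20, 30)]))
        assert emap.genomic_to_exonic(20) == 10
        assert emap.genomic_to_exonic(15) is None  # intron

    def test_minus_strand_reverses(self):
        emap = build_exon_map(model_of([(0, 10), (20, 30)], strand="-"))
        assert emap.genomic_to_exonic(29) == 0
        assert emap.genomic_to_exonic(0) == 19

    def test_bijectivity_on_random_transcripts(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            model = random_cds_model(rng)
            emap = build_exon_map(model)
            for i in range(emap.length):
                assert emap.genomic_to_exonic(emap.exonic_to_genomic(i)) == i

    def test_strand_symmetry(self):
        rng = np.random.default_rng(32)
        for _ in range(25):
            model = random_cds_model(rng)
            model.strand = "+"
            plus = build_exon_map(model)
            model.strand = "-"
            minus = build_exon_map(model)
            assert list(plus.genomic) == list(minus.genomic[::-1])


def read_at(pos, length=10, strand="+", rid="r"):
    return AlignmentRecord(rid, "chr1", strand, [(pos, pos + length)], length)


class TestGeneCoverage:
    def test_intron_only_read_contributes_zero(self):
        model = model_of([(0, 50), (100, 150)])
        track, _ = gene_coverage([read_at(60, 20)], model)
        assert track.counts.sum() == 0

    def test_feature_marks_in_exon_space(self):
        model = model_of([(0, 50), (100, 150)], cds=[(30, 50), (100, 120)])
        _, features = gene_coverage([], model)
        assert features["cds_start"] == 30
        assert features["cds_end"] == 70

    def test_utr5_cluster_appears_upstream_of_cds_marker(self):
        cfg = SimulationConfig(seed=17, n_genes=2, reads_per_gene=400,
                               utr5_cluster_fraction=0.5)
        ref = make_reference(cfg)
        reads = simulate_reads(cfg, ref)
        tid = ref.truth.iloc[0]["transcript_id"]
        model = ref.annotation.transcripts[tid]
        mine = [a for a in reads.alignments
                if a.read_id.split(".")[1] == model.gene_id]
        track, features = gene_coverage(mine, model)
        utr = track.counts[: features["cds_start"]]
        assert utr.sum() > 0, "expected a 5' UTR footprint cluster"


def annotation_of(models):
    ann = GenomeAnnotation([], {m.transcript_id: m for m in models}, {})
    for m in models:
        ann.genes.setdefault(m.gene_id, []).append(m.transcript_id)
    return ann


class TestMetagene:
    def test_sum_to_one_and_flat_profile(self, small_reference, uniform_reads):
        profile = metagene(uniform_reads.alignments,
                           small_reference.annotation, bins=20)
        assert profile.n_transcripts == 5
        assert profile.bins.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(profile.bins - 0.05) < 0.02)

    def test_first_half_coverage_closed_form(self):
        model = model_of([(0, 200)])
        model.transcript_id, model.gene_id = "T", "G"
        ann = annotation_of([model])
        reads = [read_at(5 * i, 10, rid=f"r{i}") for i in range(20)]  # 5' < 100
        profile = metagene(reads, ann, bins=10, min_coverage=10)
        assert profile.bins[:5] == pytest.approx([0.2] * 5)
        assert profile.bins[5:].sum() == 0

    def test_super_expressor_damping_bit_identical(
        self, small_reference, uniform_reads
    ):
        base = metagene(uniform_reads.alignments,
                        small_reference.annotation, bins=25)
        boosted_gene = small_reference.truth.iloc[0]["gene_id"]
        boosted = list(uniform_reads.alignments)
        for rep in range(99):
            for aln in uniform_reads.alignments:
                if aln.read_id.split(".")[1] == boosted_gene:
                    boosted.append(aln)
        damped = metagene(boosted, small_reference.annotation, bins=25)
        assert np.array_equal(base.bins, damped.bins)

    def test_below_threshold_excluded_with_warning(self, caplog):
        model = model_of([(0, 200)])
        model.transcript_id, model.gene_id = "T", "G"
        ann = annotation_of([model])
        profile = metagene([read_at(0)], ann, min_coverage=10)
        assert profile.n_transcripts == 0
        assert profile.n_excluded == 1
        assert profile.bins.sum() == 0


class TestPhasing:
    def simulate(self, **overrides):
        cfg = SimulationConfig(seed=11, n_genes=6, reads_per_gene=1500,
                               pileup_5prime_factor=20.0, **overrides)
        ref = make_reference(cfg)
        return ref, simulate_reads(cfg, ref)

    def test_offset_recovery_and_frame_concentration(self):
        ref, reads = self.simulate()
        profile = phasing(reads.alignments, ref.annotation)
        # every recovered per-length offset within 1 nt of the truth
        assert profile.offsets
        for length, offset in profile.offsets.items():
            assert abs(offset - 12) <= 1, (length, offset)
        assert profile.frame_fractions[0] > 0.9
        assert profile.frame_counts.sum() == profile.n_reads_used

    def test_single_read_at_start_trivial(self):
        model = model_of([(0, 300)], cds=[(60, 240)])
        model.transcript_id, model.gene_id = "T", "G"
        ann = annotation_of([model])
        profile = phasing([read_at(60, 30)], ann, offset_mode="fixed",
                          fixed_offset=0)
        assert profile.frame_counts.tolist() == [1, 0, 0]
        assert profile.start_relative_histogram == {0: 1}

    def test_uniform_random_reads_give_uniform_frames(self):
        rng = np.random.default_rng(55)
        model = model_of([(0, 3000)], cds=[(60, 2940)])
        model.transcript_id, model.gene_id = "T", "G"
        ann = annotation_of([model])
        reads = [read_at(int(p), 28, rid=f"r{i}")
                 for i, p in enumerate(rng.integers(0, 2900, size=3000))]
        profile = phasing(reads, ann, offset_mode="fixed", fixed_offset=12)
        chi2 = sps.chisquare(profile.frame_counts)
        assert chi2.pvalue > 0.01

    def test_auto_falls_back_without_start_proximal_reads(self):
        model = model_of([(0, 3000)], cds=[(60, 2940)])
        model.transcript_id, model.gene_id = "T", "G"
        ann = annotation_of([model])
        reads = [read_at(2000 + i, 28, rid=f"r{i}") for i in range(5)]
        profile = phasing(reads, ann, offset_mode="auto", fixed_offset=16)
        assert profile.fallback_used


def test_truncation_excludes_five_prime_pileup_from_cds_profile(tmp_path):
    """Metagene over a truncated annotation loses the 5' pile-up elevation."""
    from riboprof.annotation_io import parse_gtf
    from riboprof.gtf_curation import curate_reference

    cfg = SimulationConfig(seed=23, n_genes=5, reads_per_gene=1500,
                           pileup_5prime_factor=12.0)
    ref = make_reference(cfg)
    reads = simulate_reads(cfg, ref)
    gtf_in = tmp_path / "ref.gtf"
    gtf_out = tmp_path / "truncated.gtf"
    from riboprof.annotation_io import write_gtf

    write_gtf(ref.annotation, gtf_in)
    curate_reference(gtf_in, gtf_out, canonical=False)
    untruncated = metagene(reads.alignments, ref.annotation,
                           bins=20, cds_only=True)
    truncated = metagene(reads.alignments, parse_gtf(gtf_out),
                         bins=20, cds_only=True)
    assert untruncated.bins[0] > 1.1 * truncated.bins[0]
    assert untruncated.bins[0] > 1.0 / 20  # elevated above the flat level
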