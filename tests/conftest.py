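import numpy as np
import pytest

from riboprof.annotation_io import TranscriptModel
from riboprof.synthetic_fixtures import (
    Reference,
    SimulationConfig,
    make_reference,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_reference() -> Reference:
    """Five protein-coding genes plus two rRNA genes, both strands."""
    return make_reference(SimulationConfig(seed=7, n_genes=5, n_rrna_genes=2))


@pytest.fixture(scope="session")
def small_reference_dir(small_reference, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("ref")
    small_reference.write(outdir)
    return outdir


@pytest.fixture(scope="session")
def uniform_reads(small_reference):
    """RNA-assay library: uniform 5' ends, no biases, no duplicates."""
    return simulate_reads(
        small_reference.config, small_reference, assay="rna", sample="uni"
    )


def random_cds_model(rng: np.random.Generator) -> TranscriptModel:
    """Random multi-segment CDS transcript for truncation/exon-map tests."""
    n_seg = int(rng.integers(1, 6))
    strand = "+" if rng.random() < 0.5 else "-"
    cursor = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n_seg):
        length = int(rng.integers(5, 200))
        exons.append((cursor, cursor + length))
        cursor += length + int(rng.integers(10, 100))
    return TranscriptModel(
        "t", "g", "chr1", strand, "protein_coding", exons, list(exons)
    )


def coding_order_positions(model: TranscriptModel) -> list[int]:
    """All CDS base positions in 5'->3' transcript orientation."""
    positions = [p for s, e in model.cds_segments for p in range(s, e)]
    return positions if model.strand == "+" else positions[::-1]


def positions_to_segments(positions) -> list[tuple[int, int]]:
    """Re-assemble sorted genomic positions into maximal intervals."""
    out = []
    for p in sorted(positions):
        if out and out[-1][1] == p:
            out[-1][1] = p + 1
        else:
            out.append([p, p + 1])
    return [tuple(iv) for iv in out]


def truncate_brute_force(model, trim5: int, trim3: int):
    """Base-by-base truncation oracle, independent of interval arithmetic."""
    positions = coding_order_positions(model)
    kept = positions[trim5 : len(positions) - trim3]
    return positions_to_segments(kept)
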