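"""Synthetic genomes, annotations, and footprint libraries with ground truth.

Every downstream module is exercised against data produced here, so the
generator records the truth it samples from: per-transcript interval
lists, per-read placements and duplicate status, planted rRNA fragments,
and planted translation-efficiency effects.

The read model mirrors the biases ribosome profiling is known for:
footprint lengths follow a discrete triangular distribution peaked at
28 nt over 17-33 nt; P-sites are placed codon-aligned (frame 0) at a
fixed, length-independent offset from the footprint 5' end; initiation
and termination pile-ups are modeled as multiplicative P-site enrichment
that is maximal at the start/stop codon and decays exponentially over the
first/last k coding nucleotides; rRNA contamination is a configurable
fraction of the library drawn from a small set of fragment sequences;
PCR duplication re-samples already-emitted molecules.  Reads are emitted
pre-aligned (SAM) so no aligner is involved; FASTQ is emitted for the
sequence-level modules.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_model import AlignmentRecord, write_sam
from .annotation_io import (
    Attributes,
    GenomeAnnotation,
    GtfRecord,
    write_fasta,
    write_gtf,
)
from .coverage_profiles import ExonCoordinateMap, build_exon_map

_COMPLEMENT = str.maketrans("ACGTN", "TACGN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Knobs of the simulated experiment; the defaults are the baseline
    unbiased library, with biases switched on per scenario."""

    seed: int = 1
    n_genes: int = 5
    n_rrna_genes: int = 0
    exons_per_gene: tuple[int, int] = (2, 4)
    cds_length: tuple[int, int] = (300, 900)  # rounded down to codons
    utr5_length: tuple[int, int] = (60, 150)
    utr3_length: tuple[int, int] = (60, 150)
    intron_length: tuple[int, int] = (50, 300)
    intergenic: tuple[int, int] = (200, 500)
    chrom: str = "chr1"
    # read model
    reads_per_gene: int | dict = 200
    footprint_len_range: tuple[int, int] = (17, 33)
    footprint_len_mode: int = 28
    p_site_offset: int = 12
    pileup_5prime_factor: float = 1.0
    pileup_5prime_k: int = 45
    pileup_3prime_factor: float = 1.0
    pileup_3prime_k: int = 15
    utr5_cluster_fraction: float = 0.0  # uORF-like 5' UTR footprints
    rrna_fragments: list[str] = field(default_factory=list)
    contamination_fraction: float = 0.0
    duplication_rate: float = 0.0
    umi: bool = False
    umi_length: int = 10
    # count-level TE experiment
    replicates: int = 3
    noise_cv: float = 0.2

    def __post_init__(self):
        for name in ("contamination_fraction", "duplication_rate",
                     "utr5_cluster_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1): got {v}")
        if self.cds_length[0] < 3:
            raise ValueError("cds_length must allow at least one codon")
        if self.exons_per_gene[0] < 1:
            raise ValueError("exons_per_gene must be >= 1")


@dataclass
class Reference:
    genome: dict[str, str]
    annotation: GenomeAnnotation
    truth: pd.DataFrame  # per-transcript structure table
    config: SimulationConfig

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.genome, f"{outdir}/genome.fa")
        write_gtf(self.annotation, f"{outdir}/annotation.gtf")
        self.truth.to_csv(f"{outdir}/reference_truth.tsv", sep="\t",
                          index=False)


def _attrs(pairs) -> Attributes:
    return Attributes([(k, str(v), True) for k, v in pairs])


def _transcript_to_genomic(
    exon_tx: list[tuple[int, int]],
    exon_gx: list[tuple[int, int]],
    strand: str,
    lo: int,
    hi: int,
) -> list[tuple[int, int]]:
    """Image of transcript-space [lo,hi) as ascending genomic intervals."""
    pieces = []
    for (ts, te), (gs, ge) in zip(exon_tx, exon_gx):
        a, b = max(lo, ts), min(hi, te)
        if a >= b:
            continue
        if strand == "+":
            pieces.append((gs + (a - ts), gs + (b - ts)))
        else:
            pieces.append((ge - (b - ts), ge - (a - ts)))
    return sorted(pieces)


def _split_lengths(rng, total: int, parts: int, minimum: int) -> list[int]:
    """Random composition of ``total`` into ``parts`` pieces >= minimum."""
    if parts * minimum > total:
        parts = max(1, total // minimum)
    free = total - parts * minimum
    cuts = np.sort(rng.integers(0, free + 1, size=parts - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [free]])) + minimum
    return [int(s) for s in sizes]


def make_reference(config: SimulationConfig) -> Reference:
    """Generate a genome + Ensembl-dialect GTF with known structure."""
    rng = np.random.default_rng(config.seed)
    records: list[GtfRecord] = []
    truth_rows = []
    cursor = 100
    chrom = config.chrom
    n_total = config.n_genes + config.n_rrna_genes
    for gi in range(n_total):
        is_rrna = gi >= config.n_genes
        gid = f"G{gi + 1:04d}"
        tid = f"T{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        biotype = "rRNA" if is_rrna else "protein_coding"

        if is_rrna:
            u5 = u3 = cds = 0
            L = int(rng.integers(120, 200))
            exon_lengths = [L]
        else:
            u5 = int(rng.integers(*config.utr5_length))
            u3 = int(rng.integers(*config.utr3_length))
            cds = int(rng.integers(*config.cds_length)) // 3 * 3
            L = u5 + cds + 3 + u3  # stop codon sits between CDS and 3' UTR
            n_exons = int(rng.integers(config.exons_per_gene[0],
                                       config.exons_per_gene[1] + 1))
            exon_lengths = _split_lengths(rng, L, n_exons, minimum=30)

        # transcript-space exon ranges, then genomic placement
        exon_tx = []
        t = 0
        for ln in exon_lengths:
            exon_tx.append((t, t + ln))
            t += ln
        gx_order = exon_lengths if strand == "+" else exon_lengths[::-1]
        g = cursor
        gx_intervals = []
        for i, ln in enumerate(gx_order):
            gx_intervals.append((g, g + ln))
            g += ln
            if i < len(gx_order) - 1:
                g += int(rng.integers(*config.intron_length))
        gene_start, gene_end = gx_intervals[0][0], gx_intervals[-1][1]
        cursor = gene_end + int(rng.integers(*config.intergenic))
        exon_gx = gx_intervals if strand == "+" else gx_intervals[::-1]

        def gtf(feature, s, e, frame=".", extra=()):
            base = [("gene_id", gid)]
            if feature != "gene":
                base.append(("transcript_id", tid))
            base.append(("gene_biotype", biotype))
            if feature != "gene":
                base.append(("transcript_biotype", biotype))
            records.append(
                GtfRecord(chrom, "sim", feature, s + 1, e, ".", strand,
                          frame, _attrs(base + list(extra)))
            )

        gtf("gene", gene_start, gene_end)
        gtf("transcript", gene_start, gene_end,
            extra=[("tag", "Ensembl_canonical")])
        for num, ((ts, te), _) in enumerate(zip(exon_tx, exon_gx), start=1):
            for gs, ge in _transcript_to_genomic(exon_tx, exon_gx, strand,
                                                 ts, te):
                gtf("exon", gs, ge, extra=[("exon_number", num)])
        cds_gx: list[tuple[int, int]] = []
        if not is_rrna:
            cds_gx = _transcript_to_genomic(exon_tx, exon_gx, strand,
                                            u5, u5 + cds)
            ordered = cds_gx if strand == "+" else cds_gx[::-1]
            frame = 0
            for gs, ge in ordered:
                gtf("CDS", gs, ge, frame=str(frame))
                frame = (3 - ((ge - gs - frame) % 3)) % 3
            for gs, ge in _transcript_to_genomic(exon_tx, exon_gx, strand,
                                                 u5, u5 + 3):
                gtf("start_codon", gs, ge, frame="0")
            for gs, ge in _transcript_to_genomic(exon_tx, exon_gx, strand,
                                                 u5 + cds, u5 + cds + 3):
                gtf("stop_codon", gs, ge, frame="0")
            if u5:
                for gs, ge in _transcript_to_genomic(exon_tx, exon_gx,
                                                     strand, 0, u5):
                    gtf("five_prime_utr", gs, ge)
            if u3:
                for gs, ge in _transcript_to_genomic(
                    exon_tx, exon_gx, strand, u5 + cds + 3, L
                ):
                    gtf("three_prime_utr", gs, ge)

        truth_rows.append(
            {
                "transcript_id": tid,
                "gene_id": gid,
                "chrom": chrom,
                "strand": strand,
                "biotype": biotype,
                "exonic_length": L,
                "cds_length": cds,
                "utr5_length": u5,
                "utr3_length": u3,
                "exons": ",".join(f"{s}-{e}" for s, e in sorted(gx_intervals)),
                "cds_segments": ",".join(f"{s}-{e}" for s, e in cds_gx),
            }
        )

    genome_len = cursor + 200
    bases = rng.choice(list("ACGT"), size=genome_len)
    genome = {chrom: "".join(bases)}
    annotation = GenomeAnnotation.from_records(
        records, header_lines=["#!genome-build simulated"]
    )
    return Reference(genome, annotation, pd.DataFrame(truth_rows), config)


def _length_weights(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = config.footprint_len_range
    mode = config.footprint_len_mode
    lengths = np.arange(lo, hi + 1)
    w = np.where(
        lengths <= mode,
        (lengths - lo + 1) / (mode - lo + 1),
        (hi - lengths + 1) / (hi - mode + 1),
    ).astype(float)
    return lengths, w / w.sum()


def _psite_weights(cds: int, config: SimulationConfig) -> np.ndarray:
    """Per-codon P-site sampling weights with end pile-ups.

    The enrichment is maximal at the initiation (termination) codon and
    decays exponentially over the first (last) k coding nucleotides,
    approximating the sharp ribosome pauses seen at CDS ends.
    """
    codons = np.arange(0, cds, 3, dtype=float)
    w = np.ones_like(codons)
    f5, k5 = config.pileup_5prime_factor, config.pileup_5prime_k
    f3, k3 = config.pileup_3prime_factor, config.pileup_3prime_k
    if f5 != 1.0 and k5 > 0:
        w += (f5 - 1.0) * np.exp(-9.0 * codons / k5) * (codons < k5)
    if f3 != 1.0 and k3 > 0:
        dist = cds - 3 - codons
        w += (f3 - 1.0) * np.exp(-9.0 * dist / k3) * (dist < k3)
    return w / w.sum()


def _blocks_for(emap: ExonCoordinateMap, start: int, length: int):
    positions = np.sort(emap.genomic[start : start + length])
    breaks = np.where(np.diff(positions) != 1)[0]
    blocks = []
    prev = 0
    for b in list(breaks) + [len(positions) - 1]:
        blocks.append((int(positions[prev]), int(positions[b]) + 1))
        prev = b + 1
    return blocks


@dataclass
class SimReads:
    alignments: list[AlignmentRecord]
    fastq: list[tuple[str, str]]  # (read id, sequence)
    truth: pd.DataFrame
    sample: str

    def write(self, outdir, genome_lengths: dict[str, int]) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_sam(self.alignments, genome_lengths,
                  f"{outdir}/{self.sample}.sam")
        with open(f"{outdir}/{self.sample}.fastq", "w") as fh:
            for rid, seq in self.fastq:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        self.truth.to_csv(f"{outdir}/{self.sample}_truth.tsv", sep="\t",
                          index=False)


def simulate_reads(
    config: SimulationConfig,
    reference: Reference,
    assay: str = "rpf",
    sample: str = "s1",
) -> SimReads:
    """Simulate one library over a reference; see the module docstring."""
    if assay not in ("rpf", "rna"):
        raise ValueError("assay must be 'rpf' or 'rna'")
    sample_tag = zlib.crc32(sample.encode()) % (2**31)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed, sample_tag, 0 if assay == "rpf" else 1]
        )
    )
    lengths, length_p = _length_weights(config)
    alignments: list[AlignmentRecord] = []
    fastq: list[tuple[str, str]] = []
    truth_rows = []

    coding = [
        m
        for m in reference.annotation.transcripts.values()
        if m.biotype == "protein_coding" and m.cds_segments
    ]
    for model in coding:
        info = reference.truth.set_index("transcript_id").loc[
            model.transcript_id
        ]
        L, u5, cds = (int(info["exonic_length"]), int(info["utr5_length"]),
                      int(info["cds_length"]))
        if isinstance(config.reads_per_gene, dict):
            n = int(config.reads_per_gene.get(model.gene_id, 0))
        else:
            n = int(config.reads_per_gene)
        if n == 0:
            continue
        emap = build_exon_map(model)
        psite_p = _psite_weights(cds, config) if assay == "rpf" else None

        n_unique = max(1, int(round(n * (1.0 - config.duplication_rate))))
        molecules = []
        for mi in range(n_unique):
            read_len = int(rng.choice(lengths, p=length_p))
            if assay == "rna":
                # uniform 5' ends over the whole transcript; the read is
                # clamped at the 3' end so the 5'-end profile stays flat
                five_t = int(rng.integers(0, L))
            elif (
                config.utr5_cluster_fraction > 0
                and rng.random() < config.utr5_cluster_fraction
                and u5 > read_len
            ):
                five_t = int(rng.integers(0, u5 - read_len))
            else:
                for _ in range(50):
                    psite = int(rng.choice(np.arange(0, cds, 3), p=psite_p))
                    five_t = u5 + psite - config.p_site_offset
                    if 0 <= five_t and five_t + read_len <= L:
                        break
                else:
                    five_t = max(0, min(u5, L - read_len))
            read_len = min(read_len, L - five_t)
            umi = (
                "".join(rng.choice(list("ACGT"), size=config.umi_length))
                if config.umi
                else None
            )
            molecules.append((five_t, read_len, umi))

        for ri in range(n):
            mi = ri if ri < n_unique else int(rng.integers(0, n_unique))
            five_t, read_len, umi = molecules[mi]
            rid = f"{sample}.{model.gene_id}.{ri}"
            if umi:
                rid = f"{rid}_{umi}"
            blocks = _blocks_for(emap, five_t, read_len)
            aln = AlignmentRecord(
                read_id=rid,
                chrom=model.chrom,
                strand=model.strand,
                blocks=blocks,
                read_length=read_len,
                mapq=255,
                umi=umi,
            )
            alignments.append(aln)
            seq = "".join(
                reference.genome[model.chrom][s:e] for s, e in blocks
            )
            if model.strand == "-":
                seq = revcomp(seq)
            fastq.append((rid, seq))
            truth_rows.append(
                {
                    "read_id": rid,
                    "gene_id": model.gene_id,
                    "transcript_id": model.transcript_id,
                    "category": "genomic",
                    "five_prime_tx": five_t,
                    "read_length": read_len,
                    "molecule": mi,
                    "is_duplicate": ri >= n_unique,
                }
            )

    if config.contamination_fraction > 0 and config.rrna_fragments:
        frac = config.contamination_fraction
        n_contam = int(round(frac / (1.0 - frac) * len(fastq)))
        for ci in range(n_contam):
            frag = config.rrna_fragments[
                int(rng.integers(0, len(config.rrna_fragments)))
            ]
            if len(frag) > 20 and rng.random() < 0.3:
                sub_len = int(rng.integers(17, len(frag)))
                start = int(rng.integers(0, len(frag) - sub_len + 1))
                seq = frag[start : start + sub_len]
            else:
                seq = frag
            rid = f"{sample}.rrna.{ci}"
            fastq.append((rid, seq))
            truth_rows.append(
                {
                    "read_id": rid,
                    "gene_id": "rRNA",
                    "transcript_id": "",
                    "category": "rrna",
                    "five_prime_tx": -1,
                    "read_length": len(seq),
                    "molecule": -1,
                    "is_duplicate": False,
                }
            )

    return SimReads(alignments, fastq, pd.DataFrame(truth_rows), sample)


def simulate_te_experiment(
    config: SimulationConfig,
    n_genes: int = 2000,
    n_restored: int = 20,
    stress_te: float = 0.2,
    conditions: tuple[str, str, str] = ("untreated", "stress", "cotreat"),
):
    """Count-level paired RPF/RNA experiment with planted restored genes.

    The planted genes lose translation efficiency ``stress_te``-fold under
    stress and regain it fully under co-treatment; RNA abundance is
    unaffected.  With ``config.noise_cv == 0`` counts are the exact
    expectations; otherwise counts are Poisson draws around log-normally
    perturbed means with the given coefficient of variation.

    Returns (rpf: CountMatrix, rna: CountMatrix, conditions map, truth).
    """
    from .quantification import SPECIAL_ROWS, CountMatrix

    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    lengths = pd.Series(
        rng.integers(500, 3000, size=n_genes), index=genes, name="length"
    )
    base = rng.lognormal(mean=np.log(200), sigma=0.8, size=n_genes)
    base = np.maximum(base, 30.0)
    planted = sorted(rng.choice(n_genes, size=n_restored, replace=False))
    te_mult = pd.DataFrame(1.0, index=genes, columns=list(conditions))
    te_mult.iloc[planted, te_mult.columns.get_loc(conditions[1])] = stress_te

    cv = config.noise_cv
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    cond_map: dict[str, str] = {}
    rpf_cols, rna_cols = {}, {}
    for cond in conditions:
        for rep in range(1, config.replicates + 1):
            for assay, cols in (("rpf", rpf_cols), ("rna", rna_cols)):
                label = f"{assay}_{cond}_r{rep}"
                cond_map[label] = cond
                mean = base * (te_mult[cond].values if assay == "rpf" else 1.0)
                if sigma > 0:
                    noisy = mean * rng.lognormal(
                        -sigma**2 / 2, sigma, size=n_genes
                    )
                    cols[label] = rng.poisson(noisy)
                else:
                    cols[label] = np.round(mean).astype(np.int64)

    def as_matrix(cols) -> CountMatrix:
        counts = pd.DataFrame(cols, index=genes, dtype=np.int64)
        specials = pd.DataFrame(
            0, index=list(SPECIAL_ROWS), columns=counts.columns,
            dtype=np.int64,
        )
        return CountMatrix(counts, lengths, specials)

    truth = pd.DataFrame(
        {"gene_id": [genes[i] for i in planted],
         "planted_effect": "restored"}
    )
    return as_matrix(rpf_cols), as_matrix(rna_cols), cond_map, truth
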