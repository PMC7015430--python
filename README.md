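# riboprof

Reference curation, quality control, and translation-efficiency analysis
for ribosome profiling (Ribo-seq) data.

Ribosome profiling sequences ribosome-protected mRNA fragments
("footprints", 17–33 nt) and, paired with bulk RNA-Seq, measures how
efficiently each transcript is translated. Getting trustworthy numbers out
of these libraries requires a set of specialized steps that generic RNA-Seq
tooling does not provide. `riboprof` implements them as a library plus a
CLI for people who process Ribo-seq experiments:

- **Reference curation** — recursive, strand-aware truncation of CDS
  annotations (by default 45 nt from the 5′ end and 15 nt from the 3′ end
  of *coding space*, recursing across intron-split CDS records), masking to
  protein-coding genes, and canonical-transcript selection.
  Initiation/termination ribosome pile-ups sit in the trimmed regions, so
  quantifying against the truncated GTF removes their bias from
  translation-efficiency estimates.
- **QC profiles** — metagene coverage (per-transcript normalized, so
  super-expressors carry no extra weight), intron-collapsed single-gene
  coverage in exon space, and codon phasing: per-read-length P-site offsets
  are estimated from footprints near start codons, and the 3-nt periodicity
  of inferred P-sites is reported as frame counts.
- **rRNA probe design** — ranks exact sequences over-represented across
  trimmed footprint FASTQ libraries, merging substring-conserved sequences
  across samples, for subtractive-hybridization probe design.
- **Quantification & normalization** — gene-level counting with
  intersection-nonempty semantics (per-base gene sets, empty sets
  discarded, remainder intersected) and RPM / RPKM / FPKM / TPM
  normalization.
- **Library complexity** — position/UMI-based PCR duplicate marking and a
  per-gene duplication-rate-versus-expression table.
- **TE screen** — descriptive translation efficiency
  `TE = (RPF TPM + 0.01) / (RNA TPM + 0.01)` per condition (replicates
  averaged on the log2 scale) and a strict fold-change screen for genes
  whose TE loss under stress is restored by a co-treatment.
- **Synthetic fixtures** — a deterministic simulator that generates the
  genome, GTF, SAM, and FASTQ inputs with full ground truth, used by the
  test suite and available from the CLI.

## Worked example

```bash
# 1. simulate a small experiment (reference + rpf/rna libraries)
riboprof simulate --seed 5 --out fixtures/

# 2. curate the reference: mask, pick canonical transcripts, truncate CDS
riboprof modify-gtf -i fixtures/annotation.gtf -o curated.gtf \
    --truncate --trim5 45 --trim3 15 --protein-coding --canonical
```

This prints the curation report:

```
# reference curation report
protein_coding: 62 -> 62 records
canonical: 62 -> 62 records
truncate: 62 -> 56 records {'n_truncated': 5, 'n_skipped': 0, 'skipped': []}
```

All five simulated genes were truncated: each coding length shrank by
exactly 60 nt, the five `start_codon` records left quantification space,
and one CDS record was consumed whole by the recursion (hence 62 → 56
records). Then count and normalize:

```bash
riboprof count -i fixtures/rpf.sam -g curated.gtf --feature CDS -o counts.tsv
riboprof normalize -i counts.tsv -g curated.gtf --method tpm -o tpm.tsv
riboprof phasing --sam fixtures/rpf.sam -g fixtures/annotation.gtf -o phasing.json
```

`counts.tsv` is an HTSeq-style table (genes × samples with trailing
`__no_feature` / `__ambiguous` / `__too_low_qual` rows); TPM columns sum to
10⁶. `phasing.json` reports the estimated P-site offset per read length and
the frame counts — a healthy footprint library concentrates P-sites in
frame 0, and this simulated one does: `"frame_counts": [988, 0, 0]`.

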