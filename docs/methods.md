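# Methods

## Coordinate model

GTF files are 1-based with inclusive ends; all internal computation uses
0-based half-open intervals, converted exactly once at the I/O boundary.
This makes the truncation arithmetic (`new coding length = old − trim5 −
trim3`) exact without ±1 bookkeeping. The attribute column is preserved as
an ordered multi-map with per-key quoting, so parse → serialize is the
byte identity on Ensembl-dialect files; GENCODE-style unquoted values are
accepted on input and round-trip with their original quoting. Records with
strand `.` remain in the file but are excluded from transcript assembly
with a warning, and records lacking biotype attributes pass through the
parser untouched.

## CDS truncation

Truncation operates in coding space, oriented with the transcript: the 5′
end is the lowest genomic coordinate on `+` and the highest on `−`. The
defaults remove 45 nt from the 5′ end and 15 nt from the 3′ end — the
field's convention for excluding initiation/termination pile-ups — and
recurse across intron-split CDS segments: a terminal segment shorter than
the remaining trim is deleted whole and the remainder is taken from the
next segment. Exon and UTR records are never modified; truncation
redefines quantification space, not transcript structure. Transcripts
whose coding length is ≤ trim5 + trim3 + 3 (one codon must survive) are
returned unmodified and flagged `truncation_skipped` — emitting zero- or
negative-length CDS records would corrupt downstream counting.
`start_codon` records are dropped once trim5 ≥ 3 (the annotated start is
no longer in quantification space); `stop_codon` records are kept, since
the Ensembl CDS excludes the stop codon. Frames are recomputed along the
truncated records: the first retained base gets frame
`(3 − trim5 mod 3) mod 3`, propagated segment-to-segment as
`(3 − (len − frame) mod 3) mod 3`.

Canonical-transcript selection prefers the `Ensembl_canonical` tag, then
longest CDS, longest exonic length, and finally smallest transcript id —
an explicit total order so output is reproducible on untagged input.

## Coverage profiles

All profiles work in exon space: introns are collapsed via a bijective
map with position 0 at the transcript 5′ end. A read's meta-coordinate is
its 5′-most exonic position (strand-aware), the natural summary for
footprints whose biological signal is the P-site at a fixed offset from
the 5′ end. The metagene profile bins each transcript's positional counts
into B equal-width bins (position → bin `floor(B·pos/L)`, so uniform
expectations carry a ±1-position remainder tolerance), normalizes each
transcript's vector to sum to 1, and averages with equal weight over
transcripts with ≥ `min_coverage` reads (default 10, mirroring the
count-filter convention used elsewhere in the package). Equal weighting
makes the profile invariant to any one transcript's depth — the
"super-expressor damping" property, asserted bit-exactly in the tests.
Reads are attributed to every transcript whose exons they overlap by ≥ 1
base: the metagene is descriptive QC, not quantification, and this choice
maximizes profile stability.

Phasing estimates one offset per read length as the modal distance from
footprint 5′ ends to annotated start codons, over reads whose 5′ end lies
within 50 nt upstream of a start; ties break toward the smaller offset.
Read lengths with no start-proximal reads of their own inherit the pooled
(all-lengths) modal distance rather than an arbitrary constant — an
uninformed per-length guess would scramble the frame statistics of rare
lengths. Only when no reads at all lie near starts does the estimator
fall back to a fixed offset (default 16 nt) with a warning. P-site = 5′ end + offset in
transcript orientation; frames are counted only for P-sites inside the
CDS.

## Counting and normalization

Counting follows intersection-nonempty semantics at the gene level: for
each read, per-base sets of gene ids covering that base are formed
(deletions are bridged; N gaps are not covered), empty sets discarded,
and the remaining sets intersected. |set| = 1 counts for the gene; 0 is
`no_feature`; > 1 is `ambiguous`. Gene-level (not transcript-level) sets
mean a read overlapping several isoforms of one gene is not penalized.
Counting is unstranded by default (`--stranded yes|reverse` available);
secondary/supplementary alignments are always excluded; `too_low_qual` is
populated only when a MAPQ threshold is requested. Per sample,
`Σ counts + no_feature + ambiguous + too_low_qual = reads processed`
exactly. Feature lengths are per-gene unions of the feature's intervals
across isoforms.

Normalization excludes the special counter rows, so denominators are the
counted-gene totals. FPKM equals RPKM (single-end semantics — footprint
libraries are single-end). Batch correction is deliberately not
implemented; the CLI flag exists and points the user to dedicated methods.

## Duplicates and complexity

The duplicate key is (chromosome, strand, 5′-most aligned position,
aligned length, and UMI when enabled) — aligned length rather than full
block identity, which is robust at footprint length scales. The highest
MAPQ (tie: smallest read id) member represents each group. Duplicates are
flagged, not removed: by default quantification keeps them, and the flags
feed only the per-gene duplication-rate-versus-expression table, since
duplicate removal is usually overly stringent for properly prepared
libraries. Note that without UMIs, distinct molecules of a short,
highly expressed CDS collide on coordinates, so the coordinate-only rate
upper-bounds the true PCR rate; the simulator-recovery tests therefore
run UMI-aware.

## rRNA probe design

Over-representation is exact-sequence counting with an inclusive
`count/total ≥ min_fraction` rule (default 0.001, the usual
over-representation convention) and a 17-nt minimum (the footprint window
floor). Cross-sample merging closes the exact-substring relation
transitively (union-find over all pairs); the longest member represents a
group and per-sample counts are preserved, so total counts are conserved
and the result is independent of sample order. Reverse complements are
not merged — depletion probes are strand-specific. Fuzzy matching and
rRNA identity assignment are out of scope; the ranked list is handed to
the user for probe design.

## Translation-efficiency screen

TE is computed descriptively: both matrices are TPM-normalized
independently, 0.01 is added to each TPM (small enough to be negligible
above ~1 TPM while keeping log ratios finite), and replicate log2 TE
values are averaged within condition — the geometric mean of ratios,
symmetric in the up/down direction. The screen applies the strict
fold-change paradigm on three conditions: `down_in_stress` when
TE(stress)/TE(untreated) ≤ 1/threshold, `restored_by_cotreatment` when
such a gene also has TE(cotreat)/TE(stress) ≥ threshold, with mirror
definitions for up/reversed; both comparisons are inclusive, and raising
the threshold can only shrink each category. Count-model statistical
testing (e.g. a negative-binomial interaction test) is intentionally
delegated: `significance_filter` accepts externally computed p-values and
applies Benjamini–Hochberg (FDR 0.1, |log2 FC| > 1 defaults). The
descriptive estimator will disagree with count-model estimators for
low-count genes, which is why the RNA-side low-count filter (every RNA
sample ≥ 10 reads, inclusive) is applied first.

## Synthetic data

The generator is the package's source of test inputs and ground truth.
Genes have 2–4 exons, 300–900 nt CDS (codon-rounded), 60–150 nt UTRs, and
alternate strands; the stop codon sits between CDS and 3′ UTR per Ensembl
convention. Footprint lengths follow a discrete triangular distribution
over 17–33 nt peaked at 28 nt. RPF P-sites are codon-aligned (pure frame
0) at a fixed 12-nt offset from the 5′ end; RNA reads place 5′ ends
uniformly over the transcript with 3′-clamped lengths, so uniform
simulations give flat 5′-end profiles. End pile-ups are modeled as P-site
enrichment maximal at the initiation/termination codon and decaying
exponentially over the first 45 / last 15 coding nt: real initiation
pauses are sharply peaked at the start codon, and a flat elevation would
make the modal offset estimator unidentifiable (every distance within the
window equally likely). PCR duplication draws `n·(1−rate)` distinct
molecules and re-samples the remainder uniformly among them; UMIs are
random 10-mers per molecule, appended to read names after the final `_`.
Contaminant reads are full rRNA fragments (30% of the time a ≥17-nt
substring) at the configured fraction of the FASTQ, emitted to FASTQ
only. All sampling derives from a single seed (sample/assay streams are
split deterministically), so fixed seeds give byte-identical files.

The count-level TE experiment plants "restored" genes at a 5-fold TE loss
under stress (not exactly 2-fold: TPM renormalization shifts every gene's
TE by a small global constant, and an effect placed exactly at the screen
threshold would straddle it); with `noise_cv = 0` counts are exact
expectations, otherwise Poisson draws around log-normally perturbed means.

What the simulator does **not** model: sequencing errors and quality
variation, length-dependent P-site offsets, nucleotide-composition
(ligation/CircLigase) biases, multimapping, and real rRNA homology.
Passing tests therefore demonstrate the correctness of the arithmetic and
the estimators under the stated generative model, not robustness to every
artifact of real libraries.

## Problem sizes and numerical choices

The test suite and acceptance checks run on deliberately small problems —
5–6 genes, 1 000–9 000 reads, 200 randomized truncation models, count
matrices of 300–2 000 genes × 18 samples — sizes at which the brute-force
oracles (base-by-base truncation, per-base counting sets, O(n²) substring
closure) are exact and fast. Tolerances: TPM column sums at 10⁻⁶
relative; metagene flatness at 4σ of binomial bin noise under a fixed
seed; duplication-rate and phasing-offset recovery at the resolution the
sampling noise of the stated read depths supports (±0.05 and ±1 nt).
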