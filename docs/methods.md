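# Methods

## Read classification model

Each amplicon read is assumed to be adapter-trimmed and (for paired-end
data) merged before it reaches the classifier; the package performs no
merging or quality trimming. Reads are aligned globally (end-to-end) to the
wild-type amplicon and, when the target programs substitutions, to the
expected-HDR amplicon, under affine-gap scoring with defaults match +2,
mismatch −1, gap-open −5, gap-extend −1 (gap-open is charged for the first
base of a gap). These scores favour compact indels of the kind double-strand
break repair produces; they are exposed in `ClassifierConfig` because
different amplicon lengths or error profiles may warrant different values.
Identity is the fraction of alignment columns that match, with gap columns
in the denominator — the conservative reading of "percent similarity".

Among co-optimal alignments the aligner's traceback picks one
deterministically; all indels are then shifted to their leftmost equivalent
placement on the reference (deletions slide while `ref[s−1] == ref[e−1]`,
insertions rotate), which makes event coordinates canonical. Microhomology
is measured on the wild-type reference at the normalized deletion
coordinates, as the larger of the two one-sided extensions of the junction;
split homology on the two sides is not summed, and when a read carries
several windowed deletions the maximum decides MMEJ status. Because
left-normalization maps every equivalent placement to the same coordinates,
classification is invariant to where the aligner happened to put a deletion
inside a repeat tract.

Decision thresholds: reads under 70 % identity to the wild-type amplicon are
discarded (boundary inclusive — exactly 70 % keeps); indel and substitution
evidence is restricted to ± 20 bp windows around each guide cut site (windows
are unioned when guides are close, and each guide is anchored on its own cut
for paired-nickase designs); HDR additionally requires ≥ 95 % identity to the
expected-HDR sequence over the full alignment, not just the window. An
indel-free read with only part of the programmed substitution set is called
WT but flagged `some` in the per-read record for auditing. Reads carrying
both insertions and deletions in the window are MMEJ if any deletion
qualifies, else NHEJ. Substitutions other than the programmed ones never
affect the category — they are treated as sequencing errors. One consequence
worth knowing: a sequencing error that lands exactly on a programmed
substitution position in a true HDR read demotes it to WT/`some`; at the
default error rate this affects ~0.1–0.2 % of HDR reads and is visible in
the simulation round trips.

## Aggregation

Percentages are computed over non-discarded reads. The HDR-to-error-prone
ratio is HDR % / (NHEJ % + MMEJ %), undefined (an error, not infinity) when
the denominator is zero; it is scale-invariant, so counts and percentages
give the same value. Averages across targets or replicates are unweighted
arithmetic means of per-run percentages; both the ratio-of-averages and the
mean of per-run ratios are provided, because the two disagree whenever
per-run denominators vary. Fold-changes are reported to one decimal.

## Clone genotyping

Reads from a colony are collapsed into alleles by their windowed alignment
signature — the left-normalized windowed indels plus the presence pattern of
the programmed substitutions — so isolated sequencing errors never split an
allele. Zygosity thresholds: a colony needs ≥ 50 reads (`depth_floor`); one
allele with ≥ 80 % of reads is homozygous (`majority`); two alleles each with
strictly more than 25 % (`het_minor`) and jointly ≥ 80 % are heterozygous;
anything else — including three substantial alleles — is not clonal and is
never forced into a diploid call. The minor-allele bound is deliberately
strict (>, not ≥) so that a 60/25/15 colony is rejected rather than called
heterozygous on the strength of an exactly-boundary minor allele. These
numbers quantify the qualitative notions of a "clear majority" and "similar
read counts"; they are exposed in the API and CLI and logged in every
report.

The multiplexing question — are edits at different genes independent? — is
answered by comparing the fraction of clonal colonies homozygous for the HDR
allele at every target with the product of per-target homozygous
frequencies. Colonies with any low-depth or non-clonal call are excluded
from both numerator and denominator.

## Lineage WGS stage

Input is a three-sample VCF (per-sample GT, DP, AD; alt-allele frequency is
AD[alt]/DP) plus BED masks; full VCF semantics (multi-allelic records,
phasing, likelihoods) are out of scope. A site survives filtering iff it is
outside all masks, every line's depth is within the inclusive corridor
[30, 50], and the spread (max − min) of alt-allele frequencies across the
lines is ≥ 0.30. Era assignment uses called genotypes, not frequencies:
alt in both descendants but not the ancestor → WT-era mutation; alt private
to the last clone → KR-era; alt in all three → ancestral; every other
pattern (e.g. alt lost along the chain) → unassigned, never silently
recounted. Coverage is summarized as mask-aware mean depth in 1 Mb windows;
windows with under 10 % unmasked bases are reported missing rather than as a
misleading mean. A loss-of-heterozygosity query reports runs of ≥ N
consecutive sites heterozygous in the ancestor but homozygous in both
descendants (N configurable); no break-induced-replication inference is
attempted.

The per-passage mutation-fixation rate is (n_novel / passages) ×
(genome_bp / surveyed_bp). `genome_bp` has no default in the CLI report
path: extrapolation is meaningless without an explicit genome size, so the
rate section is withheld with a warning when it is absent. With the commonly
used 3.2 Gb for the human genome, 19 novel variants over 48 passages in a
62.1 Mb surveyed fraction give ≈ 20.4 fixations per passage, and 3 over 24
give ≈ 6.4.

## Synthetic data

The generators emulate the three data types the pipeline consumes, with the
truth recorded per read/site:

* **Amplicon read sets.** A 200 bp amplicon with one cut site at the centre;
  repeat pairs (unit lengths 2–5 by default, spacer 1 bp) are planted inside
  the quantification window so that deleting one repeat copy plus the spacer
  leaves a junction with exactly the requested microhomology — verified
  against the classifier's own microhomology measure, with the whole
  amplicon redrawn if flanking sequence accidentally extends a junction.
  One targeted and one blocking substitution sit inside the window, clear of
  the planted repeats. Outcome proportions are drawn per read; NHEJ indels
  are 1–10 bp (truncated geometric, p = 0.5), insertions or deletions with
  equal probability, deletions redrawn until junction microhomology ≤ 1 and
  until their left-normalized placement stays inside the window; MIX indels
  additionally avoid the programmed substitution positions so the planted
  category remains well-defined. Errors are independent uniform base
  substitutions (default 0.001/base); error indels are not simulated, and
  Illumina-specific error structure (quality decay, context effects, PCR
  duplicates) is not emulated — passing round trips therefore demonstrate
  correctness of the decision procedure under idealized noise, not
  robustness to platform artefacts.
* **Colony read sets.** Per-colony diploid genotypes over named alleles
  (WT, HDR, or an explicit deletion); heterozygous colonies emit their two
  alleles 50/50 binomially at the configured depth (default 100).
* **Lineage tables.** Planted ancestral/WT-era/KR-era sites whose depths are
  drawn inside the coverage corridor and whose alt-read counts are clamped
  to keep the cross-line frequency spread ≥ 0.4, so planted sites pass the
  filters by construction; noise sites each violate exactly one filter
  (depth outside the corridor, spread < 0.3, or masked position), cycling
  through the three violation types.

Every generator is a pure function of its seed and recipe (byte-identical
on re-run).

## Problem sizes and numerical choices

The simulation round trips run at 10,000 reads for the classifier (all five
categories recovered within 3 binomial standard errors of the planted
proportions), 200 colonies × 2 targets × depth 100 for genotyping (≥ 99 %
zygosity recovery; joint-homozygosity fraction within 3 SE of truth), and
18 planted + 50 noise sites for the lineage stage (exact recovery) — sizes
at which the binomial tolerances are meaningful while a full run stays in
the tens of seconds. Score ties in alignment are resolved by the
deterministic traceback plus left-normalization; insertions exactly on a
window edge count as windowed (inter-base coordinates make either convention
defensible; the inclusive one is used and tested). The 70 % and 95 %
identity thresholds and the 30–50× corridor are inclusive at their
boundaries.

## Known limitations

Quality scores are ignored (constant-quality FASTQ is emitted and accepted);
large structural variants, translocations and copy-number changes are out of
scope at every stage; the clone caller assumes a diploid locus; the lineage
stage trusts upstream mapping/variant calling and models only biallelic
SNV-like records. The HDR homology check is applied to full-alignment
identity; a window-restricted variant would be slightly more permissive for
long amplicons with dense outside-window errors.
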