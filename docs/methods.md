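# Methods

## Model and assumptions

A-to-I editing is observed as A>G mismatches between RNA reads and the
reference genome (on the minus strand, T>C on the reference plus
strand).  Two measurement regimes are implemented.

**Hyperediting detection** assumes editing by Adar on long dsRNA is
processive: true editing produces dense same-class mismatch runs, while
genomic SNPs and sequencing errors are positionally isolated.  Candidate
sites are called per pileup column for every non-reference allele with
more than five supporting reads (n_alt ≥ 6) and an editing level
strictly above 0.01, where the level is n_alt/(n_ref + n_alt) over bases
with quality ≥ 20 from reads with mapping quality ≥ 20.  Clusters are
maximal runs of same-contig, same-strand, same-class candidates with
consecutive gaps ≤ 100 bp and at least 3 members.  The window and
minimum size are this package's defaults (configurable): one read length
is the natural linkage scale for cluster evidence, and three sites is the
smallest run that is improbable under isolated-error models.

**Targeted-amplicon quantification** treats each sequenced molecule as an
independent Bernoulli draw of the edited allele at each site, so a
site's per-sample level estimate is binomial with SE √(p(1−p)/depth).
Reads are demultiplexed by exact 5′ barcode match (no error tolerance —
exactness keeps bins reproducible), aligned gaplessly to the panel by
minimizing mismatches over all amplicons, orientations and offsets
(reads over a 10% mismatch ceiling or tied between amplicons are
dropped), and counted as A or G on the transcript strand at quality
≥ 20.  Off-target sites are untargeted transcript-strand A positions
between the primers with ≥ 10 quality-passing G reads in some sample.

SNP masking excludes a site when the pooled matched-gDNA G-fraction
exceeds 1% (configurable; a heterozygote sits near 50%, a homozygote
near 100%), when the site appears in a user-supplied known-SNP list, or
— conservatively — when no gDNA evidence exists at all.

The retention cascade works per genotype: a sample–site cell is
"captured" iff its depth is ≥ 400; a site passes for a genotype iff
captured in ≥ 75% of that genotype's samples and the genotype's mean
level over captured samples is ≥ 2%; a site is retained when it passes
in every genotype.  The per-genotype audit attributes a failure to
coverage when no sample is captured, to incidence when some but fewer
than 75% are, and to the level floor otherwise.  Both the per-cell
coverage reading and the site-level incidence reading were genuinely
open design points; the cell-level choice makes the cascade monotone in
each threshold and reproducible from counts alone.

Differential editing compares per-sample levels between exactly two
genotype groups with Welch's unequal-variance t-test (two-sided by
default, matching how such group contrasts are conventionally reported);
raw p-values are reported, with Benjamini–Hochberg available behind a
flag and off by default.  Welch is computed from the closed form — 
t = (x̄−ȳ)/√(s²x/nx + s²y/ny) with Welch–Satterthwaite df — using sample
(n−1) variances; degenerate zero-variance inputs give t = 0, p = 1 when
means agree and a flagged p = 0 otherwise.

**Phasing.**  When ≥ 2 targeted sites share an amplicon, every read that
spans all of them with A/G bases at quality ≥ 20 contributes one joint
allele tuple; reads failing any condition are discarded whole (no
imputation, no per-base salvage — tuples stay complete).  Tuple
marginals equal site-level estimates exactly on the identically filtered
read set, which the tests assert.  Codon maps (coding-strand codon +
site offset, carried as panel metadata) translate tuples through the
standard genetic code: on the first packaged two-site layout the
unedited tuple reads LR and editing the second site recodes R→G; on the
second, double editing recodes T→A and I→V, i.e. AV.

**RRE scanning.**  FMRP recognition elements ACUK and WGGA (K = G/U,
W = A/U) are matched at every position with overlaps counted (the
overlap policy is configurable); U and T are unified on T internally.
Cross-species conservation is scored by exact substring occurrence of
flank-extended motif segments in a target CDS; the flank length is an
exposed parameter because the segment length used in the original
homology searches is not derivable, and counts are provably
non-increasing in flank.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_base_qual` / `min_mapq` | 20 / 20 | Phred floors for counted bases and reads |
| `he_min_edited_reads` | 6 | ">5 edited reads" candidate floor |
| `he_min_level` | 0.01 (exclusive) | candidate editing-level floor |
| `min_mismatch_reads` | 10 | off-target discovery support |
| `amp_min_coverage` | 400 | per-cell capture depth (criterion ii) |
| `amp_min_incidence` | 0.75 | captured fraction per genotype (criterion i) |
| `amp_min_level` | 0.02 | genotype mean level floor (criterion iii) |
| `cluster_window_bp` / `cluster_min_sites` | 100 / 3 | HE cluster geometry (package default) |
| `snp_max_gdna_alt` | 0.01 | pooled gDNA G-fraction ceiling (package default) |

Coordinates are 0-based half-open internally; every report renders
1-based positions.  Quality encoding is Phred+33.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
with defaults fixed once as the study conditions: two genotypes with 10
RNA samples and 3 gDNA samples each; 12 amplicons of 120 bp (20 bp
primers, 8 bp barcodes) at ~2,000× RNA / ~800× gDNA coverage with
log-normal per-amplicon efficiency (σ = 0.25) shared across samples and
a per-sample factor (σ = 0.08); uniform substitution error 10⁻³ at
constant Q30; editing levels drawn once from U(0.05, 0.45) with a +0.04
genotype shift planted at four single-site amplicons; one heterozygous
SNP on a targeted site and one homozygous SNP at an untargeted decoy
position, present in RNA and gDNA alike; and two two-site amplicons
whose joint haplotype distributions are anchored at an unedited-tuple
abundance of 43.2%/40.6% (WT/mutant) and a double-edited abundance of
9.8%/11.3% — the scale of variant-abundance contrasts this kind of assay
is designed to resolve — with the remaining mass split in fixed
proportions so that truth marginals equal per-site levels by
construction.  Transcriptome mode plants same-class HE clusters inside
repeat elements (inverted-repeat arms first; the second arm mirrors
arm-1 bases to keep the palindrome exact) over 76 bp gapless reads at
~30×.

What the generator does **not** emulate: alignment ambiguity and splice
junctions (reads are emitted pre-aligned or gapless), indels and
homopolymer errors, PCR duplicates, quality–error coupling (errors are
independent of the constant quality string), overdispersion of editing
levels across biological replicates beyond binomial noise, and
expression-level variation.  Passing tests therefore demonstrate the
correctness of counting, filtering, phasing and testing logic under the
stated sampling model — not robustness to alignment artifacts or
platform-specific error structure in real libraries.

`simulate_site_columns` additionally draws pileup columns directly from
the planted binomial model (10,000 sites at a 93:7 A>G:other class mix
in the spectrum study) so class-mix recovery can be measured at a scale
where read-level synthesis would add nothing.

## Numerical choices and degenerate inputs

Editing level at zero coverage raises a distinct error rather than
returning 0.  Deletions reduce depth (samtools-style) rather than count
as a fifth allele; N bases are discarded; overlapping read pairs are not
de-duplicated (single-end model).  Repeat families with edited sites but
zero genomic bases report an infinite fold flag.  Ambiguous amplicon
assignments (cross-amplicon mismatch ties) are dropped, not arbitrated.
Pearson correlation with zero variance, empty spectra and empty panels
are signaled errors.  Tie-breaking in annotation follows the fixed
precedence CDS > 3′-UTR > 5′-UTR > intron > intergenic; repeat
membership is orthogonal and resolves to the earliest-starting element.

## Problem sizes

The test suite and acceptance script are sized for a single CPU:
spectrum recovery at 10,000 sites × 200×; null calibration at 1,000
sites × 10 samples/group; brute-force oracle equivalence at 100 seeded
trials per component on ~25–80 bp instances; and one full study at the
default conditions above (~500k reads), which completes in roughly half
a minute.

## Known limitations

Only exactly two genotype groups are supported in differential ops.  The
gapless panel aligner is for synthetic/desk-scale amplicon data;
externally aligned SAM is the intended input for real libraries.  BAM,
GFF3 and spliced CIGARs (N) are out of scope; spliced records are
skipped with a warning.  The HE caller starts from final alignments and
does not re-map heavily edited reads, so sites whose reads fail to align
upstream are invisible to it.
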