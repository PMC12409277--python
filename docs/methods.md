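# Methods

This note documents the models, parameter choices and numerical conventions
behind `sedsift`, and what the synthetic-data generator does and does not
emulate.

## The damage model

Post-mortem cytosine deamination is modelled as a geometric decay from the
fragment end: the probability of observing C→T at 1-based distance *i* from
the 5′ terminus is

    rate(i) = floor + (peak − floor) · decay^(i−1)

with defaults peak (δ₅′) = 0.2, decay = 0.6, floor = 0.01. For
double-stranded library preparation (the default) the model is symmetric:
G→A at distance *j* from the 3′ end with the same magnitudes. The
geometric form is the standard single-strand-overhang approximation; its
virtue here is parameter recoverability — weighted least squares on the
first ten positions of the 5′ C→T curve (`damage.fit_damage_model`)
recovers peak and decay within ±10% relative error at 20,000 reads, and
the position-wise estimates sit inside 99% binomial intervals of the curve.
The default magnitudes are generator conventions chosen to be typical of
well-preserved ancient material (terminal deamination in the 10–30% range);
they are not fitted to any particular dataset.

Contaminant reads are drawn from a designated modern source with damage
forced to zero — the authentication logic rests exactly on this contrast.

## The synthetic-data generator

`simulate` produces: taxon mixtures with truncated-lognormal fragment
lengths (log-mean log 55, log-sd 0.35, truncated to [30, 150] bp — short
fragments typical of degraded DNA); per-read uniform placement and strand;
deamination as above; uniform sequencing error (default 10⁻³); constant
Q37 quality strings; exact truth alignments with MD/NM tags; sex-chromosome
read counts proportional to copy number × chromosome length (XY: one X and
one Y at half the autosomal rate; XX: a configurable Y-mis-mapping noise
floor); Poisson-depth allele pileups with a binomial contaminant fraction
per covering read; KrakenUniq-style classification reports built from exact
(reference, offset) k-mer sets; and PSM tables whose peptides are true
substrings of one species' proteins in a two-species homolog database with
planted single-residue diagnostic differences.

Randomness is split into named sub-streams (taxon choice, fragmentation,
damage, error, contamination) spawned from the master seed, so toggling one
model never perturbs the draws of another, and identical (config, seed)
yields byte-identical outputs.

What the generator does **not** emulate: indel damage, single-stranded
library 3′ asymmetry, base-quality miscalibration, k-mer collisions between
genomes, chimeric reads, GC-biased coverage and classifier
misclassification. Tests passing on this generator therefore demonstrate
the correctness of the decision logic and estimators under the stated
models, not robustness to every artefact of real sequencing data.

## E-score strategies

The default E-score is the literal algebra `(unique_kmers / reads) / cov`.
When a report's `cov` column equals unique k-mers over genome k-mers — as
it does by construction in the synthetic reports — this expression cancels
to `genome_kmers / reads` and carries no dispersal information. The formula
is therefore exposed as a strategy seam: `kmers_per_read_escore` (unique
k-mers per read) is included as a dispersal-sensitive alternative, scoring
near 1 for clonal read stacks and near the per-read k-mer yield for
dispersed hits. All retention thresholds (≥7) apply to whichever strategy
is active. In the end-to-end flow, clonal exact-duplicate reads are
additionally collapsed by QC deduplication, so a locus-saturated taxon
fails the genus mitochondrial-hit rule (>3 read hits) regardless of
strategy.

## Decision thresholds

All thresholds live in one place per module and are the field-standard
values: QC length 30 bp / mean Q20 / DUST 7; E-score 7, reads 10, relative
abundance 0.02%, genus mito hits >3; assignment MAPQ ≥30; damage-summary
gate >100 mapped reads; Ry 0.016/0.077; consensus depth ≥5, GQ ≥20,
minority:majority recode boundary 1/9 (inclusive); imputation MAF ≥0.05 and
GP ≥0.98 (both inclusive — where sources print both ">0.98" and "98% and
higher", the inclusive reading is implemented and pinned by test); dosage
hard-call threshold 0.1 (plink's default, distance-to-nearest-integer
rule, with 1e-9 slack against binary-float representation of decimal
boundaries); PSM score ≤0.01 with ≥2 PSMs; ≥2 unique peptides per protein;
partial-protein coverage ≥5%.

Boundary semantics worth noting: "quality below 20" is read as *mean* read
phred (the common screening practice; per-base filtering would not be
monotone under trimming); the DUST statistic is pinned to the windowed
overlapping-triplet score (window 64, step 32, removal strictly above the
threshold) so a numeric threshold of 7 is reproducible without external
tools; deduplication is exact-sequence because it runs pre-alignment.

## Sex classification

The read-ratio classifier compares the Ry point estimate against
0.016/0.077; the binomial 95% CI is reported but not used for the decision.
The coverage estimator is oriented Y-over-X (male: X and Y each at half the
autosomal copy number so r ≈ 1; female: r ≈ 0), with decision bands
0.25/0.75 as package defaults — the verbal rule this encodes ("near 1 male,
near 0 female") fixes the orientation but no published band, so the bands
are deliberately wide and symmetric.

## Contamination and individuality

The contamination estimator pools minority over (majority + minority)
allele depths across user-annotated diagnostic sites; it is the maximum
likelihood estimator of the admixture fraction when the two haplotypes
differ at those sites, and simulation (500 replicates, 50 sites × depth
100) shows mean bias within 0.005 at c ∈ {0.01, 0.05, 0.10}. Diagnostic
site selection is an explicit input, not automated.

The heterozygosity screen requires two alleles each at ≥10% of a ≥5× site;
the 10% minor-allele floor is a package choice that prevents single
sequencing errors from being counted as heterozygous evidence. Transition
pairs (C↔T, G↔A) are excluded as candidate deamination artefacts, so the
verdict rests on transversion-heterozygous sites only.

For pileup-only consensus input, `genotype_quality_from_depths` supplies a
phred-scaled majority-vs-minority likelihood ratio under a symmetric 1%
error model; it is a convenience score for data lacking a caller GQ, not a
genotype-caller reimplementation, and any caller-provided GQ takes
precedence.

## Competitive assignment

Minimal edit distance is the best-hit criterion, with MAPQ as tie-breaker
and residual ties discarded: authentication favours specificity over yield,
and a read that cannot distinguish two references should support neither.
Coverage in the per-taxon summary is breadth-agnostic mean depth (aligned
bases / genome length). Both separate per-reference SAM files and a single
multi-reference file are accepted; the decision logic is identical.

## Concordance conventions

Pseudohaploid calls draw one covering base uniformly per site (seeded);
bases matching neither panel allele become missing. Concordance excludes
pairs with any missing code from numerator and denominator by default (a
flag includes them as discordant); it is symmetric, and the worked example
109 markers / 29 discordant evaluates to 73.39…%, printed as 73.4%.
Transitions are not excluded from concordance by default; a
transversions-only mode is available.

## Peptide discrimination

Matching is exact-substring with I/L equivalence on by default (isobaric
residues are indistinguishable by mass spectrometry). Tryptic termini are
not enforced — the module validates search-engine output rather than
re-searching spectra — and a strict-tryptic flag exists for callers who
want it. Modifications in parentheses are stripped for matching and
retained for the PTM-proportion report. Diagnostic residues are reported by
scanning, for each diagnostic peptide, same-length windows of the other
species' proteins and recording positions where a near-identical homologous
window differs; windows differing at more than max(2, length/5) residues
are treated as non-homologous and skipped.

## Problem sizes

The test and acceptance workloads use 200–20,000 reads, 50-site pileups at
depth 100 with up to 500 replicates, 100-seed sex-classification sweeps and
1,000 random two-species protein databases. These sizes were chosen so
every stochastic check has comfortable statistical power (binomial CIs at
n = 20,000 are ±0.7 percentage points at rate 0.2) while the whole suite
remains quick to run; estimator behaviour at these sizes is representative
because every estimator here is a ratio or count statistic whose error
scales as 1/√n.

## Known limitations

The pipeline consumes classifier reports and alignments; it never runs
classification or alignment itself, so garbage-in propagates. The E-score
default carries no dispersal signal when cov is exactly proportional to
unique k-mers (see above). The contamination estimator assumes exactly two
haplotypes at diagnostic sites. The damage model is substitution-only. The
coverage-sex bands and the heterozygosity minor-allele floor are package
defaults, not published constants, and should be revisited for unusual
data.
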