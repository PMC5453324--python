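# Methods

`chemopair` analyses matched trios — germline, pre-chemotherapy tumor,
post-chemotherapy tumor — to ask where the two tumor samples sit on the
clone tree and whether their differences could postdate treatment.  This
note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Observation model

At a germline-heterozygous locus in a tumor sample of cellularity
(tumor-cell fraction) ρ with local allele-specific copy numbers
(n_a, n_b), the expected read depth and the expected fraction of reads
carrying allele *b* are

    depth = d · (ρ·(n_a + n_b) + 2·(1 − ρ))
    BAF_b = (ρ·n_b + (1 − ρ)) / (ρ·(n_a + n_b) + 2·(1 − ρ))

where d is the haploid depth in reads per copy.  A clonal somatic SNV
present on m copies (its *multiplicity*) has expected variant allele
fraction VAF = ρ·m / (ρ·n_total + 2·(1 − ρ)).  Multiplicity is the clock
that orders SNVs against copy-number changes: an SNV acquired before a
gain of its carrying allele was duplicated with it (m ≥ 2, "early"),
one acquired after sits on one copy (m = 1, "late").

## Het-locus selection and smoothing

Candidate loci are filtered to autosomal sites with germline coverage in
[16, 90], at least 4 reads per allele, per-site strand bias (fraction of
forward reads) in [0.1, 0.9], and outside germline-CNV regions found by
segmenting the germline depth track and flagging segments deviating more
than 25% from the chromosome median.  "Strand bias" is read as the
per-site forward-read fraction (the test-statistic reading is possible;
the choice is configurable).  An optional stricter depth floor of 21
(`gatk_prefilter`) reproduces the intersection with an upstream caller's
low-coverage filter; default off, the [16, 90] rule being primary.
Depth and allele-fraction tracks are smoothed with a running median
(default window 51 loci; edges use shrinking windows).  Tumor depth is
normalised by the *smoothed* germline depth — dividing by the raw
per-locus count would inject 1/g noise and an upward E[1/g] bias of
roughly 2% at 50× that is large enough to push clonal segments off their
lattice centers.

## Joint segmentation

One breakpoint set per patient: at each candidate cut, a sliding-window
(default 200 loci) two-group ANOVA F statistic is computed on four
per-chromosome z-scored channels (depth and mirrored BAF × two samples);
the maximising cut is accepted if the largest channel F exceeds the
threshold (default 25) and the halves are split recursively, with a
minimum segment length of 20 loci.  The parametrisation is declared, not
derived; the procedure deliberately oversegments — downstream state
assignment and same-state merging absorb spurious breakpoints at little
cost, while a missed breakpoint would corrupt segment means.

Segment mirrored BAF is computed as the fold of the segment's *mean
unfolded* allele fraction, not the mean of per-locus folds: folding
first would bias balanced segments downward by σ·√(2/π).  Unfolded
fractions (anchored to the germline allele identities) are retained for
allele-consistency checks.

## Cellularity and haploid depth

A deterministic grid search (ρ in [0.05, 1] step 0.01; d in
[0.2, 1.2]·d̂ step 0.01·d̂, where d̂ is half the locus-weighted median
segment depth) scores each (ρ, d) by the locus-weighted squared distance
of every segment's (depth, BAF) mean to its nearest predicted state
center, channels scaled by robust (MAD) spreads.  A binomial/Poisson
Gaussian-likelihood objective is available behind `objective='loglik'`.

Two exact ambiguities shape the design.  Any solution admits a
genome-doubled re-scaling — states 2n at ρ′ = ρ/(2−ρ), d′ = d·(2−ρ)/2 —
that reproduces every center exactly, and an all-even profile admits the
halved re-scaling (ρ′ = 2ρ/(1+ρ), d′ = d·(1+ρ)); noise even favours the
finer-lattice (doubled) interpretation, because its extra interleaved
centers absorb segment-mean error.  Ranking therefore applies a soft
parsimony preference — scores are inflated by 0.3 per copy of implied
mean ploidy above 2 — so the lowest-ploidy member of an equivalence
class ranks first, while all near-ties (within 5% of the best adjusted
score and separated by > 0.05 in ρ or > 5% in d) are reported rather
than hidden.  Genuinely doubled genomes remain identifiable because real
doubled genomes carry odd post-doubling states (AAB and relatives) that
the halved model cannot represent; the synthetic generator includes such
states for the same reason.  Genomes whose segments all fall in a single
cluster (e.g. pure diploid) are flagged unidentifiable.

## State assignment and paired logic

Segments are assigned the nearest clonal state when their residual is
within 0.25 of that center's distance to its closest neighbour;
otherwise the best two-state mixture of states adjacent by one copy step
is fitted along the exact (depth, BAF) curve of cell-fraction mixtures
(the curve is linear in depth but not in BAF), with the fraction solved
on a 0.01 grid.  Wider mixture searches are deliberately excluded by
default.  Major-allele identity per sample comes from the segment's mean
unfolded fraction; paired calls whose major alleles disagree are flagged
as mirrored events, never overwritten.  Adjacent segments with identical
anchored state pairs are merged with locus-weighted means.

Genome metrics (bp-weighted over assigned segments): average ploidy;
amplified = total/ploidy > 2; deleted = total/ploidy < 0.5 — strict, so
a single-copy loss at ploidy 2 is *not* deleted (a flag switches to ≤);
LOH = minor copy number 0.

LOH incompatibility: LOH is irreversible, so a region with LOH in the
pre sample but retained heterozygosity in the post sample rules out the
post sample descending from the pre sample's clone and implies a shared
antecedent.  The reverse direction alone is compatible with linear
descent and is reported but not taken as evidence.  A minimum aggregate
span of 1 Mb (our choice; no published value exists) guards against
assignment noise.

Competing subclonal histories for a segment (e.g. subclonal loss from a
clonal AAABB versus clonal AABB with a later gain) are compared by the
likelihood of the segment's SNV allele fractions under binomial mixtures
at each scenario's predicted VAF centers, weights free (EM), scenarios
ranked by BIC; identical center sets or < 20 SNVs return "undetermined".
The observed number of populated clusters (weight ≥ 5%) is reported
against each scenario's expectation — a missing cluster is the
diagnostic signal.

## SNV timing and divergence

Timing is attempted only in states where the hypotheses separate:
AA, AAB, AABB, AAA, AAAA, AAAAB (our concretisation of "where states
and power allowed"; configurable).  Candidate multiplicities are
{1, n_a} (plus n_b if ≥ 2); the binomial likelihood of the alt count at
each candidate's expected VAF decides the call when the likelihood ratio
reaches 10 (m = 1 → late, m ≥ 2 → early), otherwise unclassified.  SNVs
in unassigned or subclonal-mixture segments are excluded from timing:
mixtures break the multiplicity lattice.

Divergence logic, on SNVs in duplicated (n_a ≥ 2), eligible regions:
f1 = fraction of classified lineage-private SNVs that are early;
f2 = fraction of classified shared SNVs that are late.  Early private
SNVs mean clonal diversity predates the copy-number changes; late shared
SNVs mean the changes predate diversity; neither places the divergence
near-synchronous with the doubling.  "Neither" is operationalised as a
one-sided binomial test at α = 0.05 against a residual misclassification
rate ε = 0.02, not a hard cutoff on the point estimate: with a few
hundred classified SNVs the point estimate fluctuates by ±0.01–0.02
around ε, and the test makes the verdict respect that sampling error.
Sensitivity: at ε = 0.01 the near-synchronous verdict starts misfiring
at cellularity ≈ 0.5 (observed misclassification ≈ 0.3–0.8% per sample,
but private-SNV denominators are small); at ε = 0.05 the
diversity-predates signal needs f1 ≳ 0.07 to register, which the
pre-doubling scenarios exceed by an order of magnitude.  A shared
fraction ≥ 0.9 of all SNV keys is additionally reported as recent
divergence, and the LOH shared-antecedent flag is propagated.

## Signatures

96-channel catalogs follow the COSMIC pyrimidine-strand convention.
Deconstruction into known signatures solves min ‖Pw − c‖² on the weight
simplex by exact active-set NNLS on a penalty-augmented system (the
sum-to-one constraint as a heavily weighted row, then renormalisation);
exposures under 1% are zeroed and renormalised.  De novo extraction uses
multiplicative-update NMF with multinomial bootstrap resampling,
components matched across resamples by Hungarian cosine assignment;
stability is the cosine silhouette, and the suggested k maximises
stability minus min–max-normalised Frobenius error.  The cisplatin test
counts C>A substitutions whose 5′ neighbour is C (the XpC reading of
"CpC"; the 3′ reading is available behind a flag), pools catalogs per
cohort, and applies a two-sided Fisher exact test to the
[CpC C>A, other] × [treated, naive] table.  Common-variant removal is a
user-supplied mask VCF hook; no population database is bundled.  The
COSMIC signature matrix is likewise a user input — tests and the
synthetic generator use deterministic sparse Dirichlet signature
matrices.

## Cohort statistics

Wilcoxon rank-sum comparisons use the exact null for combined n ≤ 25
without ties and the tie-corrected normal approximation otherwise;
constant data return p = 1.  Contingency proportions are computed in
exact rational arithmetic before rounding to one decimal percent;
chi-square (continuity-corrected) and two-sided Fisher p are both
reported.  Gene-recurrence proportions compare the fraction of samples
per cohort carrying ≥ 1 nonsynonymous variant, with per-gene Fisher
tests under Benjamini–Hochberg adjustment (our choice of correction).
The mutations/Mb denominator defaults to 2800 callable Mb, is always
user-overridable, and is recorded in output metadata.

## The synthetic generator

The generator emulates the clonal history the analysis assumes: a
diploid germline (het sites at mean 1500 bp spacing on a 10 Mb toy
genome over two pseudo-chromosomes) acquires truncal SNVs, LOH and
single-copy gains; optionally endoreduplicates; suffers truncal
single-copy losses after the doubling (producing the AAB-like odd states
that dominate real doubled genomes); and diverges into the two sampled
lineages with private SNVs and optional private LOH.  Reads are Poisson
in depth and binomial in allele counts (beta-binomial overdispersion
behind a knob, default off so analytic expectations stay exact);
trinucleotide contexts are drawn from a configured signature mixture and
written into a synthetic FASTA so context extraction exercises the same
code path as real data.  Defaults are the study regime: ~50× depth,
cellularity 0.75 (the cohort's ≥ 70% pathology threshold), 500 truncal
and 300 private SNVs per lineage.

All somatic SNVs ride on germline allele 'a' while LOH removes allele
'b', so no SNV is silently deleted by a later loss and sharing-class
counts are conserved exactly.  What the generator does *not* emulate —
mapping artefacts, GC waves, kataegis, subclonal SNVs within a sample,
contaminating structural variation — bounds what passing tests show:
they validate the inference logic under the stated noise model, not
robustness to real-data artefacts.

## Problem sizes and determinism

Simulated patients use 10 Mb genomes (~6700 het loci, ~1100 SNVs), which
keeps a full per-patient analysis under two seconds while leaving every
stage's statistics in their asymptotic regime; recovery-rate suites use
8–20 patients per scenario and 20–50 random purity models.  Every
source of randomness flows from explicit seeds; reruns of the pipeline
with the same configuration are byte-identical, and every output file
carries the configuration hash and seed.

## Known limitations

Two tumor samples per patient (no multi-region phylogenetics); no
chronological (mutation-rate) dating; subclonal mixtures restricted to
one-copy-step pairs; timing is undefined in mixture segments; the
cisplatin test is a pooled 2×2, not per-sample; de novo NMF is validated
on simulations only.
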