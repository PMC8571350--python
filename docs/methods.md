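# Methods

This note documents the statistical procedures `panelqc` implements, the
defaults and their units, the design choices made where several reasonable
options existed, and what the synthetic-data generator does and does not
emulate.

## Synthetic admixed cohorts

The generator produces the statistical structure the downstream analyses
assume, not sequence-level realism.

**Ancestral divergence.** Each site draws an ancestral alternate-allele
frequency p ~ Uniform(0.05, 0.95); the two ancestries ("African" and
"European") then draw frequencies from Beta((1−F)/F·p, (1−F)/F·(1−p)) with
F the divergence parameter (default `fst = 0.15`). This is the standard
Balding–Nichols construction; the uniform support avoids monomorphic sites.

**Admixture.** Individual African proportions are Beta-distributed with
mean `mean_admixture` (default 0.823) and concentration 10. Only the mean
is asserted anywhere; the concentration sets a realistic spread and is a
free shape parameter — no data source specifies the variance of individual
admixture proportions.

**Local ancestry.** Each haplotype is a two-state Markov mosaic along the
chromosome: ancestry is redrawn Bernoulli(α_i) at switch points placed with
probability 1 − exp(−ρ·d) per inter-site gap of d bp, ρ =
`ancestry_switch_rate`/1e6 (default 1 switch/Mb). Any mosaic with tunable
admixture serves the tests; no recombination-map realism is attempted.

**Pedigrees.** Children are explicit Mendelian recombinants: each gamete is
a crossover mosaic of the parent's two haplotypes. The default crossover
density is 1e−5 per bp — deliberately far above the physical ~1e−8 — because
the single simulated chromosome stands in for a whole genome ("compressed
genome" convention). At physical rates a 20 Mb chromosome carries ~0.2
crossovers per meiosis, so realized IBD between relatives is dominated by
whole-chromosome segregation variance (first cousins frequently share
nothing), whereas genome-wide kinship estimates average over thousands of
segments. The scaled rate makes realized IBD concentrate near its pedigree
expectation, which is the regime kinship-recovery checks presume. The rate
is a `PedigreeSpec` field for users who want chromosome-scale variance
instead.

Trios consume two visible panel founders; a duo consumes one (its co-parent
is hidden). Sibling and cousin pairs are grafted onto hidden founders drawn
site-independently from the panel's pooled empirical allele frequencies, so
only the named relatives join the panel and no unintended relatedness to
panel members is created. The default pedigree mix is 15 parent-child pairs
(one a full trio), three sibling pairs and seven first-cousin pairs. The
truth table records each related pair with expected kinship (0.25, 0.25,
0.0625) and expected IBD0 (0, 0.25, 0.75).

**Sequencing emulation.** Per call: depth ~ Poisson(`mean_coverage`,
default 15); alt-read count ~ Binomial(depth, q) with q = e, ½, 1−e for
true genotypes 0/1/2 and e = `base_error` (default 0.005, an aggregate
per-read allele error typical of short-read callers at the variant level);
the hard call maximizes the binomial likelihood under a flat genotype
prior; GQ is the phred-scaled posterior error probability capped at
`gq_cap` (default 99, matching caller convention); zero depth yields a
missing call. This reproduces the qualitative coverage behavior the
pipeline is sensitive to: at lower coverage, false negatives and genotype
errors rise faster than false positives (a hom-ref call needs no reads,
while detecting and genotyping an alt allele does).

**Microarray emulation** restricts the truth to a random site subset and
applies independent genotype errors (a wrong genotype is drawn uniformly
from the two alternatives).

**Dosage corruption.** Within each allele-frequency bin, dosages are
genotype + Gaussian noise clipped to [0, 2]. The nominal noise variance
Var(g)·(1−r)/r would give pooled squared correlation r without clipping,
but clipping attenuates noise preferentially at the boundary genotypes and
biases the realized R² upward by up to ~0.05 at intermediate frequencies.
The implementation therefore calibrates the noise scale by bisection
against the realized post-clipping pooled correlation on the data being
corrupted (deterministic given the seed), so the requested per-bin R² is
achieved rather than approximated.

### What the generator does not emulate

No linkage disequilibrium beyond the ancestry mosaic; no recombination
maps, gene conversion or mutation; no read-level artifacts (mapping error,
strand bias, indel realignment); no array probe chemistry (cluster
separation, batch effects); contamination enters only as a metadata number.
Consequently, passing tests demonstrate the *statistical machinery* —
estimators, filters, vote/splice logic, binned correlation — under the
stated generative assumptions, not robustness to the full error structure
of real sequencing data.

## Sample QC and relatedness

Samples fail QC below 3× aligned coverage or above 5 % contamination
(strict inequalities; both thresholds are arguments).

Kinship uses the heterozygote-normalized robust estimator
φ = (N_AaAa − 2·N_AA,aa)/(N_Aa,i + N_Aa,j) over pairwise-complete sites,
requiring at least 100 informative (heterozygous) sites. IBD0 is the
opposite-homozygote count divided by its expectation under unrelatedness
and HWE, 2·Σ p²(1−p)², with p the cohort allele frequency (passing cohort
frequencies is strongly preferred over the pair-only fallback). Duplicates
give exactly φ = 0.5 and IBD0 = 0 with complete data.

Degrees follow the standard bands at powers of 2^(−1/2): φ > 0.354
duplicate; (0.177, 0.354] first degree, split by IBD0 < 0.1 into
parent-child vs sibling; (0.0884, 0.177] second; (0.0442, 0.0884] third;
otherwise unrelated.

Pruning removes identified children first (in a trio, the sample with
parent-child edges to two mutually-unrelated partners; in a duo the
orientation is unidentifiable from kinship alone, so the lower-coverage
member is removed as the assumed child, consistent with preferring
higher-quality data). Remaining related components must be pairs — anything
larger raises an error listing the component — and each pair keeps its
higher-coverage member, ties broken by removing the lexicographically
larger id.

**Known behavior.** The robust estimator is unbiased for pairs drawn from
the same (possibly admixed) population, but a *contrast* in admixture
between two individuals biases φ away from zero — in the default synthetic
cohort unrelated founder pairs with very different African fractions reach
|φ| ≈ 0.04, still below the third-degree band but visibly non-zero. This
mirrors the estimator's real-world behavior and is why unrelated-recovery
checks use ancestry-homogeneous pairs. At small site counts (≲1000) this
bias plus sampling noise can create spurious third-degree edges and hence
unresolved-clique errors during pruning.

## Site filtration

Per-site statistics exclude missing genotypes from genotype counts and
AC/AF denominators. A site fails if any enabled rule fires; reasons record
every firing rule:

* **singleton** — alternate allele count exactly 1 (alt-oriented, not
  minor-allele count; configurable);
* **missingness** — missing fraction strictly above the threshold;
* **hwe** — exact conditional Hardy–Weinberg p-value below the threshold.
  The test enumerates all heterozygote counts consistent with the observed
  allele counts and sums the probabilities of configurations no more likely
  than the observed one (probability-ordered two-sided; not mid-p). The
  implementation evaluates the conditional distribution in log space with a
  1e−9 relative guard for probability ties; an exhaustive sweep against an
  exact-rational enumeration oracle over all configurations with n ≤ 50
  agrees to < 1e−12.
* **expected_correct** — mean over called genotypes of 1 − 10^(−GQ/10)
  below the threshold. Missing calls are excluded; a matrix without GQ
  skips the rule. Note that a uniform GQ of 5 gives 0.684, *above* the 0.60
  default — only GQ ≲ 4 fails it.

Presets: `dvglx` = (HWE ≥ 1e−20, missingness ≤ 0.20, expected-correct
≥ 0.60, drop singletons) and `gatk` = (missingness ≤ 0.10, drop singletons,
no HWE or GQ rule). The filter is monotone: tightening any threshold never
rescues a failing site.

## Truth-set curation

**WGS consensus**: site set = intersection of two callers' variant keys;
per call, genotypes are blanked when the callers disagree or either GQ <
20; sites with more than 10 % blanked calls are dropped; surviving sites
are restricted to confident regions minus an exclusion mask (interval
subtraction on 0-based half-open coordinates).

**Microarray truth**: a probe's site survives only if it is autosomal,
meets database call-rate (≥ 0.90) and MAF (≥ 1e−5) gates, is polymorphic in
the cohort (minor allele count ≥ 1), has exactly one exact full-length
match in the reference consistent with its vendor coordinates, its 50 bp
footprint overlaps no common variant (AF > 0.01) other than its own target,
and its footprint overlaps no other probe's (both members of an overlapping
pair are dropped). Probe alignment is emulated as unique exact substring
search — at this scale the MAPQ = 60 / edit-distance 0 / no-clipping
alignment conditions collapse to exactly that — and a hook accepts
precomputed placements for real data. Forward-strand matching only; indel
probes are handled identically to SNP probes by footprint. Homozygous-
reference genotypes contribute to the confident regions but are not
emitted as variant records.

## Chunk planning and ligation

Fixed-length plans start chunk k at k·(target − overlap) (defaults 10 Mbp /
400 kbp); the final chunk ends at the interval end and is merged into its
predecessor if shorter than the overlap. Marker-count plans group
consecutive markers into cores (boundaries at midpoints between flanking
markers) and extend each chunk leftward by the overlap.

Ligation resolves each downstream chunk's orientation per sample by
majority vote over heterozygous sites shared in the overlap — robust to
isolated phase errors, unlike first-het anchoring — and splices at the
median shared heterozygote (any overlap-interior point would do; the median
is deterministic). A vote tie or an overlap with no shared heterozygote
keeps the same orientation and logs a warning. Ligation never alters
genotypes (asserted), and any pattern of whole-chunk flips on internally
correct chunks is recovered with zero switch errors. Statistical phasing
itself is out of scope; in tests "phased chunks" are truth haplotypes with
injected flips.

## Imputation evaluation

Aggregate R² is the squared Pearson correlation of *pooled* (sample,
variant) pairs within an allele-frequency bin — not the mean of
per-variant R² — matching how panel comparisons pool all genotypes in a
bin. Default bin edges are
0, 1e−4, 2e−4, 5e−4, 1e−3, 2e−3, 5e−3, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0
(half-open, last bin closed); edges are configurable and recorded in the
report. In `penalize` mode, truth variants absent from the imputed set
contribute pairs with dosage 0.0 (imputed homozygous reference), penalizing
panels with missing variation; `intersect` mode skips them. Missing truth
genotypes are skipped pairwise; truth variants without an AF annotation
are dropped and counted; bins with zero variance in either pooled vector
are reported as undefined rather than 0.

Discordance hard-calls dosages by rounding, ties at x.5 toward the smaller
genotype (declared for determinism; whether real evaluations used hard
calls or posteriors is unknowable from outside). NRD excludes comparisons
where both truth and call are homozygous reference from numerator and
denominator, so NRD ≥ overall discordance whenever such pairs exist.
Completeness stratifies truth variants by allele count (1, 2, > 2) and
type (SNP vs indel) and reports the fraction present in a panel's site
set; empty strata are undefined, not zero.

## Benchmarking

Matching is at key level (chrom, pos, ref, alt) after left-alignment and
multiallelic splitting, without haplotype-aware realignment of complex
representations — a documented divergence from full hap.py semantics on
complex indel clusters. Per confident-region truth record: TP if a query
record matches key and genotype; FP.gt if the key matches but the genotype
differs; FP.al if only the position matches (consuming both records — the
truth record is not additionally an FN); FN otherwise. Query records with
no truth counterpart are spurious FP; FP = FP.gt + FP.al + spurious. A
single TP count feeds both recall = TP/(TP+FN) and precision = TP/(TP+FP);
F1 is their harmonic mean; zero denominators leave a metric undefined.

## Problem sizes used in tests and the acceptance script

Simulated checks run at desk scale, chosen as the smallest sizes at which
the estimators' sampling noise is well inside the stated tolerances:
kinship recovery on 60 founders × 20k sites with the default pedigree mix;
ligation on 50 samples, 10 chunks of 1.4 Mbp with 400 kbp overlaps;
R² recovery on 400 samples × 3000 sites (≥ 5000 pooled pairs per bin);
the HWE sweep is exhaustive for n ≤ 50. Cohort-scale quantities from real
panels (tens of millions of sites, thousands of samples) are outside the
scope of these synthetic checks.
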