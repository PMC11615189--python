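# Methods

This note documents the models behind `nbdosage`, the defaults and why they
were chosen, what the synthetic cohort does and does not emulate, and the
numerical decisions that affect results.

## Copy-number model

A tumor sample is modeled as a two-population mixture: a fraction ρ
(purity) of tumor cells with segment-wise integer allele counts
`(n_A, n_B)` and average ploidy ψ, and `1−ρ` diploid normal cells. The
expected B-allele frequency and coverage log-ratio of a segment follow
directly from copy counting over the mixture (README, forward model).
Inversion enumerates all pairs `n_A ≥ n_B ≥ 0` up to `max_cn = 12` and
minimizes squared error against the observed (mirrored) segment BAF and
LogR. Ties break toward smaller total copy number, then larger minor
allele count — the most parsimonious, most balanced interpretation; the
choice only matters in degenerate corners (e.g. ρ → 0.5 ambiguities) and is
fixed for determinism.

**Segmentation.** Breakpoints are found on the mirrored signal
`|BAF − 0.5|` per chromosome by penalized binary segmentation: a split is
accepted while it reduces the sum of squared errors by more than
`6·σ²·log n`, with σ estimated robustly from first differences (MAD). Using
BAF only avoids over-segmentation from wavy coverage; segment LogR is the
mean of its sites afterwards. The penalty constant was set so that a
constant-BAF chromosome of 10³ sites at BAF noise 0.02 yields no
breakpoints while allelic-ratio steps of ≳ 0.05 are detected; measured
recall/precision on planted profiles at that noise exceed 0.95/0.9.
Minimum segment size is 3 sites.

**States.** Gain/loss conditions are evaluated in a fixed order with the
last matching condition winning: weak gain (`total > round(ψ)`), medium
gain (`> 1.5·round(ψ)`), strong gain (`> 2.5·round(ψ)`), shallow loss
(`< round(ψ)`), loss (`< 0.5·round(ψ)`), else neutral. **round(ψ) uses
round-half-to-even** (Python/NumPy default); a cohort with ploidies near
x.5 can change state labels under half-up rounding, so this is deliberately
prominent. Focal amplification (segment < 10 Mb, `n_A ≥ 5`,
`LogR_seg − LogR_chrom > 0.7`) overrides both the CN state and the balance
state. Balance: *balance* iff `n_B > 0` and `n_A = n_B`; otherwise weak vs
strong imbalance split at `CN_ratio = 2/3`; LOH iff `n_B = 0`. A (0,0)
segment has no defined balance state. Region summaries are overlap-length
weighted means; 5 Mb bins overlapping an amplified segment take that
segment's value directly (largest overlap wins among several) so focal
events survive binning.

## Telomere maintenance

Telomere content is a read-count proxy: a read counts if it contains ≥ k
(default 7) exact consecutive `TTAGGG` or `CCCTAA` copies. Both strands are
counted by default (switchable); a G-strand-only counter differs by an
approximately constant factor which cancels in the tumor/normal ratio, as
does the overall scale constant standing in for GC/genome-size
normalization. TLR is the natural log of the tumor/normal length proxies;
the ALT cut of 0.5 (≈ 1.65-fold elongation) is a config parameter.

TERT activation: cohort TERT expression Z-scores are fit with a
2-component Gaussian mixture (EM, 10 restarts, tol 1e-6, seeded). The
threshold is the smallest Z at which the posterior of the high component
reaches 0.95, located on a dense grid. **Components share a pooled (tied)
variance by default**: with ~10² samples, component-specific variances make
the 95% crossing unstable (recovery within ±0.1 of the analytic crossing
in only ~50–70% of simulated cohorts, versus ~95% pooled); `'full'` is
available when the two expression modes genuinely differ in spread. The
decision rule is then purely boolean: TERT-high requires Z above threshold
and the absence of both MYCN amplification and TERT rearrangement; CTM =
any of the three; ALT = TLR above cut; Mix = both; None = neither.

TERRA abundance counts read pairs where either mate carries ≥ 5 consecutive
telomere motifs, reported as fragments per million.

## Allele-specific expression

Sites need ≥ 8 total and ≥ 2 reads **per allele** (the stricter reading;
an `'either'` mode is provided). The bi-allelic screen tests
`min(ref, alt)` against the sample noise rate
`p0 = Σ other / Σ raw_depth` with an upper-tail exact binomial test —
upper-tail because only an excess of minor-allele reads over noise
evidences true heterozygous expression — BH-adjusted per sample. Reference
bias is reported (mean ref fraction in copy-balanced segments) but does not
re-center the AEI null by default; a bias-corrected null is a config
switch. Haplotype counts are summed per gene over phased sites; genes need
≥ 10 counts. AEI uses the exact two-sided binomial test at null 0.5 in the
minimum-likelihood convention (the p-value sums all outcome probabilities
no larger than the observed one — conventions differ and this one is
pinned), BH-pooled across all gene × sample observations jointly (pooling
granularity is itself a choice; per-sample pooling is one groupby away).
Note the exact test is conservative by discreteness: at depth 50 the
largest attainable rejection rate below α = 0.05 is 0.0328, which is what a
correct implementation shows on null simulations.

## Genetic effects

Per gene, ordinary least squares with sequential (Type I) ANOVA in a fixed
predictor order — eQTL term, copy number, SV flag, promoter SNVs, gene-body
SNVs, then covariates (purity, MYCN; plus log allelic coverage for ASE).
The order is part of the contract: sequential sums of squares are
order-dependent, and the genetic effect of interest (copy number) is
credited only with variance not already absorbed by the germline eQTL term.
Fractions are `SS_effect/SS_total` and sum to 1 with the residual (checked
to 1e-8). Per-effect significance is the F statistic, Bonferroni-adjusted
across genes within each effect (an FDR switch exists because both
conventions are in circulation). Genes need ≥ 20 complete observations.
Variance stabilization is log1p of library-size-scaled counts (CPM)
followed by per-gene cohort residualization; recovery properties, not
exact agreement with any particular VST, are the validated contract.

The allelic-dosage test regresses the ASE ratio on expression plus
covariates per gene (≥ 10 informative samples), F-tests the expression
term and BH-adjusts across genes; a negative coefficient is the
loss-of-imprinting signature (bi-allelic activation raises expression), a
positive one the mono-allelic-amplification signature. The ALT
differential-expression scan compares covariate-only and covariate+ALT
linear models per gene by likelihood ratio, BH-adjusted.

## Events and association scans

ATRX exon deletions: 2-component GMM (10 restarts, tol 1e-6) on 50 bp
coverage log-ratios; deletion iff the component means differ by ≥ 1.5 and
the smaller cluster's weight is ≥ 10% **of the larger cluster's weight**
(ratio reading). WGD: 100 bootstrap profiles of 22 chromosomes drawn with
replacement; positive if ≥ 5% of bootstrap calls are positive. The default
single-profile caller — ≥ 50% of genome length at total CN ≥ 4 with major
≥ 2 — is an explicit stand-in and is pluggable; the bootstrap wrapper is
the tested contribution. Fisher enrichment of WGD across TMM groups
reports `expected = round(n_g · total/N)` and a two-sided Fisher p
(sidedness switchable).

Arm-vs-ALT and bin-vs-mortality scans test each region between nested
logistic GLMs (covariates only vs covariates + region value) with the Rao
score chi-squared. **Family-wise error control is a single-step
max-statistic parametric bootstrap, not plain Bonferroni on asymptotic
p-values**: under the fitted covariate-only null, outcomes are resimulated
(199 replicates by default) and each observed region statistic is referred
to the bootstrap distribution of the maximum statistic across regions.
The motivation is empirical: at n ≈ 115 with 7–8 covariates and ~20
events, Bonferroni on asymptotic likelihood-ratio or score p-values showed
measured family-wise error of 0.06–0.10 on null cohorts (the χ² tail is
too light at the 0.05/39 level, and a Firth-penalized LRT was worse);
the bootstrap adjustment measures 0.043 over 300 null cohorts and also
accounts for inter-region correlation. Classical Bonferroni on the
asymptotic p-values remains available (``method='bonferroni'``). The
reported coefficient is the one-step estimate of the region term;
complete separation in the null fit falls back to a weakly
ridge-penalized fit and flags the scan. Adjacent significant bins on one
chromosome merge into candidate regions. Kaplan–Meier/Cox follow-up is
deliberately left to standard survival packages.

## Synthetic cohort

The generator plants per-sample truth (purity U(0.6, 1), 38% WGD,
TMM labels at frequencies 43:20:1:51 over CTM/ALT/Mix/None, ATRX deletions
in 45% of ALT samples), per-segment truth (Poisson(1.5) breakpoints per
chromosome over an abstract 22 × 100 Mb genome, alteration events around a
diploid or tetraploid baseline, ALT-linked 11q-loss/17q-gain lesions,
occasional focal amplifications), and per-gene truth (30% eQTL genes,
5% imprinted, dosage coefficients). Observables are generated through the
same physics the callers invert: depths are Poisson around the mixture
expectation, allelic counts binomial (optionally beta-binomial) around the
allelic copy ratio modulated by eQTL log-odds and imprinting, TERT
expression encodes a planted two-component Z mixture, telomere reads are
exact repeat concatenations with random flanks at a rate proportional to
the planted lengths, and survival labels follow a logistic model on MYCN
and TMM status. Marker density (300 SNPs and 20 genes per chromosome) and
read counts (4,000 per FASTQ) are scaled-down choices that keep a full
cohort simulation under ~10 s while leaving every statistical check
well-powered; reads are fixed 150 bp.

What it does **not** emulate: sequencing error and mapping bias at read
level, reference-genome context (no real coordinates, no mappability
structure), LD between SNPs, trans-regulatory networks, subclonality, and
SV breakpoint sequences (SV presence is a per-gene boolean). Passing
tests therefore demonstrate correctness of the inference given the model's
own generative assumptions and calibrated behavior under clean noise —
not robustness to artifacts of real sequencing data.

## Determinism and degenerate inputs

All randomness flows from one seed through named substreams
(`numpy.random.SeedSequence.spawn`); identical configs reproduce output
files byte for byte. Degenerate cases are explicit: zero purity, zero
telomere lengths and non-positive depths are errors; a pure tumor segment
of total CN 0 (no DNA) is handled with a floor on its LogR during
inversion; a zero noise-rate in the bi-allelic test is floored at 1e-4
with a warning; zero-variance signals return no-deletion (ATRX) or raise
(mixture fit). Depth-filter and site-filter drops are counted, never
silent.

## Known limitations

- The CN inversion trusts the supplied purity/ploidy; there is no
  goodness-of-fit search over (ρ, ψ), by design.
- The segmentation penalty is tuned for ~10²–10³ het sites per chromosome;
  far denser panels may warrant a larger penalty constant.
- The exact AEI test is conservative at low depth (see above); power
  claims are stated against the exact binomial power, not nominal α.
- Sequential ANOVA fractions depend on predictor order; marginal (Type
  III) shares are not implemented.
- The default WGD caller is a threshold heuristic; evolutionary-distance
  callers plug in through the same interface.
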