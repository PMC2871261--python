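# Methods

## Measurement model

Each bead carries probes for one SNP; its two fluorescence channels
measure allele A (Cy5 role) and allele B (Cy3 role). All statistics run
on the per-bead log-ratio M = log2(I_A/I_B) and average log-intensity
A = ½·log2(I_A·I_B). For genomic DNA, M clusters at three levels
(AA / AB / BB); for cDNA of a heterozygote, M measures the allelic
expression ratio, bounded by the array's dynamic range (cross-
hybridisation keeps the "absent" channel above zero, so even a fully
silenced allele leaves a finite M).

## Preprocessing

Per array, in fixed order:

1. **Between-channel quantile normalisation** over all beads of the
   array jointly: both channels are mapped onto the mean of their sorted
   vectors, removing global dye effects while preserving within-channel
   ranks. Ties receive the mean of their target quantiles.
2. **Per-bead (M, A).**
3. **Bead-type summarisation**: per SNP, values farther than
   `mad_k = 3` *unscaled* median-absolute-deviations from the median are
   removed and the rest averaged. "MAD" is the median absolute deviation
   about the median without the 1.4826 normal-consistency factor, as the
   abbreviation suggests; with MAD = 0 (constant beads) nothing is
   removed. M and A are filtered independently; the reported
   `n_beads_removed` refers to the M filter.
4. **Median centering** of the summarised M per array (median exactly 0
   afterwards). A is not centred.

Between-channel quantile normalisation is exact only in distribution:
a residual rank-mapping error of order 1% of a global bias remains on
finite panels (tests assert cancellation to within 0.05 log2 units for
a 1.0-unit injected bias). The rank mapping also degrades on very small
panels (tens of SNPs), where channel distributions are sparse; the
benchmark experiments therefore use panels of 200–3500 SNPs, closer to
real array scale.

## ASE test

For each SNP × placenta, the replicate cDNA log-ratios (duplicate
arrays; unscaled standard error u = 1/√n) are summarised by an
intercept-only fit: coefficient β̂ (the log-fold-change), residual
variance s², df = n−1. Variances are pooled across all fits of a run by
empirical Bayes under a scaled-F model: s² ~ s0²·F(d_g, d0). The prior
(d0, s0²) is estimated by method of moments on log s² (mean and excess
variance over the trigamma sampling floor; the trigamma inverse is
solved by Newton iteration). The posterior variance
s̃² = (d0·s0² + d·s²)/(d0 + d) gives the moderated statistic
t̃ = β̂/(u·s̃) on d0 + d degrees of freedom, two-sided p, and a posterior
log-odds of differential allelic expression (B-statistic) whose
non-null coefficient variance is estimated from the extreme tail of the
t distribution. One test verifies t̃, p and the log-odds against the R
reference implementation of this framework (limma) to 1e-10 relative
tolerance; a recovery test checks (d0, s0²) = (4, 0.05) is recovered
within 25%/10% from 2000 single-df variances. Degenerate cases: a
single replicate (df 0) shrinks fully to the prior; fewer than 10
informative fits falls back to ordinary t with a warning; all-zero
variances raise.

P-values are BH-adjusted **globally** across every SNP × sample test of
a run. The adjustment, Pearson correlation, paired t-test and ROC/AUC
are delegated to statsmodels, scipy and scikit-learn respectively; each
is checked against a brute-force reference on ~1000 random instances.

The call rule (all three required):

| criterion | default | meaning |
|---|---|---|
| mean A across cDNA samples | > 11.25 log2 units | expressed strongly enough for reliable allelic quantification |
| significant heterozygotes | ≥ 2 with p_adj < 0.01 and \|β̂\| > 0.585 | reproducible allelic imbalance in informative samples |
| homozygote pass fraction | ≥ 80% at the same cutoffs | the assay separates the two alleles at this SNP |

0.585 = log2(60/40) is the imbalance at the 60:40 mixing ratio, the
calibrated detection boundary of the titration experiment. The same
|lfc| cutoff is applied to heterozygotes and homozygotes. SNPs with no
genotyped homozygote cannot evaluate the third criterion and are
excluded from calls (conservative). NN genotypes count toward neither
group. Genotypes come from a symmetric threshold on gDNA M (±1.5 log2
units, replicate-averaged; boundary values to the homozygote side) —
deliberately simple and deterministic rather than cluster-based, which
is adequate for well-separated clusters; Mendelian consistency of every
trio is reported, with any missing call giving "indeterminate" rather
than "inconsistent". Per-array M range is exposed in the summaries for
dynamic-range diagnostics, but no automatic array-discard rule is
applied.

## Parent-of-origin and mode classification

For an informative heterozygote (AB placenta gDNA), the sign of the
cDNA M names the over-expressed allele. A homozygous parent fixes the
transmission: the parent homozygous for the expressed allele is its
origin; a parent homozygous for the other allele implies the opposite
origin. Both parents heterozygous → uninformative; both homozygous for
the same allele → Mendelian-error flag. With an absent father, a
homozygous mother still decides (the untransmitted maternal allele
implies the paternal one).

Silencing *completeness* is judged against the SNP's own homozygous-gDNA
reference (median |M| of AA/BB gDNA samples — the effective dynamic
range): complete iff |cDNA M| ≥ 0.8 × reference. ASE-positive SNPs then
go through a first-match ladder over the significant heterozygotes
(parental shares over the origin-informative subset, minimum 2):

1. **imprinting** — ≥ 80% share one parent and ≥ 80% complete;
2. **partial_imprinting** — ≥ 80% share one parent, completeness fails;
3. **preferential** — the same allele identity over-expressed in ≥ 90%;
4. **random_monoallelic** — ≥ 80% complete, no parental/allelic
   consistency;
5. **random_ase** — the rest with observable (≥ 2 origin-informative)
   origins; otherwise **unclassified**.

These 0.8/0.8/0.9 thresholds codify what was originally a visual
categorisation; they are configurable (`ClassifyConfig`) and their
defaults are declared here, not fitted. Misclassification concentrates
where the information genuinely runs out: preferential SNPs with few
origin-informative heterozygotes can mimic a parental bias, and random
ASE/monoallelic calls swap with partial imprinting when a coin-flip
allele sequence happens to align with transmissions — the balanced-mode
benchmark reflects this (≥ 99% for imprinting/biallelic, 83–100% for
the other modes at 250–500 SNPs per mode).

Fold-differences reconstruct per-allele intensities I_A = 2^(A+M/2),
I_B = 2^(A−M/2) and take the ratio of means (expressed over silenced)
across significant heterozygotes, on the raw scale.

## Mixture calibration

The titration design blends two individuals' gDNA in proportions
0:100, 5:95, 91:9, 83:17, 67:33, 64:36, 60:40, 56:44, 50:50, 44:56,
40:60, 36:64, 33:67, 17:83, 9:91, 5:95, 100:0 (the 5:95 point appears
twice in the assayed series and is kept as two separate conditions),
each in duplicate. Per SNP, a mixture-indexed linear model (group
means; residual variance pooled across mixtures) yields contrasts of
every mixture against 50:50 — cancelling dye bias and shared shifts —
moderated by the same empirical-Bayes machinery. Truth: genotype pairs
that differ (AA:BB, AA:AB, …) are true positives, identical pairs true
negatives, NN excluded. Ranking by log-odds (for the balanced design,
rank-equivalent to |t̃|) gives ROC curves; AUC is the tie-corrected
Mann-Whitney statistic. AUC decreases monotonically towards 50:50 and
at 67:33/33:67 stays ≥ 0.81 under default noise.

## Paired allelic-ratio screen

The mass-spec-style arm starts from allele-A signal fractions with a
call-quality rating. The success rate (SR) is the fraction of attempts
rated "conservative"; SNPs keep only if cDNA SR / gDNA SR ≥ 0.75
(expression proxy; boundary inclusive). On heterozygous-placenta trios
the paired statistic is d_i = |frac_cDNA − ½| − |frac_gDNA − ½|, tested
one-tailed (upper) on t(n−1) and BH-adjusted across SNPs. Testing
*absolute skew* rather than the raw fraction is deliberate: under
imprinting the over-expressed allele alternates between trios, so raw
fractions cancel while skew accumulates. The reported "Difference"
column is mean(|2·frac − 1|)·100 percentage points over heterozygous
cDNA samples — a reconstruction of the conventional summary, flagged as
such. Zero-variance differences return p = 0.5 (all-null) or 0/1 by
sign.

## Synthetic-data generator

The generator defines the study conditions: 23 trios; placental gDNA
and cDNA in duplicate plus one array per parent (138 arrays); 30
beads/SNP; minor-allele frequency 0.3 with the minor allele assigned to
A or B at random (keeping per-array M distributions symmetric, as on
real panels); per-SNP base intensity uniform on 9–15 log2 units;
bead-level log-normal noise sd 0.3 per channel (per-bead M sd ≈ √2·0.3);
additive dye bias 0.1 on M per array; Hardy-Weinberg parents and
uniform Mendelian transmission with transmitted alleles retained as
ground truth.

Expression modes for heterozygotes: biallelic ½; imprinting 0.97 toward
the maternal (or paternal) allele — complete silencing is deliberately
not 1.0, reflecting residual expression of the repressed allele;
partial imprinting 0.72 maternal; preferential 0.8 toward a fixed
allele; random monoallelic 0.97 and random ASE 0.75 toward a fair-coin
allele per sample. Homozygotes express their only allele.

Bead channel A is 2^(base + log2(2·frac + ε) + dye/2 + N(0, sd)) with
ε = 0.15 the cross-hybridisation background. ε bounds the dynamic
range: a homozygote reads |M| = log2(2.15/0.15) ≈ 3.84 and a
97%-silenced transcript ≈ 3.32, a completeness ratio of 0.86 — above
the 0.8 threshold with ~2σ of margin under array-level variation, so
complete imprinting is classified as such while partial imprinting
(ratio ≈ 0.3) is clearly separated. A smaller background would push the
homozygote reference far beyond what any real transcript reaches and
make *every* imprinted SNP look partial; 0.15 (≈ 7% of a balanced
channel) matches the compression seen on real arrays, where measured
imprinted fold-differences (here ~10×) sit well below the biological
expression ratio (0.97/0.03 ≈ 32×).

What the generator does **not** model: spatial array artifacts,
intensity-dependent (banana-shaped) dye bias, genotyping-error clusters,
probe-specific affinity differences, or biological variance between
placentas beyond the mode rules. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated noise model,
not performance on any real cohort.

## Benchmark experiment sizes

Chosen to estimate each characteristic stably on a single core: control
power/specificity on 300-SNP panels over 20 seeds (the two control-style
SNPs pin 12 and 13 heterozygous placentas at base intensities 14.0 and
12.78); titration series with 1300 SNPs (≈ 750 TP / 550 TN after
labelling); type-I error on 5 fully-null 200-SNP cohorts (all tests
truly M = 0); prior recovery on 20 × 2000 variances at 4 residual df —
the regime where the moment estimator is well identified; with a single
residual df the log-chi-square tails are heavy enough that even the
median over 20 runs wanders tens of percent around the generative d0,
so the single-df regime is exercised in the unit tests rather than
used as the benchmark; mode classification
on 250–500 SNPs per mode at base 12–15; end-to-end sensitivity/FPR on
20 default 200-SNP cohorts, computed over *assessable* SNPs (above the
intensity threshold, ≥ 2 heterozygotes, ≥ 1 homozygote) — the same
conditioning the call criteria impose, since a SNP below the expression
threshold is by design untestable rather than a miss.
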