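# Methods

This note documents the statistical procedures tbscan implements, the
generative models behind its synthetic data, the defaults and why they were
chosen, and what the validation experiments do and do not demonstrate.

## Differentiation scan

Per-site differentiation uses Nei's GST form of FST: with allele frequencies
p₁, p₂ in two populations and p̄ = (p₁+p₂)/2 (unweighted — no sample-size
correction),

    H_T = 2 p̄ (1 − p̄),   H_S = p₁(1−p₁) + p₂(1−p₂),   FST = (H_T − H_S)/H_T.

Sites monomorphic in both populations (H_T = 0) are defined as FST 0 and
flagged non-segregating. This form is never negative, so no clamping is
needed. Windows are 20 kb sliding in 2-kb steps, anchored at coordinate 0 of
each chromosome; a window's value is the unweighted mean over the SNPs it
contains, and a SNP at 1-based position p belongs to the window
[start, start+w) iff start ≤ p < start+w. Empty windows are reported with
n_snps = 0 and no value. The genome-wide top 5‰ of window means (empirical
quantile, linear interpolation, ties at the threshold included) marks
candidate regions.

## Branch lengths, PBS and the HKA-style contrast

Pairwise FST values are converted to divergence-scaled branch lengths with
the Cavalli-Sforza transform T = −ln(1 − FST) (natural log, the convention
of the PBS literature); FST = 1 is clamped to 1 − 1e−12 with a warning. The
population branch statistic for the target population is

    PBS = (T_target,sister + T_target,outgroup − T_sister,outgroup) / 2,

which may legitimately be negative. A `paper` mode computing
(T₁₂+T₁₃+T₂₃)/2 — a literal reading of one published rendering of the
formula, almost certainly a typesetting slip since it is no longer a branch
length — is available behind a flag and recorded in output metadata; it is
never the default.

The polymorphism/fixation contrast works per gene over coding SNPs only
(CDS intervals merged per gene): A counts sites polymorphic in the target
population, B counts sites whose FST strictly exceeds 0.9 against **both**
other populations. By default the classes are disjoint — a site meeting the
fixation rule goes to B only. This matters: the gene-versus-genome 2×2
Pearson chi-square (no continuity correction, df = 1) assumes the table
cells partition the sites; letting a high-frequency but still-segregating
site count in both A and B correlates the columns and makes the test
measurably conservative (neutral flag rate ≈ 0.038 instead of 0.047 at
nominal 0.05 in our calibration conditions). The literal overlapping count
is available via `count_fixed_in_A=True`. Two further interpretation
switches are provided because the source description is ambiguous: `a_sites`
(count A over coding SNPs, the default, or all SNPs in the gene span) and
`a_pop` (polymorphic in the focal population, the default, or in any).
Tables with any expected cell below 1 are flagged low-count rather than
trusted. Genes in the PBS top 5% (genome-wide empirical quantile) with
nominal HKA P < 0.05 are sweep candidates; no multiple-testing correction is
applied by default, matching the nominal-P convention of the analysis this
package reproduces (Benjamini–Hochberg can be added as a labelled extra
column downstream, never silently).

## Hitch-hiking diagnostic

Alleles are polarized against an outgroup population: the ancestral allele
is the outgroup's major allele where the outgroup major-allele frequency is
≥ 0.9 (monomorphic included); more polymorphic or fully missing outgroup
sites are excluded with logged counts. Polarization against an outgroup has
an irreducible error: sites whose derived allele was already at high
frequency in the common ancestor pass the filter with inverted polarity.
Under the generator's neutral frequency law this is ~3% of retained sites
even with zero outgroup drift, which is why truth-agreement is ~97%, not
100%.

Polarized segregating sites (derived frequency strictly inside (0,1)) are
binned by distance from the focal position — bin k covering ((k−1)·10 kb,
k·10 kb], upstream and downstream combined, out to 80 kb — and each bin's
derived AFS is compared to the background (all polarized segregating sites
outside the focal ±80 kb) with an asymptotic two-sample Kolmogorov–Smirnov
test. Bins with fewer than 5 sites are flagged, not tested. Decay is
summarized as the Spearman rank correlation between bin distance and KS D
over tested bins: negative means the spectrum approaches the background
with distance, the hitch-hiking signature. A `u_shape_index` — the fraction
of sites with derived frequency ≤ 0.1 or ≥ 0.9 — is reported per bin as a
labelled convenience summary; the KS procedure is the operative test.

## Association layer

At each biallelic site, accessions are split into the two homozygote classes
(heterozygotes and missing calls set aside with counts); sites whose minor
homozygote class is below 5% of the homozygotes are flagged rare and not
tested, as are splits leaving fewer than two per group. Groups are compared
with the pooled-variance two-sample Student's t-test, two-sided (Welch is
available as an option, never the default). Reported per comparison:

* effect size — the absolute difference of group means, in tillers;
* mean value difference — 100·(m_high − m_low)/m_low, i.e. "X% more
  tillers" relative to the lower group;
* variance — the pooled within-group variance of the values entering the
  test.

The last two are documented interpretations: the source tables print
"Mean value difference" and "Variance" without defining the denominator or
the variance in question. Line-level means (over the replicated plants of a
line) are the default unit of analysis. Conditional association subsets to
accessions homozygous for a required genotype at a second site and reruns
the comparison, with subset sizes logged. Segregation distortion is the
Pearson chi-square goodness-of-fit of observed genotype-class counts to a
ratio (1:1 for homozygote classes of near-homozygous RILs, 1:2:1 for an F2),
df = classes − 1. Expression–phenotype association is the Pearson
correlation with the two-sided P from t = r·sqrt((n−2)/(1−r²)).

## Synthetic-data generators

**Three populations.** Site positions are drawn uniformly without
replacement (1-based, to match VCF). Each site's ancestral derived-allele
frequency follows the standard neutral law, P(i copies among n chromosomes)
∝ 1/i. Population frequencies are Balding–Nichols draws: Beta with mean p
and shape (1−F)/F per population, so F acts as a per-population drift/
fixation parameter; diploid genotypes are binomial. Which of REF/ALT is
ancestral is randomized per site and emitted as truth (AA tag); a
polarization-error rate (default 0) can corrupt the recorded labels. The
default configuration is three populations of 40 diploids with
F = (0.15, 0.15, 0.3) — moderate differentiation between the two sister
groups, a more diverged third population to serve as outgroup.

**Sweep.** The hitch-hiking effect is modelled phenomenologically: at
distance d from the focal position, with probability w₀·exp(−d/λ) the
target population's derived frequency is replaced by a uniform draw on
[0.9, 1]. Defaults w₀ = 0.8, λ = 20 kb produce the U-shaped,
distance-decaying spectrum the diagnostic is designed to detect; w₀ = 0 is
exactly neutrality. This is deliberately a minimal stand-in, not a
coalescent simulation: it reproduces the frequency-spectrum consequence of
a sweep without linkage, trajectories or recombination maps, which is all
the downstream statistics consume.

**Crosses.** Founders are homozygous opposite at all loci. The F2 is one
meiosis from the double-heterozygous F1; F8 RILs are produced by single-seed
descent (seven selfing meioses), giving per-locus residual heterozygosity
(1/2)⁷ before distortion. Gametes recombine between adjacent loci with
fraction r. Segregation distortion is viability selection: each individual
is accepted with probability proportional to the product over loci of a
per-genotype weight, so F2 class frequencies follow the renormalized
1:2:1 × weights closed form exactly (the oracle used in tests). Weights
(1, 0.948, 0.4446) reproduce a 135:256:60 pattern in 451 individuals.

**Phenotypes.** Per plant and timepoint: baseline + Σ (per-copy effect ×
dosage) + Gaussian noise; the per-line value is the mean of 8 plants
(the replication level of the emulated field design). Defaults: baselines
6.0 tillers at 40 DAG and 12.0 at 50 DAG — back-calculated from the printed
effect-size / mean-value-difference ratios of the association tables (an
absolute difference of 2.77 tillers printed as a 22.8% relative difference
implies a ~12-tiller group mean, and 0.47 at 7.59% implies ~6) — and
per-plant residual SD of sqrt(baseline) (≈2.45 and 3.46 tillers), i.e.
count-like dispersion. The printed phenotype variances (9–81) are larger
than these residuals produce, because real field data include polygenic
background and environmental heterogeneity that the two-locus additive
model deliberately omits; the generator models the causal-locus signal and
measurement-scale noise only. Consequences of that omission are stated
under Limitations.

## Validation experiments and problem sizes

The validation experiments (in `tbscan.experiments`, reported by
`scripts/acceptance.py`) run at desk scale, sizes chosen so the whole
battery completes in about a minute:

* **Neutral HKA calibration** — 200 replicates of a 1.2-Mb, 12,000-SNP
  genome with strong drift (F = 0.9 for all three populations) and 60-kb
  exchangeable gene blocks. Strong drift makes fixed sites common and the
  block length puts the 2×2 table's expected cells in the tens — the regime
  the asymptotic chi-square targets. Low-count-flagged tests are excluded
  from the rate (they are flagged precisely because the approximation is
  unreliable there).
* **Neutral KS calibration** — 200 replicates, 400-kb/4,000-SNP genomes
  with 250 diploids per population. The larger panel matters: sample
  frequencies are discrete, and with only ~80 chromosomes the tie-heavy
  samples make the KS test conservative (rejection ≈ 0.03–0.04 at nominal
  0.05); at 500 chromosomes the continuous-null approximation holds.
* **t-test type-I error** — 2,000 null replicates at 20 per group.
* **Sweep detection** — 50 replicates of a 5-Mb, 50,000-SNP genome
  (40 diploids × 3 populations) with one implanted sweep and 2-kb genes
  every 10 kb; reports how often a gene within 30 kb of the focal position
  is called a candidate and how often the KS decay correlation is negative.
* **Effect recovery** — 200 replicates each of a 2.77-tiller contrast at
  50 DAG with 60 vs 135 lines and a 0.47-tiller contrast at 40 DAG with
  75 vs 60 lines, under the generator defaults; reports the fraction
  recovered within ±0.6 and ±0.3 tillers respectively.

Passing these shows the statistics are implemented correctly, calibrated in
their validity regimes, and powered against the generator's sweep and
effect models at these sizes. It does **not** reproduce any resequencing-
scale result: real genome scans involve linkage disequilibrium, population
structure, variable recombination and mutation rates, and ascertainment,
none of which the generator emulates.

## Numerical and degenerate-input conventions

* Quantile thresholds use numpy's linear-interpolation empirical quantile;
  all values ≥ threshold are flagged (ties included); NaNs never flag.
* Zero pooled variance with equal means → t = 0, P = 1; with unequal means
  → P floored at the smallest positive double and flagged.
* A zero margin in the HKA table (e.g. no fixed sites genome-wide) is an
  undefined test and raises, rather than returning a value.
* Monomorphic-in-both FST is 0 by definition; FST = 1 is clamped only inside
  the log transform.
* VCF round trips preserve calls, positions and ancestral tags exactly;
  multiallelic and non-SNP records are skipped with counts. Files carry one
  chromosome; coordinates are opaque (no liftover between assembly
  versions).
* All generators and pipelines are pure functions of (parameters, seed);
  pipeline outputs embed the tool version, seed and a hash of the scientific
  configuration (output paths excluded).

## Limitations

* The sweep model is phenomenological; statistics sensitive to haplotype
  structure (iHS, nSL, XP-CLR, SweeD-style composite likelihoods) are out of
  scope, and the CLI only documents where external composite-likelihood
  output would slot in.
* The KS diagnostic is conservative on small panels (frequency-grid ties);
  interpret borderline bin P-values accordingly.
* Outgroup polarization mis-orients anciently high-frequency derived
  alleles (~3% of retained sites under the neutral law); derived-AFS tails
  are correspondingly contaminated in any outgroup-polarized analysis, not
  just here.
* The phenotype generator omits polygenic background and
  genotype-by-environment variance, so simulated phenotype variances are
  smaller than the printed field-trial variances; recovery rates measured
  here are accordingly upper bounds on what identical panel sizes would
  achieve in the field.
* The association layer is two-group testing, not mixed-model GWAS; no
  kinship correction is applied.
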