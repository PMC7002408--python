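# tbscan

Selection-scan and genotype–phenotype association toolkit for rice tillering
loci — a tested re-implementation of the population-genetics evidence chain
used to argue that a tillering gene on chromosome 9 was artificially selected
during upland rice improvement and is associated with tiller number.

It is written for population geneticists and rice-genetics groups who want to
run (or scrutinize) that evidence chain on their own variant panels, and for
method developers who want a desk-scale, fully synthetic testbed for each
stage.

## What it computes

**Windowed differentiation scan.** Per-site Nei FST (the GST form,
FST = (H_T − H_S)/H_T with the unweighted mean frequency p̄ = (p₁+p₂)/2),
averaged over 20-kb windows sliding in 2-kb steps; windows in the genome-wide
top 5‰ are candidate selection regions.

**Gene-level sweep calling.** For three populations (target, sister,
outgroup) and each gene's coding SNPs: pairwise mean FST, Cavalli-Sforza
branch lengths T = −ln(1 − FST), and the population branch statistic

    PBS_target = (T_ts + T_to − T_so) / 2

together with an HKA-style polymorphism/fixation contrast: A = coding sites
polymorphic in the target, B = coding sites with FST > 0.9 against **both**
other populations, tested against the genome-wide A/B ratio with a 2×2
Pearson chi-square. Genes in the PBS top 5% with HKA P < 0.05 are sweep
candidates.

**Hitch-hiking diagnostic.** Derived allele-frequency spectra (polarized
against an outgroup population) in 10-kb distance bins out to 80 kb from a
focal mutation, each compared to the genome background with a two-sample
Kolmogorov–Smirnov test; a sweep shows a U-shaped spectrum whose KS D decays
with distance (negative Spearman rank correlation).

**Association layer.** Two-homozygote Student's t-tests of tiller number at
40/50 days after germination, conditional association (testing one variant
inside a fixed homozygote class of a linked variant), effect sizes in
tillers, percent mean differences, chi-square segregation-distortion tests
for F8 RIL and near-isogenic F2 crosses, and expression–phenotype Pearson
correlation.

**Synthetic data.** A Balding–Nichols three-population generator with an
optional phenomenological sweep (high-frequency derived alleles mixed in
with probability w₀·exp(−d/λ)), biparental-cross simulators with viability
distortion, and an additive tiller-number phenotype model — so every stage
runs and is validated without any downloads.

## Worked example

```python
from tbscan import PopulationModel, SweepConfig, SelectionScan, HitchhikingScan
from tbscan.experiments import spaced_genes

model = PopulationModel(n_sites=10_000, chrom_length_bp=1_000_000, seed=7)
sweep = SweepConfig(focal_position_bp=500_000, target_pop="upland_jap")
genotypes = model.simulate(sweep)

scan = SelectionScan(genotypes, spaced_genes(1_000_000), model.pop_labels)
print(scan.fit(chrom_length=1_000_000).summary())
print(HitchhikingScan(genotypes, 500_000, "upland_jap", "indica").fit().summary())
```

prints (abridged):

```
Selection scan summary
----------------------
populations (target, sister, third): ('upland_jap', 'irrigated_jap', 'indica')
windows: 491 of 20000 bp every 2000 bp; top-0.500% mean-FST threshold = 0.4600
candidate windows: 3
genes scored: 100 (PBS mode: standard)
sweep candidates (PBS top 5% and HKA P < 0.05): 3
top candidate: gene00051 (PBS=1.107, HKA P=6.1e-12)
...
decay: Spearman rho = -1.000 (P = 0, 8 bins)
```

`gene00051` spans 500,001–502,000 bp — the implanted sweep is recovered as
the top candidate, and the KS statistic falls off with distance from the
focal site (negative rho), the hitch-hiking signature.

The same run is available from the shell:

```bash
tbscan scan --config examples/demo_scan.yaml --out demo_out
tbscan assoc --config examples/demo_assoc.yaml --out demo_out
```

The association demo simulates a 451-individual near-isogenic F2 segregating
a coding indel and a 3'UTR SNP (with viability distortion calibrated to a
135:256:60 genotype-class pattern), then reproduces the conditional
association table and segregation-distortion report.

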