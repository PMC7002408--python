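"""Seeded Monte-Carlo validation experiments.

These experiments exercise the full pipeline on synthetic data and measure
the properties the method is supposed to have: type-I error calibration of
the HKA-style, KS and t tests under neutrality, detection power for an
implanted sweep, distance decay of the hitch-hiking signature, and recovery
of programmed phenotype effect sizes.  They are used both by the acceptance
test suite and by ``scripts/acceptance.py``.

Problem sizes are desk scale: a few megabases and tens of diploids per
population, far below a resequencing study, so headline genome-scan numbers
are not reproduced here - only the method's operating characteristics.
"""

from __future__ import annotations

import numpy as np

from .afs import HitchhikingScan
from .assoc import pearson_correlation_test, t_test_association
from .io import GeneAnnotation
from .scan import ScanThresholds, SelectionScan, hka_test, nei_fst
from .synthetic import PhenotypeModel, PopulationModel, SweepConfig, simulate_phenotypes


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def block_genes(chrom_length: int, block: int = 20_000, chrom: str = "chr09"):
    """Contiguous gene blocks tiling the chromosome (for calibration runs)."""
    return [GeneAnnotation(f"block{i:04d}", chrom, [(s + 1, s + block)])
            for i, s in enumerate(range(0, chrom_length - block + 1, block))]


def spaced_genes(chrom_length: int, gene_length: int = 2_000, spacing: int = 10_000,
                 chrom: str = "chr09"):
    """Sparse 2-kb genes every 10 kb (for scan runs)."""
    return [GeneAnnotation(f"gene{i + 1:05d}", chrom, [(s, s + gene_length - 1)])
            for i, s in enumerate(range(1, chrom_length - gene_length, spacing))]


# ---------------------------------------------------------------------------
# neutral calibration
# ---------------------------------------------------------------------------

def neutral_hka_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    n_sites: int = 12_000,
    chrom_length: int = 1_200_000,
    drift_F: float = 0.9,
    block: int = 60_000,
) -> dict:
    """HKA flag rate over neutral replicates with exchangeable gene blocks.

    Strong drift (F = 0.9, three long-separated populations) makes fixed
    sites common, and 60-kb gene blocks at 10 SNPs/kb put the 2x2 table's
    expected cells in the tens - the regime the asymptotic chi-square
    targets; low-count tests are excluded (they are flagged by the
    implementation as unreliable).
    """
    genes = block_genes(chrom_length, block=block)
    hits = total = 0
    for s in _child_seeds(seed, n_replicates):
        model = PopulationModel(n_sites=n_sites, chrom_length_bp=chrom_length,
                                drift_F_per_pop=(drift_F,) * 3, seed=int(s))
        m = model.simulate()
        pops = tuple(m.populations)
        pt = m.alt_freq(pops[0])
        f12 = nei_fst(pt, m.alt_freq(pops[1]))
        f13 = nei_fst(pt, m.alt_freq(pops[2]))
        fixed = (f12 > 0.9) & (f13 > 0.9)
        seg = (pt > 0) & (pt < 1) & ~fixed
        A_tot, B_tot = int(seg.sum()), int(fixed.sum())
        for g in genes:
            idx = g.site_index(m)
            a, b = int(seg[idx].sum()), int(fixed[idx].sum())
            if a + b == 0 or B_tot == 0:
                continue
            res = hka_test(a, b, A_tot, B_tot)
            if res.low_count:
                continue
            total += 1
            hits += res.p < alpha
    rate = hits / total if total else float("nan")
    return {"flag_rate": rate, "n_tests": total, "alpha": alpha,
            "mc_sd": float(np.sqrt(alpha * (1 - alpha) / max(total, 1)))}


def neutral_ks_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    n_sites: int = 4_000,
    chrom_length: int = 400_000,
    n_diploids: int = 250,
) -> dict:
    """KS rejection rate of distance bins vs background under neutrality.

    Sample allele frequencies are discrete (2 x n_diploids + 1 values); heavy
    ties make the two-sample KS test conservative, so the calibration uses
    enough diploids (250/population) for the continuous-distribution null the
    asymptotic P-value assumes.  At small panel sizes the test under-rejects
    - a documented limitation, not a bug.
    """
    hits = total = 0
    for s in _child_seeds(seed, n_replicates):
        model = PopulationModel(n_sites=n_sites, chrom_length_bp=chrom_length,
                                n_diploids_per_pop=(n_diploids,) * 3, seed=int(s))
        m = model.simulate()
        res = HitchhikingScan(m, chrom_length // 2, m.populations[0],
                              m.populations[2]).fit()
        tested = res.table.loc[~res.table["low_count"], "p"].dropna()
        total += len(tested)
        hits += int((tested < alpha).sum())
    rate = hits / total if total else float("nan")
    return {"rejection_rate": rate, "n_tests": total, "alpha": alpha,
            "mc_sd": float(np.sqrt(alpha * (1 - alpha) / max(total, 1)))}


def ttest_type1_error(
    n_replicates: int = 2_000,
    seed: int = 0,
    alpha: float = 0.05,
    n_per_group: int = 20,
    sd: float = 3.0,
) -> dict:
    """Type-I error of the pooled t-test on null Gaussian phenotypes."""
    rng = np.random.default_rng(seed)
    hits = sum(
        t_test_association(rng.normal(10, sd, n_per_group),
                           rng.normal(10, sd, n_per_group)).p < alpha
        for _ in range(n_replicates)
    )
    return {"rejection_rate": hits / n_replicates, "n_tests": n_replicates,
            "alpha": alpha,
            "mc_sd": float(np.sqrt(alpha * (1 - alpha) / n_replicates))}


# ---------------------------------------------------------------------------
# sweep detection
# ---------------------------------------------------------------------------

def sweep_detection_experiment(
    n_replicates: int = 50,
    seed: int = 0,
    chrom_length: int = 5_000_000,
    n_sites: int = 50_000,
    n_diploids: int = 40,
    focal_position: int = 2_501_000,
    intensity_w0: float = 0.8,
    decay_length: float = 20_000.0,
    locate_tol: int = 30_000,
) -> dict:
    """Detection rate of an implanted sweep and of the AFS distance decay.

    Per replicate: simulate three populations with a sweep in the target,
    run the gene-level PBS/HKA scan over sparse 2-kb genes, and record
    whether a gene within ``locate_tol`` of the focal position is called a
    candidate; run the hitch-hiking diagnostic and record whether the
    Spearman decay correlation is negative.
    """
    genes = spaced_genes(chrom_length)
    centers = np.array([(g.span[0] + g.span[1]) / 2 for g in genes])
    near = {g.gene_id for g, c in zip(genes, centers)
            if abs(c - focal_position) <= locate_tol}
    called = decay_neg = 0
    for s in _child_seeds(seed, n_replicates):
        model = PopulationModel(n_sites=n_sites, chrom_length_bp=chrom_length,
                                n_diploids_per_pop=(n_diploids,) * 3, seed=int(s))
        sweep = SweepConfig(focal_position_bp=focal_position,
                            target_pop=model.pop_labels[0],
                            intensity_w0=intensity_w0,
                            decay_length_bp=decay_length)
        m = model.simulate(sweep)
        res = SelectionScan(m, genes, model.pop_labels).fit(
            thresholds=ScanThresholds(), chrom_length=chrom_length)
        called += bool(near & set(res.candidates["gene_id"]))
        hres = HitchhikingScan(m, focal_position, model.pop_labels[0],
                               model.pop_labels[2]).fit()
        decay_neg += hres.decay["spearman_rho"] < 0
    return {"candidate_rate": called / n_replicates,
            "decay_negative_rate": decay_neg / n_replicates,
            "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# effect-size recovery
# ---------------------------------------------------------------------------

def effect_recovery_experiment(
    homozygote_contrast: float,
    timepoint: int,
    n_lines: tuple[int, int],
    tolerance: float,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Recovery of a programmed homozygote contrast by the t-test estimator.

    Lines carry dosage 0 or 2 at a single causal site; phenotypes follow the
    generator defaults (8 plants per line, count-like residual noise).  The
    recovered effect size is the absolute group-mean difference.
    """
    import pandas as pd

    n0, n2 = n_lines
    geno = pd.DataFrame({"site": np.repeat([0, 2], [n0, n2])},
                        index=[f"L{i}" for i in range(n0 + n2)])
    per_copy = homozygote_contrast / 2.0
    model = PhenotypeModel(additive_effects={"site": {timepoint: per_copy}},
                           timepoints=(timepoint,))
    rng = np.random.default_rng(seed)
    recovered = []
    for _ in range(n_replicates):
        ph = simulate_phenotypes(geno, model, seed=rng)
        v = ph.set_index("line_id")["value"].loc[geno.index].to_numpy()
        recovered.append(t_test_association(v[:n0], v[n0:]).effect_size)
    recovered = np.array(recovered)
    errors = np.abs(recovered - homozygote_contrast)
    return {"recovery_rate": float(np.mean(errors < tolerance)),
            "mean_recovered_effect": float(recovered.mean()),
            "median_abs_error": float(np.median(errors)),
            "tolerance": tolerance,
            "n_replicates": n_replicates}


def expression_correlation_recovery(
    r_true: float = 0.48,
    n: int = 39,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Recovery of a programmed expression-phenotype Pearson correlation.

    Bivariate normal pairs at the panel size of the expression experiment
    (n = 39 lines); reports the mean estimated r.
    """
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, r_true], [r_true, 1.0]])
    rs = []
    for _ in range(n_replicates):
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        rs.append(pearson_correlation_test(xy[:, 0], xy[:, 1]).r)
    return {"mean_r": float(np.mean(rs)), "r_true": r_true, "n": n,
            "n_replicates": n_replicates}
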