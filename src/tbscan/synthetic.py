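"""Synthetic genotype, cross and phenotype generators.

These generators produce data with the statistical structure the downstream
analyses assume, so every stage of the pipeline can be exercised and validated
at desk scale:

* three diverged populations (a target population, its sister and a more
  distant third population) under a Balding-Nichols drift model, optionally
  carrying a selective sweep at a focal locus that inflates high-frequency
  derived alleles with an exponential distance decay (the hitch-hiking
  signature);
* biparental crosses (an F8 recombinant-inbred-line population and a
  near-isogenic F2) segregating linked loci, with optional viability-based
  segregation distortion;
* tiller-number phenotypes with additive locus effects, replicated plants per
  line, and Gaussian residual noise.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .genotypes import GenotypeMatrix

_BASES = np.array(["A", "C", "G", "T"])

#: Phenotyping timepoints in days after germination.
DEFAULT_TIMEPOINTS = (40, 50)

#: Mean tiller number per timepoint.  Derived from the printed effect-size /
#: mean-value-difference ratios of the association tables (e.g. an absolute
#: difference of 2.77 tillers corresponding to a 22.8% relative difference
#: implies a group mean near 12).
DEFAULT_BASELINE_MU = {40: 6.0, 50: 12.0}

#: Per-plant residual SD in tillers; sqrt(baseline), i.e. count-like noise.
DEFAULT_RESIDUAL_SD = {40: float(np.sqrt(6.0)), 50: float(np.sqrt(12.0))}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Three-population drift model (target, sister, third/outgroup).

    ``drift_F`` is the Balding-Nichols fixation-index-like parameter of each
    population: each population's derived allele frequency is drawn from a
    Beta distribution with mean equal to the ancestral frequency and shape
    parameter (1-F)/F, so larger F means more drift.
    """

    pop_labels: tuple[str, str, str] = ("upland_jap", "irrigated_jap", "indica")
    n_diploids_per_pop: tuple[int, int, int] = (40, 40, 40)
    drift_F_per_pop: tuple[float, float, float] = (0.15, 0.15, 0.3)
    chrom_length_bp: int = 5_000_000
    n_sites: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pop_labels) != 3 or len(set(self.pop_labels)) != 3:
            raise InvalidParameterError("exactly three distinct populations required")
        if len(self.n_diploids_per_pop) != 3 or any(n < 1 for n in self.n_diploids_per_pop):
            raise InvalidParameterError("n_diploids_per_pop must be three positive integers")
        if len(self.drift_F_per_pop) != 3 or any(not (0.0 < f < 1.0) for f in self.drift_F_per_pop):
            raise InvalidParameterError("drift_F values must lie in the open interval (0,1)")
        if self.chrom_length_bp < 1 or self.n_sites < 1:
            raise InvalidParameterError("chrom_length_bp and n_sites must be positive")
        if self.n_sites > self.chrom_length_bp:
            raise InvalidParameterError("n_sites cannot exceed chrom_length_bp")

    def simulate(self, sweep: "SweepConfig | None" = None, seed=None) -> GenotypeMatrix:
        return simulate_three_pop_genotypes(self, sweep, seed=seed)


@dataclass
class SweepConfig:
    """Phenomenological hitch-hiking model around a focal beneficial mutation.

    At distance d from the focal position, the target population's derived
    frequency is replaced, with probability ``intensity_w0 * exp(-d/decay_length_bp)``,
    by a draw uniform on [high_freq_floor, 1].  ``intensity_w0 = 0`` reduces to
    neutrality.
    """

    focal_position_bp: int
    target_pop: str
    intensity_w0: float = 0.8
    decay_length_bp: float = 20_000.0
    high_freq_floor: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.intensity_w0 <= 1.0):
            raise InvalidParameterError("intensity_w0 must be in [0,1]")
        if self.decay_length_bp <= 0:
            raise InvalidParameterError("decay_length_bp must be positive")
        if not (0.5 < self.high_freq_floor < 1.0):
            raise InvalidParameterError("high_freq_floor must be in (0.5,1)")


@dataclass
class CrossConfig:
    """Biparental cross: F8 RILs by single-seed descent, or a near-isogenic F2.

    ``distortion_weights`` maps locus name to relative viability weights of the
    (parent-A homozygote, heterozygote, parent-B homozygote) classes; defaults
    to Mendelian (1,1,1).  ``recomb_fraction_between_adjacent`` r = 0.5 means
    free recombination.
    """

    cross_type: str  # "RIL_F8" | "NIL_F2"
    n_individuals: int
    loci: list[tuple[str, int]] = field(default_factory=lambda: [("indel1", 15_273_436), ("snp3", 15_274_099)])
    recomb_fraction_between_adjacent: float | list[float] = 0.01
    distortion_weights: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cross_type not in ("RIL_F8", "NIL_F2"):
            raise InvalidParameterError("cross_type must be RIL_F8 or NIL_F2")
        if self.n_individuals < 1:
            raise InvalidParameterError("n_individuals must be positive")
        if len(self.loci) < 1:
            raise InvalidParameterError("at least one locus required")
        for r in self._r_list():
            if not (0.0 <= r <= 0.5):
                raise InvalidParameterError("recombination fractions must be in [0, 0.5]")
        for name, w in self.distortion_weights.items():
            if len(w) != 3 or any(x <= 0 for x in w):
                raise InvalidParameterError(f"distortion weights for {name!r} must be 3 strictly positive numbers")
            if name not in [n for n, _ in self.loci]:
                raise InvalidParameterError(f"distortion weights given for unknown locus {name!r}")

    def _r_list(self) -> list[float]:
        n_int = max(len(self.loci) - 1, 0)
        r = self.recomb_fraction_between_adjacent
        if np.isscalar(r):
            return [float(r)] * n_int
        r = list(r)
        if len(r) != n_int:
            raise InvalidParameterError("need one recombination fraction per adjacent locus pair")
        return [float(x) for x in r]

    def simulate(self, seed=None) -> GenotypeMatrix:
        return simulate_cross(self, seed=seed)


@dataclass
class PhenotypeModel:
    """Additive tiller-number model: baseline + locus effects + Gaussian noise.

    ``additive_effects[locus][timepoint]`` is in tillers per derived-allele
    copy, so the homozygote contrast is twice this value.  Per-line values are
    means over ``plants_per_line`` plants measured at each timepoint.
    """

    additive_effects: dict[str, dict[int, float]]
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    baseline_mu: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_MU))
    residual_sd: float | dict[int, float] = field(default_factory=lambda: dict(DEFAULT_RESIDUAL_SD))
    plants_per_line: int = 8
    trait: str = "tiller_number"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plants_per_line < 1:
            raise InvalidParameterError("plants_per_line must be >= 1")
        for t in self.timepoints:
            if self._sd(t) <= 0:
                raise InvalidParameterError("residual_sd must be positive")
            if t not in self.baseline_mu:
                raise InvalidParameterError(f"no baseline mean for timepoint {t}")

    def _sd(self, timepoint: int) -> float:
        if np.isscalar(self.residual_sd):
            return float(self.residual_sd)
        try:
            return float(self.residual_sd[timepoint])
        except KeyError as exc:
            raise InvalidParameterError(f"no residual_sd for timepoint {timepoint}") from exc


# ---------------------------------------------------------------------------
# neutral frequency law
# ---------------------------------------------------------------------------

def draw_neutral_sfs_frequencies(n_sites: int, sample_chroms: int, seed=None) -> np.ndarray:
    """Draw derived allele frequencies from the standard neutral 1/i law.

    Each site's frequency is i/sample_chroms with i drawn from {1, ...,
    sample_chroms-1} with probability proportional to 1/i, the expected
    site-frequency spectrum of a constant-size neutral population.
    """
    if n_sites < 1 or sample_chroms < 2:
        raise InvalidParameterError("need n_sites >= 1 and sample_chroms >= 2")
    rng = _rng(seed)
    i = np.arange(1, sample_chroms)
    w = 1.0 / i
    counts = rng.choice(i, size=n_sites, p=w / w.sum())
    return counts / sample_chroms


# ---------------------------------------------------------------------------
# three-population genotypes
# ---------------------------------------------------------------------------

def simulate_three_pop_genotypes(
    model: PopulationModel,
    sweep: SweepConfig | None = None,
    seed=None,
    polarization_error: float = 0.0,
) -> GenotypeMatrix:
    """Simulate biallelic SNP genotypes for three diverged populations.

    Per site an ancestral derived-allele frequency is drawn from the neutral
    1/i law; each population's frequency is then drawn from the
    Balding-Nichols Beta distribution with that mean and drift parameter F,
    and diploid genotypes are sampled binomially.  Under a sweep, sites near
    the focal position have the target population's derived frequency replaced
    by a high-frequency draw (see :class:`SweepConfig`).

    ``polarization_error`` flips the *recorded* ancestral-state label at that
    per-site rate, leaving genotypes untouched (default 0: the simulator emits
    truth).
    """
    rng = _rng(model.seed if seed is None else seed)
    n_sites = model.n_sites
    L = model.chrom_length_bp
    if sweep is not None:
        if sweep.target_pop not in model.pop_labels:
            raise InvalidParameterError(f"sweep target {sweep.target_pop!r} not among populations")
        if not (1 <= sweep.focal_position_bp <= L):
            raise InvalidParameterError("sweep focal position is off-chromosome")

    positions = np.sort(rng.choice(L, size=n_sites, replace=False)) + 1  # 1-based

    total_chroms = 2 * int(sum(model.n_diploids_per_pop))
    p_anc = draw_neutral_sfs_frequencies(n_sites, total_chroms, seed=rng)

    # derived frequency per population under Balding-Nichols drift
    pop_freqs = []
    for F in model.drift_F_per_pop:
        shape = (1.0 - F) / F
        a = np.maximum(p_anc * shape, 1e-12)
        b = np.maximum((1.0 - p_anc) * shape, 1e-12)
        pop_freqs.append(rng.beta(a, b))

    if sweep is not None and sweep.intensity_w0 > 0:
        t_idx = model.pop_labels.index(sweep.target_pop)
        d = np.abs(positions - sweep.focal_position_bp)
        hit = rng.random(n_sites) < sweep.intensity_w0 * np.exp(-d / sweep.decay_length_bp)
        repl = rng.uniform(sweep.high_freq_floor, 1.0, size=int(hit.sum()))
        pop_freqs[t_idx] = pop_freqs[t_idx].copy()
        pop_freqs[t_idx][hit] = repl

    # diploid derived-allele dosages per population block
    derived_calls = np.empty((n_sites, sum(model.n_diploids_per_pop)), dtype=np.int8)
    col = 0
    for q, n_dip in zip(pop_freqs, model.n_diploids_per_pop):
        block = rng.binomial(2, q[:, None], size=(n_sites, n_dip)).astype(np.int8)
        derived_calls[:, col:col + n_dip] = block
        col += n_dip

    # allele labels: ancestral allele is REF or ALT with equal probability
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]
    anc_is_ref = rng.random(n_sites) < 0.5
    calls = np.where(anc_is_ref[:, None], derived_calls, 2 - derived_calls).astype(np.int8)

    ancestral = np.where(anc_is_ref, "ref", "alt").astype(object)
    if polarization_error > 0:
        flip = rng.random(n_sites) < polarization_error
        flipped = np.where(ancestral == "ref", "alt", "ref")
        ancestral[flip] = flipped[flip]

    samples, sample_pop = [], []
    for lab, n_dip in zip(model.pop_labels, model.n_diploids_per_pop):
        samples.extend(f"{lab}_{i:03d}" for i in range(n_dip))
        sample_pop.extend([lab] * n_dip)

    matrix = GenotypeMatrix(
        chrom="chr09",
        positions=positions,
        ref=ref,
        alt=alt,
        ancestral=ancestral,
        calls=calls,
        samples=samples,
        sample_pop=np.array(sample_pop, dtype=object),
    )
    # true (noise-free) per-population derived frequencies, for recovery tests
    matrix.true_derived_freq = {
        lab: q for lab, q in zip(model.pop_labels, pop_freqs)
    }
    matrix.anc_is_ref = anc_is_ref
    return matrix


# ---------------------------------------------------------------------------
# biparental crosses
# ---------------------------------------------------------------------------

def _gametes(haplos: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per individual.

    ``haplos``: (n, 2, n_loci) parental haplotypes; ``r``: recombination
    fraction per adjacent interval.
    """
    n, _, n_loci = haplos.shape
    strand = np.empty((n, n_loci), dtype=np.int8)
    strand[:, 0] = rng.integers(0, 2, size=n)
    for k in range(1, n_loci):
        switch = rng.random(n) < r[k - 1]
        strand[:, k] = np.where(switch, 1 - strand[:, k - 1], strand[:, k - 1])
    return np.take_along_axis(haplos, strand[:, None, :], axis=1)[:, 0, :]


def _viability_accept(geno: np.ndarray, weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-individual acceptance mask under multiplicative viability weights.

    ``geno``: (n, n_loci) dosages in {0,1,2}; ``weights``: (n_loci, 3) strictly
    positive class weights.  Acceptance probability is the product over loci of
    weight[genotype], scaled by the maximum attainable product.
    """
    w = weights[np.arange(weights.shape[0])[None, :], geno]
    fitness = w.prod(axis=1)
    return rng.random(len(fitness)) < fitness / weights.max(axis=1).prod()


def simulate_cross(config: CrossConfig, seed=None) -> GenotypeMatrix:
    """Simulate genotypes of a biparental cross at the configured loci.

    Founders are homozygous opposite: parent A contributes allele 0 and parent
    B allele 1 at every locus, so dosages count parent-B alleles.  The F2 is
    one meiosis from a fully heterozygous F1; genotype classes then follow
    1:2:1 per locus reweighted by the viability ``distortion_weights``.  The
    F8 RILs are produced by single-seed descent (seven selfing meioses from
    the F1), leaving per-locus residual heterozygosity (1/2)^7 before
    distortion is applied.
    """
    rng = _rng(seed)
    n_loci = len(config.loci)
    r = np.array(config._r_list())
    names = [n for n, _ in config.loci]
    w = np.ones((n_loci, 3))
    for i, name in enumerate(names):
        if name in config.distortion_weights:
            w[i] = config.distortion_weights[name]

    n_gen = 1 if config.cross_type == "NIL_F2" else 7
    collected: list[np.ndarray] = []
    n_have = 0
    while n_have < config.n_individuals:
        batch = max(2 * (config.n_individuals - n_have), 64)
        # F1: haplotype 0 all parent-A, haplotype 1 all parent-B
        hap = np.zeros((batch, 2, n_loci), dtype=np.int8)
        hap[:, 1, :] = 1
        for _ in range(n_gen):
            g1 = _gametes(hap, r, rng)
            g2 = _gametes(hap, r, rng)
            hap = np.stack([g1, g2], axis=1)
        geno = hap.sum(axis=1)
        keep = _viability_accept(geno, w, rng)
        collected.append(geno[keep])
        n_have += int(keep.sum())
    geno = np.concatenate(collected, axis=0)[: config.n_individuals]

    order = np.argsort([p for _, p in config.loci], kind="stable")
    positions = np.array([config.loci[i][1] for i in order])
    calls = geno.T[order]  # loci x individuals
    prefix = "F2" if config.cross_type == "NIL_F2" else "RIL"
    samples = [f"{prefix}_{i + 1:04d}" for i in range(config.n_individuals)]
    return GenotypeMatrix(
        chrom="chr09",
        positions=positions,
        ref=np.array(["A"] * n_loci, dtype=object),
        alt=np.array(["T"] * n_loci, dtype=object),
        ancestral=np.array(["unknown"] * n_loci, dtype=object),
        calls=calls.astype(np.int8),
        samples=samples,
        sample_pop=np.array([prefix] * config.n_individuals, dtype=object),
    )


def cross_locus_names(config: CrossConfig) -> list[str]:
    """Locus names in genome order, matching the rows of the simulated matrix."""
    order = np.argsort([p for _, p in config.loci], kind="stable")
    return [config.loci[i][0] for i in order]


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    genotypes: pd.DataFrame,
    model: PhenotypeModel,
    seed=None,
) -> pd.DataFrame:
    """Simulate per-line phenotypes from causal-locus dosages.

    ``genotypes``: lines x loci dosage table (index = line IDs, columns = locus
    names, values in {0,1,2}; -1 marks missing).  Per plant and timepoint the
    value is baseline + sum of per-copy effects x dosage + Gaussian noise; the
    reported per-line value is the mean over ``plants_per_line`` plants.
    Lines missing any causal genotype are skipped with a warning.

    Returns a long table with columns line_id, timepoint, trait, value.
    """
    import warnings

    rng = _rng(model.seed if seed is None else seed)
    loci = list(model.additive_effects)
    missing_cols = [l for l in loci if l not in genotypes.columns]
    if missing_cols:
        raise InvalidParameterError(f"genotypes lack causal loci {missing_cols}")
    G = genotypes[loci].to_numpy()
    ok = (G >= 0).all(axis=1)
    if not ok.all():
        warnings.warn(
            f"skipped {int((~ok).sum())} lines with missing causal genotypes",
            stacklevel=2,
        )
    G = G[ok]
    lines = np.asarray(genotypes.index)[ok]

    records = []
    for t in model.timepoints:
        beta = np.array([model.additive_effects[l].get(t, 0.0) for l in loci])
        mu = model.baseline_mu[t] + G @ beta
        noise = rng.normal(0.0, model._sd(t), size=(len(mu), model.plants_per_line))
        values = mu[:, None] + noise
        line_means = values.mean(axis=1)
        records.append(pd.DataFrame({
            "line_id": lines,
            "timepoint": t,
            "trait": model.trait,
            "value": line_means,
        }))
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# truth serialization for recovery tests
# ---------------------------------------------------------------------------

def truth_dict(model: PopulationModel, sweep: SweepConfig | None) -> dict:
    """JSON-serializable record of simulation parameters and causal loci."""
    out = {
        "pop_labels": list(model.pop_labels),
        "n_diploids_per_pop": list(model.n_diploids_per_pop),
        "drift_F_per_pop": list(model.drift_F_per_pop),
        "chrom_length_bp": model.chrom_length_bp,
        "n_sites": model.n_sites,
        "seed": model.seed,
        "sweep": None,
    }
    if sweep is not None:
        out["sweep"] = {
            "focal_position_bp": sweep.focal_position_bp,
            "target_pop": sweep.target_pop,
            "intensity_w0": sweep.intensity_w0,
            "decay_length_bp": sweep.decay_length_bp,
            "high_freq_floor": sweep.high_freq_floor,
        }
    return out


# keep a stable public surface
__all__ = [
    "PopulationModel",
    "SweepConfig",
    "CrossConfig",
    "PhenotypeModel",
    "draw_neutral_sfs_frequencies",
    "simulate_three_pop_genotypes",
    "simulate_cross",
    "cross_locus_names",
    "simulate_phenotypes",
    "truth_dict",
    "DEFAULT_BASELINE_MU",
    "DEFAULT_RESIDUAL_SD",
]
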