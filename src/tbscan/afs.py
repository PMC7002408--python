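"""Derived allele-frequency spectra around a focal mutation.

A selective sweep drags linked neutral variants toward fixation, producing an
excess of low- and high-frequency derived alleles (a U-shaped spectrum) near
the selected site that decays with distance.  This module polarizes alleles
against an outgroup population, bins segregating sites by distance from a
focal position (10-kb bins out to 80 kb by default), and compares each bin's
derived AFS to the genome-wide background with a two-sample
Kolmogorov-Smirnov test; decay is summarized as the Spearman rank correlation
between bin distance and the KS statistic D (negative = decay).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EmptyInputError, InvalidParameterError
from .genotypes import GenotypeMatrix

log = logging.getLogger("tbscan")


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

@dataclass
class PolarizedSites:
    """Outgroup-polarized sites with focal-population derived frequencies."""

    positions: np.ndarray
    derived_freq: np.ndarray        # derived allele frequency in the focal pop
    ancestral_is_ref: np.ndarray    # bool per retained site
    n_excluded: dict[str, int]


def polarize_derived(
    matrix: GenotypeMatrix,
    focal_pop: str,
    outgroup_pop: str,
    major_cutoff: float = 0.9,
) -> PolarizedSites:
    """Assign ancestral alleles from the outgroup's major allele.

    A site is polarized when the outgroup's major-allele frequency is at least
    ``major_cutoff`` (monomorphic outgroups always qualify); sites where the
    outgroup is too polymorphic or entirely missing are excluded with logged
    counts.  The derived frequency is 1 minus the ancestral-allele frequency
    in the focal population.
    """
    if not (0.5 < major_cutoff <= 1.0):
        raise InvalidParameterError("major_cutoff must be in (0.5, 1]")
    p_out = matrix.alt_freq(outgroup_pop)
    p_focal = matrix.alt_freq(focal_pop)

    missing_out = np.isnan(p_out)
    major = np.fmax(p_out, 1.0 - p_out)
    usable = (~missing_out) & (major >= major_cutoff) & ~np.isnan(p_focal)
    n_excluded = {
        "outgroup_missing": int(missing_out.sum()),
        "outgroup_polymorphic": int(((~missing_out) & (major < major_cutoff)).sum()),
        "focal_missing": int((np.isnan(p_focal) & ~missing_out).sum()),
    }
    if not usable.any():
        raise EmptyInputError("no sites could be polarized against the outgroup")
    if sum(n_excluded.values()):
        log.info("polarize_derived excluded sites: %s", n_excluded)

    anc_is_ref = p_out[usable] < 0.5   # outgroup major allele is REF
    derived = np.where(anc_is_ref, p_focal[usable], 1.0 - p_focal[usable])
    return PolarizedSites(
        positions=matrix.positions[usable],
        derived_freq=derived,
        ancestral_is_ref=anc_is_ref,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# distance-binned spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumWindow:
    """Derived AFS of segregating sites in one distance bin from the focal site."""

    distance_bin_bp: int            # nominal (upper) distance of the bin
    side: str                       # "upstream" | "downstream" | "combined"
    derived_freqs: np.ndarray
    n_snps: int


def distance_binned_spectra(
    polarized: PolarizedSites,
    focal_position: int,
    max_distance: int = 80_000,
    bin_size: int = 10_000,
    side: str = "combined",
) -> list[SpectrumWindow]:
    """Bin polarized segregating sites by distance from the focal position.

    Bin k covers distances ((k-1)*bin_size, k*bin_size] (upper-inclusive);
    sites with derived frequency 0 or 1 are excluded; empty bins are reported
    with n_snps = 0.
    """
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    if side not in ("combined", "upstream", "downstream"):
        raise InvalidParameterError("side must be combined/upstream/downstream")
    d = polarized.positions.astype(np.int64) - int(focal_position)
    freqs = polarized.derived_freq
    seg = (freqs > 0.0) & (freqs < 1.0)
    if side == "upstream":
        keep = seg & (d < 0)
    elif side == "downstream":
        keep = seg & (d > 0)
    else:
        keep = seg & (d != 0)
    dist = np.abs(d[keep])
    f = freqs[keep]

    out = []
    n_bins = int(np.ceil(max_distance / bin_size))
    for k in range(1, n_bins + 1):
        lo, hi = (k - 1) * bin_size, k * bin_size
        in_bin = (dist > lo) & (dist <= hi)
        out.append(SpectrumWindow(
            distance_bin_bp=hi, side=side,
            derived_freqs=f[in_bin], n_snps=int(in_bin.sum()),
        ))
    return out


def background_freqs(
    polarized: PolarizedSites,
    focal_position: int,
    max_distance: int = 80_000,
) -> np.ndarray:
    """Segregating derived frequencies outside the focal +-max_distance region."""
    d = np.abs(polarized.positions.astype(np.int64) - int(focal_position))
    f = polarized.derived_freq
    keep = (d > max_distance) & (f > 0.0) & (f < 1.0)
    return f[keep]


def u_shape_index(derived_freqs, tail: float = 0.1) -> float:
    """Fraction of sites with derived frequency <= tail or >= 1-tail.

    A convenience summary of spectrum U-shapedness (elevated under
    hitch-hiking); NaN for an empty spectrum.
    """
    if not (0.0 < tail < 0.5):
        raise InvalidParameterError("tail must be in (0, 0.5)")
    f = np.asarray(derived_freqs, dtype=float)
    if f.size == 0:
        return float("nan")
    return float(np.mean((f <= tail) | (f >= 1.0 - tail)))


# ---------------------------------------------------------------------------
# KS decay diagnostic
# ---------------------------------------------------------------------------

@dataclass
class KsResult:
    distance_bin_bp: int
    D: float
    p: float
    n_window: int
    n_background: int
    low_count: bool


def ks_decay_test(
    spectra: list[SpectrumWindow],
    background: np.ndarray,
    min_n: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Two-sample KS of each distance bin's AFS against the background.

    Bins with fewer than ``min_n`` sites are flagged and not tested.  The
    decay summary is the Spearman rank correlation between bin distance and
    KS D over tested bins (negative rho = the spectrum approaches the
    background with distance).
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ConfigurationError("background spectrum is empty")
    rows = []
    for w in spectra:
        if w.n_snps < min_n:
            rows.append(KsResult(w.distance_bin_bp, np.nan, np.nan, w.n_snps,
                                 len(background), True))
            continue
        ks = stats.ks_2samp(w.derived_freqs, background, method="asymp")
        rows.append(KsResult(w.distance_bin_bp, float(ks.statistic), float(ks.pvalue),
                             w.n_snps, len(background), False))
    table = pd.DataFrame([r.__dict__ for r in rows])
    tested = table.loc[~table["low_count"]]
    if len(tested) >= 3 and tested["D"].nunique() > 1:
        rho, rho_p = stats.spearmanr(tested["distance_bin_bp"], tested["D"])
        decay = {"spearman_rho": float(rho), "p": float(rho_p), "n_bins": int(len(tested))}
    else:
        decay = {"spearman_rho": float("nan"), "p": float("nan"), "n_bins": int(len(tested))}
    return table, decay


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class HitchhikingScan:
    """Distance-decay diagnostic of the derived AFS around a focal position.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    focal_position : int
        1-based position of the putative causal mutation.
    focal_pop, outgroup_pop : str
        Population whose spectrum is examined, and the outgroup used to
        polarize alleles.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        focal_position: int,
        focal_pop: str,
        outgroup_pop: str,
    ) -> None:
        for pop in (focal_pop, outgroup_pop):
            if pop not in genotypes.populations:
                raise ConfigurationError(f"population {pop!r} not in the genotype matrix")
        self.genotypes = genotypes
        self.focal_position = int(focal_position)
        self.focal_pop = focal_pop
        self.outgroup_pop = outgroup_pop

    @classmethod
    def from_files(cls, vcf_path, pop_map_path, focal_position, focal_pop, outgroup_pop):
        from .io import read_vcf

        return cls(read_vcf(vcf_path, pop_map_path), focal_position, focal_pop, outgroup_pop)

    def fit(
        self,
        max_distance: int = 80_000,
        bin_size: int = 10_000,
        side: str = "combined",
        tail: float = 0.1,
        major_cutoff: float = 0.9,
        min_n: int = 5,
    ) -> "HitchhikingResults":
        polarized = polarize_derived(self.genotypes, self.focal_pop,
                                     self.outgroup_pop, major_cutoff)
        spectra = distance_binned_spectra(polarized, self.focal_position,
                                          max_distance, bin_size, side)
        bg = background_freqs(polarized, self.focal_position, max_distance)
        ks_table, decay = ks_decay_test(spectra, bg, min_n=min_n)
        ks_table.insert(1, "side", side)
        ks_table.insert(2, "n_snps", [w.n_snps for w in spectra])
        ks_table.insert(3, "u_shape_index", [u_shape_index(w.derived_freqs, tail)
                                             for w in spectra])
        return HitchhikingResults(
            model=self, polarized=polarized, spectra=spectra,
            table=ks_table.drop(columns=["n_window"]), decay=decay,
            background_n=len(bg), tail=tail,
        )


@dataclass
class HitchhikingResults:
    model: HitchhikingScan
    polarized: PolarizedSites
    spectra: list[SpectrumWindow]
    table: pd.DataFrame            # distance_bin_bp, side, n_snps, u_shape_index, D, p, ...
    decay: dict
    background_n: int
    tail: float

    def summary(self) -> str:
        lines = [
            "Hitch-hiking AFS diagnostic",
            "---------------------------",
            f"focal position {self.model.focal_position} in {self.model.focal_pop} "
            f"(outgroup {self.model.outgroup_pop})",
            f"background sites: {self.background_n}",
            self.table.to_string(index=False, float_format=lambda x: f"{x:.4g}"),
            f"decay: Spearman rho = {self.decay['spearman_rho']:.3f} "
            f"(P = {self.decay['p']:.3g}, {self.decay['n_bins']} bins)",
        ]
        return "\n".join(lines)
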