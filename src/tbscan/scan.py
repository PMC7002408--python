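"""Selective-sweep scan: Nei FST, sliding windows, PBS, HKA-style test.

The scan has two layers.  The windowed layer averages per-site Nei FST (the
GST form, (HT-HS)/HT with the unweighted mean frequency) over 20-kb windows
sliding in 2-kb steps and flags the genome-wide top fraction (default 5
per-mille) as candidate regions.  The gene layer computes, per gene and over
coding SNPs only, pairwise mean FST among three populations, Cavalli-Sforza
branch lengths T = -ln(1-FST), the population branch statistic (PBS) of the
target population, and a polymorphism/fixation contrast (an HKA-style 2x2
chi-square of the gene's segregating-to-fixed-site ratio against the
genome-wide ratio).  Genes ranking in the top PBS fraction (default 5%) with
a nominal HKA P below alpha (default 0.05) are called sweep candidates.

Use :class:`SelectionScan` for the fitted-model interface or the module
functions directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DataError,
    EmptyInputError,
    InvalidParameterError,
    UndefinedTestError,
)
from .genotypes import GenotypeMatrix
from .io import GeneAnnotation


# ---------------------------------------------------------------------------
# per-site FST
# ---------------------------------------------------------------------------

@dataclass
class SiteFst:
    position: int | None
    p1: float
    p2: float
    HT: float
    HS: float
    fst: float
    segregating: bool


def nei_fst(p1, p2):
    """Vectorized Nei FST (GST): (HT - HS)/HT with unweighted mean frequency.

    Sites monomorphic in both populations (HT = 0) are defined as FST 0.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise InvalidParameterError("allele frequencies must lie in [0,1]")
    pbar = (p1 + p2) / 2.0
    HT = 2.0 * pbar * (1.0 - pbar)
    HS = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(HT > 0, (HT - HS) / np.where(HT > 0, HT, 1.0), 0.0)
    return fst


def site_fst(p1: float, p2: float, position: int | None = None) -> SiteFst:
    """Scalar Nei FST with the intermediate heterozygosities."""
    fst = float(nei_fst(p1, p2))
    pbar = (p1 + p2) / 2.0
    HT = 2.0 * pbar * (1.0 - pbar)
    HS = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    return SiteFst(position, float(p1), float(p2), HT, HS, fst, segregating=HT > 0)


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def window_starts(chrom_length: int, window: int, step: int) -> np.ndarray:
    """0-based start coordinates of windows tiling [0, chrom_length)."""
    if step > window:
        raise ConfigurationError("step larger than window would drop SNPs between windows")
    if window < 1 or step < 1:
        raise InvalidParameterError("window and step must be positive")
    if chrom_length < window:
        return np.array([0], dtype=np.int64)
    n = (chrom_length - window) // step + 1
    return np.arange(n, dtype=np.int64) * step


def window_fst(
    positions,
    fst,
    chrom_length: int,
    window: int = 20_000,
    step: int = 2_000,
    chrom: str = "chr",
) -> pd.DataFrame:
    """Mean per-site FST in sliding windows.

    A SNP at 1-based position p belongs to the window [start, start+window)
    iff start <= p < start+window.  Empty windows are reported with
    n_snps = 0 and a missing mean.  Output coordinates are 0-based half-open.
    """
    positions = np.asarray(positions)
    fst = np.asarray(fst, dtype=float)
    if np.any(np.diff(positions) < 0):
        raise DataError("positions must be sorted")
    starts = window_starts(chrom_length, window, step)
    csum = np.concatenate([[0.0], np.cumsum(fst)])
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, starts + window, side="left")
    n = hi - lo
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
    return pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": starts + window,
        "step_index": np.arange(len(starts)),
        "n_snps": n,
        "mean_fst": mean,
    })


def top_quantile_threshold(values, q: float) -> tuple[float, np.ndarray]:
    """Empirical (1-q) quantile and the mask of values at or above it.

    Ties at the threshold are all included; NaNs are never flagged.
    """
    if not (0.0 < q < 1.0):
        raise InvalidParameterError("q must be in (0,1)")
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise EmptyInputError("no finite values to threshold")
    threshold = float(np.quantile(finite, 1.0 - q))
    with np.errstate(invalid="ignore"):
        flags = values >= threshold
    flags &= np.isfinite(values)
    return threshold, flags


# ---------------------------------------------------------------------------
# branch lengths and PBS
# ---------------------------------------------------------------------------

def branch_length_T(fst):
    """Cavalli-Sforza divergence transform T = -ln(1 - FST).

    FST = 1 is clamped to 1 - 1e-12 with a warning.
    """
    fst = np.asarray(fst, dtype=float)
    if np.any((fst < 0) | (fst > 1)):
        raise InvalidParameterError("FST must lie in [0,1]")
    if np.any(fst >= 1.0):
        warnings.warn("FST of 1 clamped to 1-1e-12 in branch-length transform", stacklevel=2)
        fst = np.minimum(fst, 1.0 - 1e-12)
    out = -np.log1p(-fst)
    return float(out) if out.ndim == 0 else out


def pbs_score(T12, T13, T23, mode: str = "standard"):
    """Population branch statistic for population 1.

    mode="standard": (T12 + T13 - T23)/2 (may be negative).
    mode="paper": (T12 + T13 + T23)/2, the literal form of the printed
    equation, kept behind a flag because it is almost certainly a typesetting
    slip; the mode is recorded by callers in output metadata.
    """
    T12, T13, T23 = (np.asarray(t, dtype=float) for t in (T12, T13, T23))
    if np.any(T12 < 0) or np.any(T13 < 0) or np.any(T23 < 0):
        raise InvalidParameterError("branch lengths must be non-negative")
    if mode == "standard":
        out = (T12 + T13 - T23) / 2.0
    elif mode == "paper":
        out = (T12 + T13 + T23) / 2.0
    else:
        raise InvalidParameterError(f"unknown PBS mode {mode!r}")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# per-gene statistics and the HKA-style contrast
# ---------------------------------------------------------------------------

def gene_fst_and_counts(
    matrix: GenotypeMatrix,
    genes: list[GeneAnnotation],
    pops: tuple[str, str, str],
    fixation_fst_cutoff: float = 0.9,
    a_sites: str = "coding",
    a_pop: str = "focal",
    count_fixed_in_A: bool = False,
) -> pd.DataFrame:
    """Per-gene pairwise mean FST and polymorphism/fixation counts.

    ``pops`` orders (focal/target, sister, third).  Over each gene's coding
    SNPs: A counts sites segregating (0 < p < 1) in the focal population
    (``a_pop="any"``: in any population); B counts sites whose FST against
    BOTH other populations strictly exceeds ``fixation_fst_cutoff``.
    ``a_sites="all"`` counts A over all SNPs in the gene span instead of
    coding SNPs only.  Genes without coding SNPs get A = B = 0 and missing
    FST means.

    By default the two classes are disjoint: a site meeting the fixation rule
    is counted in B only, matching the polymorphism-versus-fixation dichotomy
    the 2x2 contingency test assumes (a doubly-counted site breaks the
    table's multinomial model and makes the chi-square conservative).
    ``count_fixed_in_A=True`` restores the literal overlapping counts.
    """
    if a_sites not in ("coding", "all") or a_pop not in ("focal", "any"):
        raise InvalidParameterError("a_sites must be coding|all, a_pop focal|any")
    p = {pop: matrix.alt_freq(pop) for pop in pops}
    f12 = nei_fst(p[pops[0]], p[pops[1]])
    f13 = nei_fst(p[pops[0]], p[pops[2]])
    f23 = nei_fst(p[pops[1]], p[pops[2]])
    seg_focal = (p[pops[0]] > 0) & (p[pops[0]] < 1)
    seg_any = seg_focal | ((p[pops[1]] > 0) & (p[pops[1]] < 1)) | ((p[pops[2]] > 0) & (p[pops[2]] < 1))
    seg = seg_focal if a_pop == "focal" else seg_any
    fixed = (f12 > fixation_fst_cutoff) & (f13 > fixation_fst_cutoff)
    if not count_fixed_in_A:
        seg = seg & ~fixed

    rows = []
    for g in genes:
        idx = g.site_index(matrix)
        if a_sites == "all":
            s, e = g.span
            idx_a = matrix.site_index_in(s, e)
        else:
            idx_a = idx
        n = len(idx)
        rows.append({
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.span[0],
            "end": g.span[1],
            "n_coding_snps": n,
            "fst12": np.nanmean(f12[idx]) if n else np.nan,
            "fst13": np.nanmean(f13[idx]) if n else np.nan,
            "fst23": np.nanmean(f23[idx]) if n else np.nan,
            "A": int(seg[idx_a].sum()),
            "B": int(fixed[idx].sum()),
        })
    return pd.DataFrame(rows)


@dataclass
class HkaResult:
    chi2: float
    p: float
    table: np.ndarray
    low_count: bool


def hka_test(A_gene: int, B_gene: int, A_genome: int, B_genome: int) -> HkaResult:
    """Pearson 2x2 chi-square of the gene's A/B ratio against the genome's.

    Table: [[A_gene, B_gene], [A_genome - A_gene, B_genome - B_gene]];
    no continuity correction, df = 1.  Any expected cell below 1 flags the
    result low-count.  A zero row or column margin makes the test undefined.
    """
    for name, v in (("A_gene", A_gene), ("B_gene", B_gene),
                    ("A_genome", A_genome), ("B_genome", B_genome)):
        if v < 0:
            raise InvalidParameterError(f"{name} must be non-negative")
    if A_gene > A_genome or B_gene > B_genome:
        raise InvalidParameterError("genome totals must be at least the gene counts")
    a, b = float(A_gene), float(B_gene)
    c, d = float(A_genome - A_gene), float(B_genome - B_gene)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0 or n == 0:
        raise UndefinedTestError("HKA table has a zero margin")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    expected = np.array([[r1 * c1, r1 * c2], [r2 * c1, r2 * c2]]) / n
    return HkaResult(float(chi2), p, np.array([[a, b], [c, d]]), bool(expected.min() < 1))


@dataclass
class ScanThresholds:
    """Candidate-calling thresholds of the scan."""

    window_quantile: float = 0.005
    pbs_quantile: float = 0.05
    hka_alpha: float = 0.05
    fixation_fst_cutoff: float = 0.9

    def __post_init__(self) -> None:
        for name in ("window_quantile", "pbs_quantile", "hka_alpha", "fixation_fst_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InvalidParameterError(f"{name} must be in (0,1)")


def sweep_candidates(gene_stats: pd.DataFrame, thresholds: ScanThresholds | None = None) -> pd.DataFrame:
    """Genes in the top PBS fraction with nominal HKA P < alpha, PBS-descending.

    ``gene_stats`` must carry ``pbs`` and ``hka_p`` columns.
    """
    thresholds = thresholds or ScanThresholds()
    if len(gene_stats) < 20:
        warnings.warn("fewer than 20 genes: the PBS quantile threshold is unstable", stacklevel=2)
    _, pbs_flag = top_quantile_threshold(gene_stats["pbs"].to_numpy(), thresholds.pbs_quantile)
    hka_flag = gene_stats["hka_p"].to_numpy() < thresholds.hka_alpha
    out = gene_stats.loc[pbs_flag & hka_flag].copy()
    return out.sort_values("pbs", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class SelectionScan:
    """Selection scan over a genotype matrix with three labelled populations.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    genes : list of GeneAnnotation, optional
        Coding annotations for the gene-level (PBS/HKA) layer.
    pops : (target, sister, third)
        Population ordering; the PBS branch is computed for the target.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        genes: list[GeneAnnotation] | None = None,
        pops: tuple[str, str, str] | None = None,
    ) -> None:
        self.genotypes = genotypes
        self.genes = genes
        available = genotypes.populations
        if pops is None:
            if len(available) != 3:
                raise ConfigurationError("pops must be given unless exactly three populations are labelled")
            pops = tuple(available)
        missing = [p for p in pops if p not in available]
        if missing:
            raise ConfigurationError(f"populations not in the genotype matrix: {missing}")
        self.pops = tuple(pops)

    @classmethod
    def from_files(cls, vcf_path, pop_map_path, genes_path=None, pops=None) -> "SelectionScan":
        from .io import read_genes, read_vcf

        matrix = read_vcf(vcf_path, pop_map_path)
        genes = read_genes(genes_path) if genes_path else None
        return cls(matrix, genes, pops)

    def fit(
        self,
        thresholds: ScanThresholds | None = None,
        window: int = 20_000,
        step: int = 2_000,
        chrom_length: int | None = None,
        pbs_mode: str = "standard",
        a_sites: str = "coding",
        a_pop: str = "focal",
    ) -> "SelectionScanResults":
        thresholds = thresholds or ScanThresholds()
        m = self.genotypes
        target, sister, third = self.pops
        p_t, p_s = m.alt_freq(target), m.alt_freq(sister)
        fst_ts = nei_fst(p_t, p_s)
        L = chrom_length or int(m.positions[-1]) + 1
        windows = window_fst(m.positions, fst_ts, L, window, step, chrom=m.chrom)
        wthr, wflag = top_quantile_threshold(windows["mean_fst"].to_numpy(), thresholds.window_quantile)
        windows["candidate"] = wflag

        genes_df = None
        candidates = None
        if self.genes is not None:
            genes_df = gene_fst_and_counts(
                m, self.genes, self.pops,
                fixation_fst_cutoff=thresholds.fixation_fst_cutoff,
                a_sites=a_sites, a_pop=a_pop,
            )
            T12 = branch_length_T(np.nan_to_num(genes_df["fst12"].to_numpy()))
            T13 = branch_length_T(np.nan_to_num(genes_df["fst13"].to_numpy()))
            T23 = branch_length_T(np.nan_to_num(genes_df["fst23"].to_numpy()))
            genes_df["T12"], genes_df["T13"], genes_df["T23"] = T12, T13, T23
            genes_df["pbs"] = pbs_score(T12, T13, T23, mode=pbs_mode)
            genes_df.loc[genes_df["n_coding_snps"] == 0, ["T12", "T13", "T23", "pbs"]] = np.nan
            A_tot = int(genes_df["A"].sum())
            B_tot = int(genes_df["B"].sum())
            if B_tot == 0 or A_tot == 0:
                raise DataError("genome-wide polymorphism/fixation margin is zero; HKA undefined")
            chi2s, ps, lows = [], [], []
            for a, b in zip(genes_df["A"], genes_df["B"]):
                if a + b == 0:
                    chi2s.append(np.nan)
                    ps.append(np.nan)
                    lows.append(True)
                    continue
                res = hka_test(int(a), int(b), A_tot, B_tot)
                chi2s.append(res.chi2)
                ps.append(res.p)
                lows.append(res.low_count)
            genes_df["chi2"] = chi2s
            genes_df["hka_p"] = ps
            genes_df["hka_low_count"] = lows
            _, pbs_flag = top_quantile_threshold(genes_df["pbs"].to_numpy(), thresholds.pbs_quantile)
            genes_df["candidate"] = pbs_flag & (genes_df["hka_p"].to_numpy() < thresholds.hka_alpha)
            candidates = sweep_candidates(genes_df, thresholds)

        return SelectionScanResults(
            model=self, windows=windows, window_threshold=wthr,
            genes=genes_df, candidates=candidates,
            thresholds=thresholds, pbs_mode=pbs_mode,
            window_size=window, step=step, chrom_length=L,
        )


@dataclass
class SelectionScanResults:
    """Windowed and gene-level scan output with candidate calls."""

    model: SelectionScan
    windows: pd.DataFrame
    window_threshold: float
    genes: pd.DataFrame | None
    candidates: pd.DataFrame | None
    thresholds: ScanThresholds
    pbs_mode: str
    window_size: int
    step: int
    chrom_length: int

    def summary(self) -> str:
        lines = [
            "Selection scan summary",
            "----------------------",
            f"populations (target, sister, third): {self.model.pops}",
            f"windows: {len(self.windows)} of {self.window_size} bp every {self.step} bp; "
            f"top-{self.thresholds.window_quantile:.3%} mean-FST threshold = {self.window_threshold:.4f}",
            f"candidate windows: {int(self.windows['candidate'].sum())}",
        ]
        if self.genes is not None:
            n_cand = len(self.candidates) if self.candidates is not None else 0
            lines += [
                f"genes scored: {len(self.genes)} (PBS mode: {self.pbs_mode})",
                f"sweep candidates (PBS top {self.thresholds.pbs_quantile:.0%} and "
                f"HKA P < {self.thresholds.hka_alpha}): {n_cand}",
            ]
            if n_cand:
                top = self.candidates.iloc[0]
                lines.append(f"top candidate: {top['gene_id']} "
                             f"(PBS={top['pbs']:.3f}, HKA P={top['hka_p']:.3g})")
        return "\n".join(lines)
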