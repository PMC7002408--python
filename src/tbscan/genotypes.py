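"""In-memory container for biallelic SNP genotypes with population labels.

The matrix is sites x samples, calls count copies of the ALT allele
(0, 1, 2; -1 for missing).  Positions are 1-based, matching VCF.  Each site
optionally records which allele is ancestral ("ref", "alt" or "unknown"),
which downstream code uses to polarize derived allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InvalidParameterError

MISSING = -1


@dataclass
class GenotypeMatrix:
    chrom: str
    positions: np.ndarray          # int64, 1-based, strictly increasing
    ref: np.ndarray                # allele strings
    alt: np.ndarray
    ancestral: np.ndarray          # per site: "ref" | "alt" | "unknown"
    calls: np.ndarray              # int8 (n_sites, n_samples); ALT-allele dosage
    samples: list[str]
    sample_pop: np.ndarray         # population label per sample

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.ancestral = np.asarray(self.ancestral, dtype=object)
        self.sample_pop = np.asarray(self.sample_pop, dtype=object)
        n_sites, n_samples = self.calls.shape
        if len(self.positions) != n_sites:
            raise DataError("positions and calls disagree on the number of sites")
        if len(self.samples) != n_samples or len(self.sample_pop) != n_samples:
            raise DataError("samples/sample_pop and calls disagree on the number of samples")
        if n_sites > 1 and np.any(np.diff(self.positions) <= 0):
            raise DataError("positions must be strictly increasing")
        bad = set(np.unique(self.calls)) - {-1, 0, 1, 2}
        if bad:
            raise DataError(f"calls must be in {{0,1,2,-1}}; found {sorted(bad)}")
        bad_aa = set(self.ancestral) - {"ref", "alt", "unknown"}
        if bad_aa:
            raise DataError(f"ancestral states must be ref/alt/unknown; found {sorted(bad_aa)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_pop:
            seen.setdefault(p, None)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        mask = self.sample_pop == pop
        if not mask.any():
            raise InvalidParameterError(f"unknown population {pop!r}")
        return mask

    # -- frequencies ----------------------------------------------------
    def alt_freq(self, pop: str | None = None) -> np.ndarray:
        """Per-site ALT allele frequency, ignoring missing calls.

        Sites where every call is missing yield NaN.
        """
        calls = self.calls if pop is None else self.calls[:, self.pop_mask(pop)]
        present = calls != MISSING
        n_chroms = 2 * present.sum(axis=1)
        alt_count = np.where(present, calls, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chroms > 0, alt_count / np.maximum(n_chroms, 1), np.nan)

    def derived_freq(self, pop: str) -> np.ndarray:
        """Per-site derived allele frequency using the recorded ancestral state.

        Sites with unknown ancestral state yield NaN.
        """
        p_alt = self.alt_freq(pop)
        out = np.full(self.n_sites, np.nan)
        is_ref = self.ancestral == "ref"
        is_alt = self.ancestral == "alt"
        out[is_ref] = p_alt[is_ref]           # ALT is derived
        out[is_alt] = 1.0 - p_alt[is_alt]     # REF is derived
        return out

    # -- slicing --------------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[index],
            ref=self.ref[index],
            alt=self.alt[index],
            ancestral=self.ancestral[index],
            calls=self.calls[index, :],
            samples=list(self.samples),
            sample_pop=self.sample_pop.copy(),
        )

    def site_index_in(self, start: int, end: int) -> np.ndarray:
        """Indices of sites with 1-based position in [start, end] inclusive."""
        lo = np.searchsorted(self.positions, start, side="left")
        hi = np.searchsorted(self.positions, end, side="right")
        return np.arange(lo, hi)

    def to_frame(self, site_ids: list[str] | None = None) -> pd.DataFrame:
        """Samples x sites dosage table (rows keyed by sample name)."""
        ids = site_ids if site_ids is not None else [
            f"{self.chrom}:{p}" for p in self.positions
        ]
        return pd.DataFrame(self.calls.T, index=list(self.samples), columns=ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypeMatrix({self.chrom}: {self.n_sites} sites x "
            f"{self.n_samples} samples, pops={self.populations})"
        )
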