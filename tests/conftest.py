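import numpy as np
import pytest

from tbscan.genotypes import GenotypeMatrix
from tbscan.io import GeneAnnotation
from tbscan.synthetic import PopulationModel, SweepConfig

POPS = ("upland_jap", "irrigated_jap", "indica")


def make_matrix(calls, positions=None, pops=None, ancestral=None, chrom="chr09"):
    """Small hand-built GenotypeMatrix for unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    positions = np.asarray(positions if positions is not None
                           else np.arange(1, n_sites + 1) * 100)
    pops = list(pops) if pops is not None else ["p1"] * n_samples
    ancestral = ancestral if ancestral is not None else ["unknown"] * n_sites
    return GenotypeMatrix(
        chrom=chrom,
        positions=positions,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        ancestral=np.array(ancestral, dtype=object),
        calls=calls,
        samples=[f"s{i}" for i in range(n_samples)],
        sample_pop=np.array(pops, dtype=object),
    )


def tiled_genes(chrom_length, gene_length=2_000, spacing=10_000, chrom="chr09"):
    genes, k = [], 0
    for start in range(1, chrom_length - gene_length, spacing):
        k += 1
        genes.append(GeneAnnotation(f"gene{k:05d}", chrom,
                                    [(start, start + gene_length - 1)]))
    return genes


@pytest.fixture(scope="session")
def neutral_matrix():
    """Mid-sized neutral three-population simulation shared across tests."""
    model = PopulationModel(n_sites=8_000, chrom_length_bp=800_000,
                            drift_F_per_pop=(0.15, 0.15, 0.3), seed=11)
    return model.simulate()


@pytest.fixture(scope="session")
def swept_matrix():
    """Same conditions with a strong sweep implanted at 400 kb."""
    model = PopulationModel(n_sites=8_000, chrom_length_bp=800_000,
                            drift_F_per_pop=(0.15, 0.15, 0.3), seed=11)
    sweep = SweepConfig(focal_position_bp=400_000, target_pop=POPS[0],
                        intensity_w0=0.8, decay_length_bp=20_000)
    return model.simulate(sweep)
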