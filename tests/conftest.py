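import numpy as np
import pytest

from hylin import GenotypeMatrix
from hylin.simdata import (
    fixed_parental_frequencies,
    make_pedigree,
    pedigree_to_matrix,
    sample_population,
)


def make_matrix(G, pos=None, chrom=None, groups=None, depth=None):
    """Small handcrafted GenotypeMatrix (samples x sites dosage array)."""
    G = np.asarray(G, dtype=np.int8)
    n_samples, n_sites = G.shape
    pos = np.arange(1, n_sites + 1) * 100 if pos is None else np.asarray(pos)
    chrom = np.array(["chr1"] * n_sites, dtype=object) if chrom is None else np.asarray(chrom, dtype=object)
    groups = np.array(["other"] * n_samples, dtype=object) if groups is None else np.asarray(groups, dtype=object)
    return GenotypeMatrix(
        samples=np.array([f"s{i}" for i in range(n_samples)], dtype=object),
        groups=groups,
        chrom=chrom,
        pos=pos,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        G=G,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
    )


def fixed_panel_scenario(n_loci=200, seed=0, pedigree_counts=None, n_parents=10):
    """Parents fixed for alternative alleles plus the requested pedigree.

    Returns (matrix with parental samples + pedigree individuals,
    pedigree individuals, frequencies).
    """
    freqs, config = fixed_parental_frequencies(
        n_loci=n_loci,
        seed=seed,
        sample_sizes={"parentalA": n_parents, "parentalB": n_parents},
        pedigree_counts=pedigree_counts or {},
    )
    rng = np.random.default_rng(seed + 17)
    mA = sample_population(freqs, "parentalA", n_parents, seed=rng, id_prefix="A")
    mB = sample_population(freqs, "parentalB", n_parents, seed=rng, id_prefix="B")
    parts = [mA, mB]
    individuals = []
    if pedigree_counts:
        individuals = make_pedigree(freqs, config, rng)
        parts.append(pedigree_to_matrix(individuals, freqs))
    matrix = GenotypeMatrix(
        samples=np.concatenate([m.samples for m in parts]),
        groups=np.concatenate([m.groups for m in parts]),
        chrom=freqs.chrom,
        pos=freqs.pos,
        ref=parts[0].ref,
        alt=parts[0].alt,
        G=np.concatenate([m.G for m in parts], axis=0),
    )
    return matrix, individuals, freqs


@pytest.fixture(scope="session")
def f1_scenario():
    """Fixed 200-locus parental lines with F1, F2, BC1 pedigree individuals."""
    return fixed_panel_scenario(
        n_loci=200,
        seed=11,
        pedigree_counts={"F1": 5, "F2": 5, "BC1A": 5, "BC1B": 5,
                         "parentalA": 3, "parentalB": 3},
    )
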