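"""Invariants-based hybridization test (γ) and SNP quartet concordance factors.

The hybridization test works on a quartet (outgroup, P1, hybrid, P2).
At each SNP, allele frequencies are polarized on the outgroup's major
allele, and three ABBA/BABA-family site-pattern weights are accumulated
from derived-allele frequencies d:

* ``x1``: hybrid shares the derived allele with P1
  (d_P1 * d_H * (1 - d_P2) * (1 - d_O)),
* ``x2``: hybrid shares the derived allele with P2,
* ``x3``: P1 and P2 share the derived allele to the exclusion of the
  hybrid (the incomplete-lineage-sorting baseline).

Under incomplete lineage sorting alone the excesses x1 - x3 and x2 - x3
are both zero in expectation; a hybrid lineage shows a positive excess
with *both* parents, and the parental contribution is estimated as
``γ = (x1 - x3) / ((x1 - x3) + (x2 - x3))``. Significance uses a
delete-one block jackknife of f_min = min(x1 - x3, x2 - x3).

Concordance factors summarize genome-wide discordance for a four-species
quartet: sampled one-individual-per-species quartets are scored at every
site where one randomly sampled allele per individual splits 2/2; each such
site supports exactly one of the three quartet resolutions, and the three
supported fractions (which sum to 1) are averaged over quartets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PatternContributions:
    """Per-site contributions to the three pattern sums, in genome order."""

    quartet: tuple[str, str, str, str]  # (outgroup, P1, hybrid, P2)
    x1_site: np.ndarray
    x2_site: np.ndarray
    x3_site: np.ndarray
    n_skipped_outgroup: int = 0
    n_skipped_monomorphic: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.x1_site)

    @property
    def sums(self) -> tuple[float, float, float]:
        return (
            float(self.x1_site.sum()),
            float(self.x2_site.sum()),
            float(self.x3_site.sum()),
        )


@dataclass
class HybridizationResult:
    quartet: tuple[str, str, str, str]
    x1: float
    x2: float
    x3: float
    gamma: float  # fraction of hybrid ancestry from P1; nan when undefined
    z: float
    p: float
    n_sites: int
    n_blocks: int
    no_signal: bool = False  # True when either derived-allele excess <= 0


@dataclass
class QuartetCF:
    species: tuple[str, str, str, str]
    cf: np.ndarray  # support for splits 12|34, 13|24, 14|23
    n_quartets: int
    n_informative_sites: float  # mean per sampled quartet
    per_quartet: np.ndarray | None = field(default=None, repr=False)


# ----------------------------------------------------------------------


def pattern_frequencies(
    matrix: GenotypeMatrix, groups: tuple[str, str, str, str]
) -> PatternContributions:
    """Per-site site-pattern weights for a quartet (outgroup, P1, hybrid, P2).

    Derived-allele frequencies are polarized on the outgroup major allele
    (sites where the outgroup alternative-allele frequency is exactly 0.5
    are skipped as unpolarizable). Sites with no genotyped outgroup
    individual are skipped and counted; sites monomorphic across the
    ingroup contribute nothing and are dropped.
    """
    out_g, p1_g, hyb_g, p2_g = groups
    f = {g: matrix.allele_freq(g) for g in groups}
    for g in groups:
        if len(matrix.sample_indices(g)) == 0:
            raise ValueError(f"group {g!r} has no samples")
    usable = np.ones(matrix.n_sites, dtype=bool)
    no_out = np.isnan(f[out_g])
    usable &= ~no_out
    for g in (p1_g, hyb_g, p2_g):
        usable &= ~np.isnan(f[g])
    usable &= f[out_g] != 0.5  # ambiguous polarization
    d = {}
    flip = f[out_g] > 0.5
    for g in groups:
        d[g] = np.where(flip, 1.0 - f[g], f[g])
    ingroup_mono = (
        (d[p1_g] == d[hyb_g]) & (d[hyb_g] == d[p2_g]) & np.isin(d[p1_g], (0.0, 1.0))
    )
    usable &= ~ingroup_mono
    dO, d1, dH, d2 = d[out_g][usable], d[p1_g][usable], d[hyb_g][usable], d[p2_g][usable]
    x1 = d1 * dH * (1.0 - d2) * (1.0 - dO)
    x2 = (1.0 - d1) * dH * d2 * (1.0 - dO)
    x3 = d1 * (1.0 - dH) * d2 * (1.0 - dO)
    return PatternContributions(
        quartet=groups,
        x1_site=x1,
        x2_site=x2,
        x3_site=x3,
        n_skipped_outgroup=int(no_out.sum()),
        n_skipped_monomorphic=int(ingroup_mono.sum()),
    )


def gamma_test(
    contrib: PatternContributions, n_blocks: int = 100
) -> HybridizationResult:
    """Estimate γ and test for hybridization by block jackknife.

    γ̂ = (x1 - x3) / ((x1 - x3) + (x2 - x3)). The test statistic is
    f_min = min(x1 - x3, x2 - x3): a genuine hybrid must share an excess of
    derived alleles with *both* parents. Z = f_min / SE_jack(f_min) over
    delete-one contiguous site blocks; one-tailed p = 1 - Φ(Z). When either
    excess is non-positive γ̂ is clamped to [0, 1] and the result flagged
    ``no_signal``.
    """
    n_sites = contrib.n_sites
    if n_sites < n_blocks:
        raise ValueError(f"need >= {n_blocks} informative sites, have {n_sites}")
    x1, x2, x3 = contrib.sums
    e1, e2 = x1 - x3, x2 - x3
    denom = e1 + e2
    no_signal = e1 <= 0 or e2 <= 0
    if denom <= 0:
        gamma = np.nan
    else:
        gamma = min(max(e1 / denom, 0.0), 1.0)

    blocks1 = np.array_split(contrib.x1_site, n_blocks)
    blocks2 = np.array_split(contrib.x2_site, n_blocks)
    blocks3 = np.array_split(contrib.x3_site, n_blocks)
    fmin_full = min(e1, e2)
    theta = np.empty(n_blocks)
    for i in range(n_blocks):
        b1 = x1 - blocks1[i].sum()
        b2 = x2 - blocks2[i].sum()
        b3 = x3 - blocks3[i].sum()
        theta[i] = min(b1 - b3, b2 - b3)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((theta - theta.mean()) ** 2).sum())
    z = fmin_full / se if se > 0 else np.inf * np.sign(fmin_full)
    p = float(stats.norm.sf(z))
    p = max(min(p, 1.0), np.nextafter(0, 1))
    return HybridizationResult(
        quartet=contrib.quartet,
        x1=x1,
        x2=x2,
        x3=x3,
        gamma=float(gamma),
        z=float(z),
        p=p,
        n_sites=n_sites,
        n_blocks=n_blocks,
        no_signal=no_signal,
    )


def hyde_test(
    matrix: GenotypeMatrix,
    outgroup: str,
    p1: str,
    hybrid: str,
    p2: str,
    n_blocks: int = 100,
) -> HybridizationResult:
    """Convenience wrapper: pattern sums + γ jackknife test on a matrix."""
    contrib = pattern_frequencies(matrix, (outgroup, p1, hybrid, p2))
    return gamma_test(contrib, n_blocks=n_blocks)


# ----------------------------------------------------------------------
# Concordance factors


def snp_concordance_factors(
    matrix: GenotypeMatrix,
    species: tuple[str, str, str, str],
    n_quartets: int = 100,
    seed: int | np.random.Generator = 0,
    sample_alleles: bool = True,
) -> QuartetCF:
    """SNP concordance factors for a four-species quartet.

    For each of ``n_quartets`` sampled quartets (one individual per
    species, uniform with replacement across quartets), one allele per
    individual is sampled from each genotype; a site is informative when
    the four sampled alleles split exactly 2/2, and then supports exactly
    one of the three resolutions 12|34, 13|24, 14|23. Per-quartet CFs are
    the supported fractions; the returned CF is their mean over quartets
    (quartets with zero informative sites are skipped). With
    ``sample_alleles=False`` both alleles of each diploid are used and
    sites are informative when the four diploids split 4/4 allele copies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = [matrix.sample_indices(s) for s in species]
    for s, ix in zip(species, idx):
        if len(ix) == 0:
            raise ValueError(f"species {s!r} has no individuals")
    per_quartet = []
    n_inf = []
    for _ in range(n_quartets):
        chosen = [ix[rng.integers(len(ix))] for ix in idx]
        G = matrix.G[chosen, :]  # (4, n_sites)
        ok = (G != MISSING).all(axis=0)
        if sample_alleles:
            # one random allele per diploid: het -> Bernoulli(1/2)
            alleles = np.where(
                G == 1, rng.integers(0, 2, size=G.shape), (G // 2)
            ).astype(np.int8)
        else:
            alleles = G
        total = alleles.sum(axis=0) if sample_alleles else G.sum(axis=0)
        informative = ok & (total == (2 if sample_alleles else 4))
        if sample_alleles:
            a = alleles[:, informative]
            support = np.zeros(3)
            s12 = (a[0] == a[1]) & (a[2] == a[3])
            s13 = (a[0] == a[2]) & (a[1] == a[3])
            s14 = (a[0] == a[3]) & (a[1] == a[2])
            support[0] = s12.sum()
            support[1] = s13.sum()
            support[2] = s14.sum()
        else:
            g = G[:, informative]
            support = np.zeros(3)
            support[0] = ((g[0] == g[1]) & (g[2] == g[3]) & (g[0] != g[2])).sum()
            support[1] = ((g[0] == g[2]) & (g[1] == g[3]) & (g[0] != g[1])).sum()
            support[2] = ((g[0] == g[3]) & (g[1] == g[2]) & (g[0] != g[1])).sum()
        tot = support.sum()
        n_inf.append(tot)
        if tot > 0:
            per_quartet.append(support / tot)
    if not per_quartet:
        raise ValueError("no informative sites in any sampled quartet")
    per_quartet = np.array(per_quartet)
    cf = per_quartet.mean(axis=0)
    cf = cf / cf.sum()  # exact normalization (guards accumulated rounding)
    return QuartetCF(
        species=species,
        cf=cf,
        n_quartets=len(per_quartet),
        n_informative_sites=float(np.mean(n_inf)),
        per_quartet=per_quartet,
    )
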