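"""Forward-time synthetic genotype data under a hybrid-speciation demography.

The generator reproduces, forward in time at the allele-frequency level, the
demographic scenario inferred for the Lake Xiloá Midas cichlid system: two
parental species diverge from a common ancestor ``tau_split`` generations
ago, and a hybrid lineage is founded ``tau_hybrid`` generations ago as a
mixture containing a fraction ``phi`` of parental-A ancestry, after which it
drifts with its own effective size. An outgroup lineage diverges earlier.
Default parameter values follow the posterior means of the study system's
coalescent demographic fit (tau_split = 2578, tau_hybrid = 242,
phi = 0.5461, Ne of order 10^3-10^4) with a mutation rate of 3.5e-9 per
site per generation and a 1.5-year generation time kept as metadata.

Drift is per-generation Wright-Fisher binomial sampling of allele
frequencies (p' = B(2*Ne, p) / (2*Ne)); only standing variation is modelled
(no new mutations during the simulated epoch), with an optional injection of
private alleles for marker-discovery testing. Explicit pedigree individuals
(F1, F2, first-generation backcrosses) are built by Mendelian crosses with
Poisson crossovers, retaining per-haplotype true-ancestry labels so that
every downstream classifier can be checked against known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, write_group_table, write_vcf

PEDIGREE_CLASSES = ("parentalA", "parentalB", "F1", "F2", "BC1A", "BC1B")

#: pedigree class -> sample group label used in output tables
CLASS_TO_GROUP = {
    "parentalA": "parentalA",
    "parentalB": "parentalB",
    "F1": "hybrid",
    "F2": "hybrid",
    "BC1A": "backcross",
    "BC1B": "backcross",
}

#: expected (ancestry S, interclass heterozygosity H) per pedigree class
CLASS_EXPECTATIONS = {
    "parentalA": (1.0, 0.0),
    "parentalB": (0.0, 0.0),
    "F1": (0.5, 1.0),
    "F2": (0.5, 0.5),
    "BC1A": (0.75, 0.5),
    "BC1B": (0.25, 0.5),
}


@dataclass
class SimConfig:
    """Ground-truth demographic configuration.

    Sizes are diploid effective sizes; times are in generations before
    present; ``recomb_rate`` is in cM per Mb (1 cM = 1% recombinants per
    meiosis). ``sample_sizes`` gives diploid counts per output group and
    defaults to the study's sampling design (13 + 10 parentals, 11 hybrids,
    21 outgroup). A fixed ``seed`` makes all output byte-identical.
    """

    n_chromosomes: int = 24
    chrom_length: int = 37_500_000
    n_loci: int = 88_369
    mu: float = 3.5e-9
    recomb_rate: float = 1.0  # cM / Mb
    ne_ancestral: int = 44_301
    ne_parentalA: int = 23_280
    ne_parentalB: int = 17_329
    ne_hybrid: int = 6_369
    ne_outgroup: int | None = None  # defaults to ne_ancestral
    tau_split: int = 2_578
    tau_hybrid: int = 242
    phi: float = 0.5461
    outgroup_time: int | None = None  # defaults to 4 * tau_split
    sample_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "parentalA": 13,
            "parentalB": 10,
            "hybrid": 11,
            "outgroup": 21,
        }
    )
    pedigree_counts: Mapping[str, int] = field(default_factory=dict)
    # ancestral allele-frequency distribution: Beta(a, b) truncated to bounds
    ancestral_beta: tuple[float, float] = (0.8, 0.8)
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    # optional per-generation migrant fraction parental -> hybrid
    migration_A: float = 0.0
    migration_B: float = 0.0
    # optional injected private alleles: group -> number of loci
    private_mutations: Mapping[str, int] = field(default_factory=dict)
    generation_time_years: float = 1.5  # metadata only
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")
        if not 0 <= self.tau_hybrid <= self.tau_split:
            raise ValueError("need 0 <= tau_hybrid <= tau_split")
        for name in ("ne_ancestral", "ne_parentalA", "ne_parentalB", "ne_hybrid"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.ne_outgroup is not None and self.ne_outgroup < 1:
            raise ValueError("ne_outgroup must be >= 1")
        if self.chrom_length * self.n_chromosomes < self.n_loci:
            raise ValueError("genome shorter than requested locus count")
        if self.outgroup_time is not None and self.outgroup_time < self.tau_split:
            raise ValueError("outgroup must diverge before tau_split")
        if self.migration_A + self.migration_B > 1.0:
            raise ValueError("migrant fractions sum above 1")
        unknown = set(self.pedigree_counts) - set(PEDIGREE_CLASSES)
        if unknown:
            raise ValueError(f"unknown pedigree classes: {sorted(unknown)}")

    @property
    def t_outgroup(self) -> int:
        return self.outgroup_time if self.outgroup_time is not None else 4 * self.tau_split

    @property
    def ne_out(self) -> int:
        return self.ne_outgroup if self.ne_outgroup is not None else self.ne_ancestral

    @classmethod
    def desk_scale(cls, factor: int = 20, **overrides) -> "SimConfig":
        """Study demography with all Ne and times divided by ``factor``.

        Scaling Ne and generation counts together preserves every branch's
        drift ratio tau / (2 Ne), so frequency-level statistics keep their
        expectations while runtime drops by the same factor.
        """
        base = dict(
            ne_ancestral=max(1, round(44_301 / factor)),
            ne_parentalA=max(1, round(23_280 / factor)),
            ne_parentalB=max(1, round(17_329 / factor)),
            ne_hybrid=max(1, round(6_369 / factor)),
            tau_split=max(1, round(2_578 / factor)),
            tau_hybrid=max(1, round(242 / factor)),
            n_loci=50_000,
            n_chromosomes=24,
            chrom_length=1_000_000,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_file(cls, path: str) -> "SimConfig":
        """Read a flat ``key = value`` text config (``#`` comments allowed)."""
        import ast

        values: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                key = key.strip()
                try:
                    values[key] = ast.literal_eval(raw.strip())
                except (ValueError, SyntaxError):
                    values[key] = raw.strip()
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(values) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**values)


@dataclass
class PopulationFrequencies:
    """Per-locus alternative-allele frequencies for the terminal populations.

    ``founding`` retains the parental frequencies at the moment the hybrid
    lineage was founded together with the exact mixture frequency, for
    oracle checks of the founding invariant.
    """

    chrom: np.ndarray
    pos: np.ndarray
    freqs: dict[str, np.ndarray]
    founding: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return len(self.pos)


@dataclass
class PedigreeIndividual:
    """A pedigree individual with per-haplotype allele and ancestry tracks.

    ``haplotypes`` is a (2, n_loci) int8 array of alleles; ``ancestry`` a
    (2, n_loci) uint8 array with 0 = parental-A origin, 1 = parental-B.
    """

    id: str
    class_label: str
    haplotypes: np.ndarray
    ancestry: np.ndarray

    @property
    def genotypes(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int8)

    @property
    def true_S(self) -> float:
        """Realized parental-A ancestry fraction across both haplotypes."""
        return float(1.0 - self.ancestry.mean())

    @property
    def true_H(self) -> float:
        """Realized fraction of loci with one allele of each ancestry."""
        return float((self.ancestry[0] != self.ancestry[1]).mean())


# ----------------------------------------------------------------------
# Wright-Fisher drift


def wright_fisher_drift(
    p: np.ndarray, ne: int, generations: int, rng: np.random.Generator
) -> np.ndarray:
    """Drift allele frequencies ``generations`` steps at diploid size ``ne``.

    Each generation resamples 2*Ne allele copies binomially:
    p' = Binomial(2*Ne, p) / (2*Ne). Neutral, so E[p'] = p and the one-step
    variance is p(1-p)/(2*Ne).
    """
    p = np.asarray(p, dtype=float).copy()
    n = 2 * int(ne)
    for _ in range(int(generations)):
        p = rng.binomial(n, p) / n
    return p


def _truncated_beta(
    n: int, a: float, b: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Beta(a, b) truncated to [lo, hi] by inverse-CDF sampling."""
    u = rng.uniform(stats.beta.cdf(lo, a, b), stats.beta.cdf(hi, a, b), size=n)
    return stats.beta.ppf(u, a, b)


def _draw_positions(config: SimConfig, n: int, rng: np.random.Generator):
    """Distinct sorted (chromosome, position) pairs, uniform over the genome."""
    chroms = np.array([f"chr{i + 1}" for i in range(config.n_chromosomes)], dtype=object)
    out_c = np.empty(0, dtype=np.int64)
    out_p = np.empty(0, dtype=np.int64)
    while len(out_p) < n:
        need = n - len(out_p)
        c = rng.integers(0, config.n_chromosomes, size=2 * need + 16)
        p = rng.integers(1, config.chrom_length + 1, size=len(c))
        key = np.concatenate([out_c * (config.chrom_length + 1) + out_p,
                              c * (config.chrom_length + 1) + p])
        key = np.unique(key)[:n]
        out_c = key // (config.chrom_length + 1)
        out_p = key % (config.chrom_length + 1)
    order = np.lexsort((out_p, out_c))
    return chroms[out_c[order]], out_p[order]


def simulate_frequencies(config: SimConfig, rng=None) -> PopulationFrequencies:
    """Run the demographic model at the allele-frequency level.

    Ancestral frequencies are drawn from the configured truncated Beta,
    drifted down the outgroup and ingroup-stem branches, split into the two
    parental branches at ``tau_split``, and mixed into the hybrid lineage at
    ``tau_hybrid`` with initial frequency ``phi * p_A + (1 - phi) * p_B``.
    Loci that end monomorphic for the same allele in *all* populations (and
    so would never be called as SNPs) are dropped; the count is recorded in
    ``meta['dropped_fixed']``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom, pos = _draw_positions(config, config.n_loci, rng)
    a, b = config.ancestral_beta
    lo, hi = config.freq_bounds
    p0 = _truncated_beta(config.n_loci, a, b, lo, hi, rng)

    p_out = wright_fisher_drift(p0, config.ne_out, config.t_outgroup, rng)
    p_anc = wright_fisher_drift(
        p0, config.ne_ancestral, config.t_outgroup - config.tau_split, rng
    )
    pre = config.tau_split - config.tau_hybrid
    p_a = wright_fisher_drift(p_anc, config.ne_parentalA, pre, rng)
    p_b = wright_fisher_drift(p_anc, config.ne_parentalB, pre, rng)

    founding = {
        "parentalA": p_a.copy(),
        "parentalB": p_b.copy(),
        "hybrid": config.phi * p_a + (1.0 - config.phi) * p_b,
    }
    p_h = founding["hybrid"].copy()

    m_a, m_b = config.migration_A, config.migration_B
    if m_a == 0.0 and m_b == 0.0:
        p_a = wright_fisher_drift(p_a, config.ne_parentalA, config.tau_hybrid, rng)
        p_b = wright_fisher_drift(p_b, config.ne_parentalB, config.tau_hybrid, rng)
        p_h = wright_fisher_drift(p_h, config.ne_hybrid, config.tau_hybrid, rng)
    else:
        for _ in range(config.tau_hybrid):
            p_a = wright_fisher_drift(p_a, config.ne_parentalA, 1, rng)
            p_b = wright_fisher_drift(p_b, config.ne_parentalB, 1, rng)
            p_h = (1.0 - m_a - m_b) * p_h + m_a * p_a + m_b * p_b
            p_h = wright_fisher_drift(p_h, config.ne_hybrid, 1, rng)

    freqs = {"parentalA": p_a, "parentalB": p_b, "hybrid": p_h, "outgroup": p_out}

    # drop loci monomorphic for the same allele in every population: these
    # would never appear as SNPs in a variant file (loci fixed for
    # *different* alleles across populations are fixed differences and kept)
    lost = np.ones(config.n_loci, dtype=bool)
    gone = np.ones(config.n_loci, dtype=bool)
    for p in freqs.values():
        lost &= p == 0.0
        gone &= p == 1.0
    keep = ~(lost | gone)
    n_dropped = int((~keep).sum())
    chrom, pos = chrom[keep], pos[keep]
    freqs = {k: v[keep] for k, v in freqs.items()}
    founding = {k: v[keep] for k, v in founding.items()}

    out = PopulationFrequencies(
        chrom=chrom,
        pos=pos,
        freqs=freqs,
        founding=founding,
        meta={"dropped_fixed": n_dropped, "config": config},
    )
    if config.private_mutations:
        out = _inject_private_alleles(out, config, rng)
    return out


def _inject_private_alleles(
    freqs: PopulationFrequencies, config: SimConfig, rng: np.random.Generator
) -> PopulationFrequencies:
    """Append loci carrying an allele segregating in exactly one population.

    A testing convenience for private-allele discovery: injected loci get a
    present-day frequency drawn Uniform(0.5, 0.95) in the focal population
    and exactly 0 elsewhere (no drift applied).
    """
    n_extra = sum(config.private_mutations.values())
    chrom_x, pos_x = _draw_positions(config, n_extra, rng)
    new_freqs = {k: np.zeros(n_extra) for k in freqs.freqs}
    start = 0
    for group, count in config.private_mutations.items():
        if group not in new_freqs:
            raise ValueError(f"unknown population {group!r}")
        new_freqs[group][start : start + count] = rng.uniform(0.5, 0.95, size=count)
        start += count
    chrom = np.concatenate([freqs.chrom, chrom_x])
    pos = np.concatenate([freqs.pos, pos_x])
    merged = {k: np.concatenate([freqs.freqs[k], new_freqs[k]]) for k in freqs.freqs}
    order = np.lexsort((pos, chrom.astype(str)))
    # drop duplicate coordinates possibly introduced by the second draw
    key = pd.MultiIndex.from_arrays([chrom[order].astype(str), pos[order]])
    uniq = ~key.duplicated()
    idx = order[np.asarray(uniq)]
    founding = {
        k: np.concatenate([v, np.zeros(n_extra)]) for k, v in freqs.founding.items()
    }
    return PopulationFrequencies(
        chrom=chrom[idx],
        pos=pos[idx],
        freqs={k: v[idx] for k, v in merged.items()},
        founding={k: v[idx] for k, v in founding.items()},
        meta=dict(freqs.meta, injected_private=dict(config.private_mutations)),
    )


def fixed_parental_frequencies(
    n_loci: int = 200, seed: int = 0, **config_overrides
) -> tuple[PopulationFrequencies, SimConfig]:
    """Idealized fully diagnostic scenario: parents fixed for alternative alleles.

    Parental A carries the alternative allele at frequency 1 and parental B
    at 0 at every locus, with one locus per chromosome so all loci are
    unlinked. Useful for exact pedigree expectations (an F1 is heterozygous
    everywhere; a diagnostic panel built from samples is fully fixed).
    """
    defaults = dict(
        n_chromosomes=n_loci,
        chrom_length=100_000,
        n_loci=n_loci,
        ne_ancestral=100,
        ne_parentalA=100,
        ne_parentalB=100,
        ne_hybrid=100,
        tau_split=1,
        tau_hybrid=0,
        sample_sizes={"parentalA": 10, "parentalB": 10},
        seed=seed,
    )
    defaults.update(config_overrides)
    config = SimConfig(**defaults)
    # deterministic round-robin placement: loci spread as evenly as possible
    # over chromosomes (one per chromosome when n_loci == n_chromosomes, so
    # "unlinked" genuinely means unlinked)
    n = config.n_loci
    chrom_idx = np.arange(n) % config.n_chromosomes
    rank = np.arange(n) // config.n_chromosomes
    per_chrom = -(-n // config.n_chromosomes)
    spacing = max(1, config.chrom_length // (per_chrom + 1))
    pos_all = (rank + 1) * spacing
    order = np.lexsort((pos_all, chrom_idx))
    chrom = np.array([f"chr{i + 1}" for i in chrom_idx[order]], dtype=object)
    pos = pos_all[order].astype(np.int64)
    freqs = PopulationFrequencies(
        chrom=chrom,
        pos=pos,
        freqs={
            "parentalA": np.ones(n),
            "parentalB": np.zeros(n),
            "hybrid": np.full(n, config.phi),
            "outgroup": np.zeros(n),
        },
        meta={"config": config, "scenario": "fixed-parental"},
    )
    return freqs, config


# ----------------------------------------------------------------------
# Diploid sampling


def sample_population(
    freqs: PopulationFrequencies,
    group: str,
    n: int,
    seed: int | np.random.Generator = 0,
    id_prefix: str | None = None,
    group_label: str | None = None,
) -> GenotypeMatrix:
    """Sample ``n`` diploids from a population under Hardy-Weinberg.

    Each genotype is an independent Binomial(2, p) draw per locus.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if group not in freqs.freqs:
        raise KeyError(f"unknown population {group!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = freqs.freqs[group]
    G = rng.binomial(2, p, size=(n, freqs.n_loci)).astype(np.int8)
    prefix = id_prefix if id_prefix is not None else group
    label = group_label if group_label is not None else group
    return GenotypeMatrix(
        samples=np.array([f"{prefix}_{i:03d}" for i in range(n)], dtype=object),
        groups=np.array([label] * n, dtype=object),
        chrom=freqs.chrom,
        pos=freqs.pos,
        ref=np.array(["A"] * freqs.n_loci, dtype=object),
        alt=np.array(["T"] * freqs.n_loci, dtype=object),
        G=G,
    )


# ----------------------------------------------------------------------
# Pedigree construction


def _sample_founder(
    freqs: PopulationFrequencies, pop: str, rng: np.random.Generator, ident: str
) -> PedigreeIndividual:
    p = freqs.freqs[pop]
    hap = (rng.random((2, freqs.n_loci)) < p).astype(np.int8)
    anc_code = 0 if pop == "parentalA" else 1
    return PedigreeIndividual(
        id=ident,
        class_label=pop,
        haplotypes=hap,
        ancestry=np.full((2, freqs.n_loci), anc_code, dtype=np.uint8),
    )


def _gamete(
    parent: PedigreeIndividual,
    chrom: np.ndarray,
    pos: np.ndarray,
    chrom_length: int,
    recomb_cm_per_mb: float,
    rng: np.random.Generator,
):
    """One meiotic product: Poisson crossovers on a uniform genetic map."""
    n_loci = parent.haplotypes.shape[1]
    allele = np.empty(n_loci, dtype=np.int8)
    anc = np.empty(n_loci, dtype=np.uint8)
    morgans = chrom_length * recomb_cm_per_mb / 1e6 / 100.0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        n_cross = rng.poisson(morgans)
        breaks = np.sort(rng.uniform(0, chrom_length, size=n_cross))
        start = rng.integers(0, 2)
        # haplotype in use at each locus = start + #breakpoints upstream, mod 2
        which = (start + np.searchsorted(breaks, pos[idx])) % 2
        allele[idx] = parent.haplotypes[which, idx]
        anc[idx] = parent.ancestry[which, idx]
    return allele, anc


def _cross(
    mother: PedigreeIndividual,
    father: PedigreeIndividual,
    label: str,
    ident: str,
    chrom: np.ndarray,
    pos: np.ndarray,
    chrom_length: int,
    recomb: float,
    rng: np.random.Generator,
) -> PedigreeIndividual:
    a1, c1 = _gamete(mother, chrom, pos, chrom_length, recomb, rng)
    a2, c2 = _gamete(father, chrom, pos, chrom_length, recomb, rng)
    return PedigreeIndividual(
        id=ident,
        class_label=label,
        haplotypes=np.stack([a1, a2]),
        ancestry=np.stack([c1, c2]),
    )


def make_pedigree(
    freqs: PopulationFrequencies, config: SimConfig, rng=None
) -> list[PedigreeIndividual]:
    """Build the requested explicit-pedigree individuals.

    Founders are fresh Hardy-Weinberg draws from the parental frequency
    vectors; F1 = A-founder x B-founder, F2 = F1 x F1 (two independent
    F1s), BC1A = F1 x A-founder, BC1B = F1 x B-founder. Crossovers follow a
    Poisson process on the uniform genetic map, and true-ancestry labels
    propagate through every meiosis.
    """
    if not config.pedigree_counts:
        raise ValueError("pedigree_counts is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    for pop in ("parentalA", "parentalB"):
        if pop not in freqs.freqs:
            raise KeyError(f"founder population {pop!r} missing from frequencies")
    args = (freqs.chrom, freqs.pos, config.chrom_length, config.recomb_rate, rng)

    def new_f1(ident: str) -> PedigreeIndividual:
        mom = _sample_founder(freqs, "parentalA", rng, ident + "_fA")
        dad = _sample_founder(freqs, "parentalB", rng, ident + "_fB")
        return _cross(mom, dad, "F1", ident, *args)

    out: list[PedigreeIndividual] = []
    for cls in PEDIGREE_CLASSES:  # fixed order for determinism
        for i in range(config.pedigree_counts.get(cls, 0)):
            ident = f"{cls}_{i:03d}"
            if cls in ("parentalA", "parentalB"):
                out.append(_sample_founder(freqs, cls, rng, ident))
            elif cls == "F1":
                out.append(new_f1(ident))
            elif cls == "F2":
                out.append(_cross(new_f1(ident + "_p1"), new_f1(ident + "_p2"),
                                  "F2", ident, *args))
            elif cls == "BC1A":
                out.append(_cross(new_f1(ident + "_p1"),
                                  _sample_founder(freqs, "parentalA", rng, ident + "_p2"),
                                  "BC1A", ident, *args))
            elif cls == "BC1B":
                out.append(_cross(new_f1(ident + "_p1"),
                                  _sample_founder(freqs, "parentalB", rng, ident + "_p2"),
                                  "BC1B", ident, *args))
    return out


def pedigree_to_matrix(
    individuals: Sequence[PedigreeIndividual], freqs: PopulationFrequencies
) -> GenotypeMatrix:
    """Stack pedigree individuals into a :class:`GenotypeMatrix`."""
    G = np.stack([ind.genotypes for ind in individuals])
    return GenotypeMatrix(
        samples=np.array([ind.id for ind in individuals], dtype=object),
        groups=np.array(
            [CLASS_TO_GROUP[ind.class_label] for ind in individuals], dtype=object
        ),
        chrom=freqs.chrom,
        pos=freqs.pos,
        ref=np.array(["A"] * freqs.n_loci, dtype=object),
        alt=np.array(["T"] * freqs.n_loci, dtype=object),
        G=G,
    )


# ----------------------------------------------------------------------
# Full simulation


@dataclass
class SimResult:
    config: SimConfig
    frequencies: PopulationFrequencies
    matrix: GenotypeMatrix
    truth: pd.DataFrame  # sample_id, group, true_class, true_S, true_H


def simulate(config: SimConfig) -> SimResult:
    """Population samples plus pedigree individuals in one genotype matrix.

    Deterministic in ``config.seed``: the same configuration yields
    byte-identical VCF output.
    """
    rng = np.random.default_rng(config.seed)
    freqs = simulate_frequencies(config, rng)

    parts: list[GenotypeMatrix] = []
    rows: list[dict] = []
    for group in ("outgroup", "parentalA", "parentalB", "hybrid"):
        n = config.sample_sizes.get(group, 0)
        if n <= 0:
            continue
        m = sample_population(freqs, group, n, seed=rng)
        parts.append(m)
        truth_S = {"parentalA": 1.0, "parentalB": 0.0}.get(group, np.nan)
        if group == "hybrid":
            truth_S = config.phi
        for s in m.samples:
            rows.append(
                dict(sample_id=s, group=group, true_class=group,
                     true_S=truth_S, true_H=np.nan)
            )
    individuals = (
        make_pedigree(freqs, config, rng) if config.pedigree_counts else []
    )
    if individuals:
        parts.append(pedigree_to_matrix(individuals, freqs))
        for ind in individuals:
            rows.append(
                dict(
                    sample_id=ind.id,
                    group=CLASS_TO_GROUP[ind.class_label],
                    true_class=ind.class_label,
                    true_S=ind.true_S,
                    true_H=ind.true_H,
                )
            )
    if not parts:
        raise ValueError("no samples requested")
    matrix = GenotypeMatrix(
        samples=np.concatenate([m.samples for m in parts]),
        groups=np.concatenate([m.groups for m in parts]),
        chrom=freqs.chrom,
        pos=freqs.pos,
        ref=parts[0].ref,
        alt=parts[0].alt,
        G=np.concatenate([m.G for m in parts], axis=0),
    )
    return SimResult(
        config=config,
        frequencies=freqs,
        matrix=matrix,
        truth=pd.DataFrame(rows),
    )


def write_simulation(result: SimResult, prefix: str) -> None:
    """Write PREFIX.vcf, PREFIX.groups.tsv and PREFIX.truth.tsv."""
    write_vcf(result.matrix, prefix + ".vcf")
    write_group_table(
        result.matrix, prefix + ".groups.tsv", true_class=result.truth["true_class"]
    )
    result.truth.to_csv(prefix + ".truth.tsv", sep="\t", index=False)
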