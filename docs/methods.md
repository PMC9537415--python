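# Methods

## The inference problem

A homoploid hybrid lineage in its earliest stages is distinguishable from
ongoing hybridization only quantitatively: contemporary F1s are
heterozygous at every marker that separates the parental species, first
backcrosses carry ~75/25 ancestry with ~50% interclass heterozygosity,
while a closed hybrid population loses interclass heterozygosity by
recombination every generation yet keeps an intermediate genome-wide
ancestry fraction. hylin implements the estimators that read this
signature out of SNP data, and a forward simulator that generates data of
known truth to validate them.

## Demographic model and simulator

`simdata` simulates allele frequencies forward in time under neutral
Wright–Fisher drift: each generation resamples p′ = Binomial(2Ne, p)/2Ne.
The default configuration mirrors the crater-lake cichlid system the
toolkit was built around:

| parameter | default | meaning |
|---|---|---|
| `tau_split` | 2578 generations | parental species divergence |
| `tau_hybrid` | 242 generations | founding of the hybrid lineage |
| `phi` | 0.5461 | fraction of hybrid ancestry from parental A |
| `ne_ancestral` | 44 301 | diploid Ne of the ancestral branch |
| `ne_parentalA` / `ne_parentalB` | 23 280 / 17 329 | terminal parental sizes |
| `ne_hybrid` | 6 369 | hybrid-lineage size |
| `mu` | 3.5e-9 /site/generation | mutation rate (metadata; see below) |
| `recomb_rate` | 1 cM/Mb | uniform physical→genetic map |
| `sample_sizes` | 13 + 10 + 11 + 21 | parental A/B, hybrid, outgroup diploids |

Design choices where the underlying demographic fit leaves the simulator
unconstrained:

* **Ancestral frequencies** are drawn from Beta(0.8, 0.8) truncated to
  [0.05, 0.95] — a U-shaped, segregating spectrum resembling a neutral
  SFS; both parameters are configurable.
* **Forward drift instead of a coalescent.** The scenario was originally
  fit with a coalescent-with-introgression model; simulating it forward as
  per-generation binomial drift is equivalent in expectation for every
  frequency-based statistic tested here, and makes the founding event
  explicit: at `tau_hybrid` the hybrid lineage starts at exactly
  p₀ = φ·p_A + (1 − φ)·p_B (asserted by tests) and then drifts with its
  own Ne. The published demographic fit also reports sizes for internal
  nodes of its species graph; those have no unambiguous branch mapping
  here, so only the ancestral and three terminal sizes are used.
* **Outgroup divergence** is not part of the fitted scenario; default
  4 × `tau_split`, configurable, with `ne_outgroup` defaulting to the
  ancestral size.
* **Standing variation only.** No new mutations arise during the simulated
  epoch — consistent with the empirical finding that most hybrid-private
  alleles derive from standing variation. A `private_mutations` option
  injects loci segregating in exactly one population (frequency
  Uniform(0.5, 0.95), zero elsewhere) as a marker-discovery test aid.
* **Monomorphic loci** (same allele fixed in *every* population) are
  dropped with a reported count, since they could never be called as SNPs.
  Loci fixed for *different* alleles across populations are kept — they
  are the fixed differences the marker module exists to find.
* **Optional continuous backcrossing**: per-generation migrant fractions
  from each parental population into the hybrid lineage (default 0).
* `desk_scale(k)` divides all Ne and all times by `k` (default 20),
  preserving every branch's drift ratio τ/2Ne, so statistics keep their
  expectations at a fraction of the runtime. The validation suite runs at
  this scale with 5 × 10⁴ loci.

Diploid population samples are Binomial(2, p) draws (Hardy–Weinberg).
Pedigree individuals (F1, F2, BC1A, BC1B) are built by explicit meioses:
founders are fresh HW draws from the parental frequencies, gametes place
crossovers as a Poisson process on the uniform genetic map (1 cM = 1%
recombinants), and every haplotype carries a per-locus true-ancestry
label, so realized S and H of each simulated individual are known exactly.

What the simulator deliberately does **not** emulate: linkage
disequilibrium within population samples (frequencies are independent
across loci; linkage exists only inside pedigree meioses), sequencing
error, depth variation and missingness (tests add these synthetically),
selection, and population structure within species. Passing tests
therefore demonstrate statistical correctness of the estimators under the
stated demography, not robustness to artifacts of a real calling pipeline.

## Genotype I/O and filters

Coordinates are 1-based (VCF convention); windows are half-open
[start, start + size). Reading keeps only biallelic SNPs, masks genotype
calls with FORMAT/DP below `min_depth` (default 5) to missing, and
accepts `/` or `|` separators — phase is never used downstream. Thinning
is greedy-from-left per chromosome (keep the first site, then each site
≥ `min_bp` beyond the last kept one); the dialect is recorded in output
metadata since other tools may subsample differently. The missing-data
filter can be scoped to named groups (e.g. "no missing data within the
parental species").

## Markers

A site is a **fixed difference** when the parental-A allele frequency
among genotyped individuals is exactly 1.0 in one parent and 0.0 in the
other (no distance thinning, matching the exploratory use of physically
close fixed SNPs to see recombination). The **relaxed diagnostic panel**
requires ≥ `hi` (0.95) in one parent and ≤ `lo` (0.05) in the other, then
50-kb thinning; each site is oriented so "the parental-A allele" is the
high-frequency allele in parental A, and the panel stores the parental
frequencies (freqA, freqB) for likelihood use. **Private alleles** must
segregate at frequency ≥ 0.5 (but < 1) in the focal group and have zero
observed copies in every comparison group — one copy elsewhere
disqualifies. Because "at least 50% frequency" and "carried by at least
50% of individuals" differ, both criteria are implemented
(`criterion="freq"` is primary; `"carrier"` optional). Frequencies use
genotyped individuals only; the intended workflow applies the
no-missing-data filter upstream.

Recoded genotypes count copies of the non-parental-A allele: 0 =
homozygous parental A, 1 = heterozygous, 2 = homozygous for the other
parent's variant.

## Hybrid index and the (S, H) triangle

For coded genotype g at locus *l*, with q_l(h) = (1 − h)(1 − freqA_l) +
h(1 − freqB_l) the probability that a random allele is non-parental-A,
the hybrid index maximizes Π_l Binomial(2, q_l(h)) over h ∈ [0, 1]
(bounded scalar optimization, boundary-snapped; a 2-log-unit profile
support interval is reported). For a fully fixed panel the MLE is the
allele-count fraction Σg/(2n), so ĥ = 1 − Ŝ there.

The joint (S, H) likelihood marginalizes each locus over three ancestry
classes with P(AA) = S − H/2, P(AB) = H, P(BB) = 1 − S − H/2, drawing each
allele from the corresponding parental frequency; the triangle constraint
H ≤ 2 min(S, 1 − S) keeps these probabilities non-negative. Maximization
is a 0.02-step grid over the triangle followed by Nelder–Mead refinement
in the square reparameterization (S, v) with H = v·2 min(S, 1 − S);
refinement is accepted only on strict improvement, so exact boundary
optima (corners, apex) survive as exact values. Loci are treated as
independent — the same approximation the 50-kb panel thinning is meant to
justify — and missing genotypes are dropped per individual per locus.

**Classification** evaluates the log-likelihood at six fixed hypothesis
points — parental A (1, 0), parental B (0, 0), F1 (0.5, 1), F2 (0.5, 0.5),
BC1A (0.75, 0.5), BC1B (0.25, 0.5) — and at the free MLE. The best fixed
class is kept unless the free MLE beats it by more than `class_margin`
log-units per free parameter (default 2.0, i.e. 4 log-units for the
2-parameter MLE, an AIC-style penalty), in which case the individual is a
`later_generation_hybrid`. The margin is deliberately exposed: it trades
false "later-generation" calls on true F2/BC1 individuals (whose MLE
fluctuates around an interior point) against sensitivity to genuinely
advanced generations. Ties prefer the fixed (simpler) hypothesis.

The **inbreeding coefficient** is the method-of-moments
F = 1 − (observed het count)/(Σ 2p_l(1 − p_l)) over an individual's
genotyped polymorphic sites, with reference frequencies from a designated
group or all samples.

## Hybridization test and γ

For the quartet (outgroup, P1, hybrid, P2), sites are polarized on the
outgroup major allele (outgroup alternative-allele frequency exactly 0.5
is unpolarizable and skipped); with derived-allele frequencies d the
per-site weights are

    x1 += d_P1 · d_H · (1 − d_P2) · (1 − d_O)
    x2 += (1 − d_P1) · d_H · d_P2 · (1 − d_O)
    x3 += d_P1 · (1 − d_H) · d_P2 · (1 − d_O)

x3 is the incomplete-lineage-sorting baseline: under a species tree with
no gene flow E[x1 − x3] = E[x2 − x3] = 0, while a hybrid lineage shows a
positive excess with *both* parents. The estimator
γ̂ = (x1 − x3)/((x1 − x3) + (x2 − x3)) is consistent for the founding
contribution φ under symmetric parental drift; when the parental Ne
differ, unequal post-founding drift biases the pattern sums, which is why
the validation suite recovers γ under equal parental sizes and the result
object flags `no_signal` whenever either excess is non-positive (γ̂ is
then clamped and not interpretable). Significance uses a delete-one block
jackknife (default 100 contiguous equal-count site blocks) of
f_min = min(x1 − x3, x2 − x3): Z = f_min/SE_jack, one-tailed p = 1 − Φ(Z).
The analytic-variance alternative used by some external tools is not
implemented; the jackknife makes no independence assumption within
blocks. Which parent is "P1" is the caller's choice; relabeling maps
γ̂ → 1 − γ̂ exactly.

## Concordance factors

For four species, `n_quartets` (default 100) quartets are sampled with one
individual per species (uniform with replacement, seeded). Within a
quartet, one allele per individual is sampled per site (heterozygotes
contribute either allele with probability ½); a site is informative when
the four sampled alleles split 2/2 and then supports exactly one
resolution (12|34, 13|24, 14|23). Per-quartet CFs are supported fractions
(summing to 1 exactly); the reported CF averages over quartets. A
both-alleles mode exists but the seeded single-allele sampler is the
default, since haplotype phase is not assumed. Under a clean species tree
the two minor CFs are equal in expectation; a hybrid inflates both
resolutions pairing it with a parent, and a star phylogeny gives
(⅓, ⅓, ⅓).

## F_st and PCA

Per-site Weir & Cockerham (1984) components a, b, c are computed from
genotype counts with unequal, per-site sample sizes (r = 2 populations;
sites with fewer than two genotyped diploids in either group, or
monomorphic across both, are skipped). The window statistic is the
weighted ratio Σa/Σ(a + b + c) over sites in each non-overlapping window
(default 10 kb); negative values are preserved, and the genome-wide
summary is the median of weighted window values — the convention of the
standard VCF tooling — with the unweighted per-site mean also emitted.
PCA mean-imputes missing dosages, centers per site (no variance scaling
by default, matching the common genotype-PCA default; scaling is a flag),
uses a full SVD, and fixes component signs by making each component's
largest-magnitude loading positive.

## Numerical notes

* Likelihoods clip probabilities at 1e-300 before logs; impossible fixed
  classes get −inf and can never win.
* The (S, H) grid contains the exact class points, so degenerate data
  (e.g. an all-heterozygous F1 at a fixed panel) yields exact estimates
  rather than optimizer approximations.
* Jackknife SE of 0 (constant blocks) maps Z to ±inf and p to the
  appropriate limit rather than NaN.
* `array_split` blocks differ in size by at most one site.
* Simulation determinism: one `numpy` Generator seeded from
  `SimConfig.seed` drives the whole run; identical configs give
  byte-identical VCF output.

## Validation problem sizes

The test suite validates γ recovery at φ ∈ {0.25, 0.5, 0.75} on 20
replicates each of the desk-scaled (factor 20) demography with 5 × 10⁴
loci and 10 diploids per population, type-I error on 200 null replicates
(the "hybrid" a parental-A sister lineage) at 5 × 10³ loci, and
generation-class recovery on 200 pedigree individuals at a 148-locus
fully diagnostic panel — sizes chosen to give tight Monte-Carlo bounds
(SE of the γ mean ≈ 0.005) at desk-scale runtimes.

## Known limitations

* γ̂ is biased when parental effective sizes differ strongly
  post-founding; report orientation and check `no_signal`.
* The (S, H) likelihood ignores linkage between panel loci; for dense
  panels the effective number of independent loci is smaller and class
  margins are anti-conservative. Thin panels physically (50 kb default).
* The classifier's six fixed points cover only first- and
  second-generation classes; F3+, double backcrosses, etc. all fall into
  `later_generation_hybrid`.
* The simulator models frequencies, not sequences: no LD decay curves, no
  mutation during the epoch, no reference bias. Conclusions about real
  pipelines (mapping, calling, phasing) are out of scope.
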