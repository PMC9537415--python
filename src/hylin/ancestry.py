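"""Hybrid index, (S, H) ancestry-triangle estimation, and classification.

Given genotypes recoded against a parental diagnostic panel, each
individual is summarized by

* the hybrid index ``h`` — maximum-likelihood proportion of its alleles of
  parental-B origin,
* the joint maximum-likelihood ancestry proportion ``S`` (fraction of the
  genome of parental-A origin) and interclass heterozygosity ``H``
  (fraction of loci carrying one allele from each parental species).

(S, H) live on the triangle ``0 <= H <= 2 min(S, 1 - S)``. Pure parentals
sit at the bottom corners (H = 0, S = 0 or 1), F1 hybrids at the apex
(S = 0.5, H = 1), first-generation backcrosses near (0.75, 0.5) and
(0.25, 0.5), and an isolated hybrid lineage drifts down the triangle as
interclass heterozygosity decays while S stays near 0.5. Classification
compares the likelihood at those fixed generation-class points against the
free maximum with an information-criterion margin.

Loci are treated as independent in all likelihoods; panels are expected to
be physically thinned (e.g. 50 kb) to keep linkage weak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .genotype_io import MISSING, GenotypeMatrix
from .markers import DiagnosticPanel

#: fixed generation-class hypothesis points on the (S, H) triangle,
#: in tie-break preference order (simpler / purer classes first)
CLASS_POINTS = {
    "parentalA": (1.0, 0.0),
    "parentalB": (0.0, 0.0),
    "F1": (0.5, 1.0),
    "BC1A": (0.75, 0.5),
    "BC1B": (0.25, 0.5),
    "F2": (0.5, 0.5),
}

_TINY = 1e-300


@dataclass
class HybridIndexResult:
    id: str
    h: float
    logL: float
    n_loci: int
    support: tuple[float, float]  # 2-log-likelihood-unit profile interval


@dataclass
class AncestryEstimate:
    id: str
    S: float
    H: float
    logL: float
    n_loci: int
    class_label: str | None = None
    on_boundary: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.H <= 1.0):
            raise ValueError("H outside [0, 1]")
        if self.H > 2.0 * min(self.S, 1.0 - self.S) + 1e-9:
            raise ValueError("(S, H) outside the triangle")


# ----------------------------------------------------------------------
# Hybrid index


def _hybrid_index_loglik(h: float, g: np.ndarray, qA: np.ndarray, qB: np.ndarray):
    """log L(h) for coded genotypes g under Binomial(2, q_l(h)).

    q_l(h) = (1-h)(1-freqA_l) + h(1-freqB_l) is the probability that a
    random allele is the non-parental-A allele.
    """
    q = np.clip((1.0 - h) * qA + h * qB, _TINY, 1.0 - 1e-16)
    logp = np.where(
        g == 0,
        2.0 * np.log1p(-q),
        np.where(g == 2, 2.0 * np.log(q), np.log(2.0 * q * (1.0 - q))),
    )
    return float(logp.sum())


def hybrid_index(
    coded: np.ndarray,
    panel: DiagnosticPanel,
    ids: list[str] | None = None,
) -> list[HybridIndexResult]:
    """Per-individual maximum-likelihood hybrid index.

    ``coded`` is the 0/1/2/missing matrix from
    :func:`hylin.markers.recode_genotypes`. For a fully fixed panel the MLE
    reduces to the allele-count estimate (sum of codes) / (2 * n loci). A
    2-log-likelihood-unit profile support interval accompanies each point
    estimate. Individuals with no scored locus get ``h = nan``.
    """
    coded = np.atleast_2d(coded)
    ids = ids if ids is not None else [f"ind_{i}" for i in range(coded.shape[0])]
    qA = 1.0 - panel.freqA  # non-A-allele probability in parental A
    qB = 1.0 - panel.freqB
    out: list[HybridIndexResult] = []
    for i, row in enumerate(coded):
        ok = row != MISSING
        if not ok.any():
            out.append(HybridIndexResult(ids[i], np.nan, np.nan, 0, (np.nan, np.nan)))
            continue
        g, a, b = row[ok], qA[ok], qB[ok]
        res = optimize.minimize_scalar(
            lambda h: -_hybrid_index_loglik(h, g, a, b),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        h_hat, best = float(res.x), -float(res.fun)
        # snap to a boundary when it is at least as good (bounded Brent
        # cannot land exactly on 0 or 1)
        for edge in (0.0, 1.0):
            le = _hybrid_index_loglik(edge, g, a, b)
            if le >= best:
                h_hat, best = edge, le
        out.append(
            HybridIndexResult(
                ids[i], h_hat, best, int(ok.sum()),
                _profile_interval(lambda h: _hybrid_index_loglik(h, g, a, b),
                                  h_hat, best),
            )
        )
    return out


def _profile_interval(loglik, h_hat: float, best: float, drop: float = 2.0):
    lo, hi = 0.0, 1.0
    f = lambda h: loglik(h) - (best - drop)
    if f(0.0) < 0 and h_hat > 0:
        lo = optimize.brentq(f, 0.0, h_hat)
    if f(1.0) < 0 and h_hat < 1:
        hi = optimize.brentq(f, h_hat, 1.0)
    return (float(lo), float(hi))


# ----------------------------------------------------------------------
# (S, H) triangle likelihood


def _genotype_class_probs(g: np.ndarray, pA: np.ndarray, pB: np.ndarray) -> np.ndarray:
    """P(observed code | locus ancestry class), shape (3, n_loci).

    Rows: both alleles of A ancestry, one of each, both of B ancestry.
    ``pA``/``pB`` are parental-A-allele frequencies in species A and B;
    codes count non-parental-A alleles.
    """
    def binom2(p):  # P(code | allele is non-A w.p. 1-p, two draws)
        return np.where(
            g == 0, p * p, np.where(g == 2, (1 - p) * (1 - p), 2 * p * (1 - p))
        )

    p_het_mix = pA * (1 - pB) + (1 - pA) * pB
    mix = np.where(g == 0, pA * pB, np.where(g == 2, (1 - pA) * (1 - pB), p_het_mix))
    return np.vstack([binom2(pA), mix, binom2(pB)])


def _sh_loglik(points: np.ndarray, P: np.ndarray) -> np.ndarray:
    """log-likelihood of (S, H) rows in ``points`` given class probs ``P``."""
    S, H = points[:, 0], points[:, 1]
    W = np.stack([S - H / 2.0, H, 1.0 - S - H / 2.0], axis=1)
    W = np.clip(W, 0.0, 1.0)
    lik = W @ P
    return np.log(np.clip(lik, _TINY, None)).sum(axis=1)


def _triangle_grid(step: float = 0.02) -> np.ndarray:
    pts = []
    for S in np.round(np.arange(0.0, 1.0 + step / 2, step), 10):
        hmax = 2.0 * min(S, 1.0 - S)
        hs = list(np.round(np.arange(0.0, hmax + step / 2, step), 10))
        if not hs or hs[-1] < hmax:
            hs.append(hmax)
        pts.extend((S, H) for H in hs if H <= hmax + 1e-12)
    return np.array(pts)


_GRID = _triangle_grid(0.02)


def estimate_SH(
    coded: np.ndarray,
    panel: DiagnosticPanel,
    ids: list[str] | None = None,
    grid_step: float = 0.02,
    refine: bool = True,
) -> list[AncestryEstimate]:
    """Joint maximum-likelihood (S, H) on the ancestry triangle.

    Per locus, the three ancestry classes have probabilities
    P(AA) = S - H/2, P(AB) = H, P(BB) = 1 - S - H/2; each allele is then
    drawn from the corresponding parental frequency. The likelihood is
    maximized by a coarse grid (step 0.02) followed by Nelder-Mead
    refinement in a square reparameterization of the triangle; refinement
    is only accepted when it strictly improves the likelihood, so exact
    grid optima (corners, apex) are preserved.
    """
    if panel.freqA is None or panel.freqB is None:
        raise ValueError("panel lacks parental frequencies")
    coded = np.atleast_2d(coded)
    ids = ids if ids is not None else [f"ind_{i}" for i in range(coded.shape[0])]
    grid = _GRID if grid_step == 0.02 else _triangle_grid(grid_step)
    out: list[AncestryEstimate] = []
    for i, row in enumerate(coded):
        ok = row != MISSING
        if not ok.any():
            out.append(AncestryEstimate(ids[i], 0.5, 0.0, np.nan, 0))
            continue
        P = _genotype_class_probs(row[ok], panel.freqA[ok], panel.freqB[ok])
        ll = _sh_loglik(grid, P)
        j = int(np.argmax(ll))
        S, H, best = grid[j, 0], grid[j, 1], float(ll[j])
        if refine:
            S, H, best = _refine_sh(S, H, best, P)
        hmax = 2.0 * min(S, 1.0 - S)
        boundary = H <= 1e-9 or H >= hmax - 1e-9
        out.append(
            AncestryEstimate(
                ids[i], float(S), float(H), best, int(ok.sum()), on_boundary=boundary
            )
        )
    return out


def _refine_sh(S: float, H: float, best: float, P: np.ndarray):
    """Nelder-Mead polish in (S, v) with H = v * 2 min(S, 1-S)."""

    def unpack(x):
        s = min(max(x[0], 0.0), 1.0)
        v = min(max(x[1], 0.0), 1.0)
        return s, v * 2.0 * min(s, 1.0 - s)

    def nll(x):
        s, h = unpack(x)
        return -float(_sh_loglik(np.array([[s, h]]), P)[0])

    hmax = 2.0 * min(S, 1.0 - S)
    v0 = min(H / hmax, 1.0) if hmax > 0 else 0.0
    res = optimize.minimize(
        nll,
        x0=[min(max(S, 0.0), 1.0), v0],
        method="Nelder-Mead",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        options={"xatol": 1e-6, "fatol": 1e-9},
    )
    if -res.fun > best:
        s, h = unpack(res.x)
        return s, h, -float(res.fun)
    return S, H, best


def loglik_at(S: float, H: float, coded_row: np.ndarray, panel: DiagnosticPanel) -> float:
    """Log-likelihood of one individual at a fixed (S, H) point."""
    ok = coded_row != MISSING
    P = _genotype_class_probs(coded_row[ok], panel.freqA[ok], panel.freqB[ok])
    return float(_sh_loglik(np.array([[S, H]]), P)[0])


def classify_individual(
    estimate: AncestryEstimate,
    panel: DiagnosticPanel,
    coded_row: np.ndarray,
    class_margin: float = 2.0,
) -> str:
    """Assign a generation class from the (S, H) likelihood surface.

    The likelihood is evaluated at the six fixed hypothesis points
    (parentals, F1, F2, BC1A, BC1B) and compared with the free maximum.
    The best fixed class wins unless the free MLE exceeds it by more than
    ``class_margin`` log-units per free parameter (2 parameters, so the
    default margin of 2.0 demands a 4-log-unit improvement, an AIC-style
    penalty); then the individual is a ``later_generation_hybrid``. Ties
    between fixed classes resolve in the order of :data:`CLASS_POINTS`.
    """
    lls = {c: loglik_at(S, H, coded_row, panel) for c, (S, H) in CLASS_POINTS.items()}
    best_class = max(lls, key=lambda c: lls[c])
    n_free_params = 2
    if estimate.logL - lls[best_class] > class_margin * n_free_params:
        return "later_generation_hybrid"
    return best_class


def classify(
    matrix: GenotypeMatrix,
    panel: DiagnosticPanel,
    class_margin: float = 2.0,
):
    """Full pipeline: recode, hybrid index, (S, H), class label.

    Returns a pandas DataFrame with one row per sample: id, group, h, S, H,
    logL, n_loci, class.
    """
    import pandas as pd

    from .markers import recode_genotypes

    coded = recode_genotypes(matrix, panel)
    ids = list(matrix.samples)
    hres = hybrid_index(coded, panel, ids)
    sh = estimate_SH(coded, panel, ids)
    rows = []
    for i, (hr, est) in enumerate(zip(hres, sh)):
        label = (
            classify_individual(est, panel, coded[i], class_margin)
            if est.n_loci
            else "unclassified"
        )
        est.class_label = label
        rows.append(
            dict(
                sample_id=hr.id,
                group=matrix.groups[i],
                h=hr.h,
                h_support_lo=hr.support[0],
                h_support_hi=hr.support[1],
                S=est.S,
                H=est.H,
                logL=est.logL,
                n_loci=est.n_loci,
                **{"class": label},
            )
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Inbreeding coefficient


def inbreeding_coefficient(
    matrix: GenotypeMatrix, ref_group: str | None = None
) -> np.ndarray:
    """Per-individual F = 1 - observed / expected heterozygosity.

    Expected heterozygosity is the Hardy-Weinberg sum of 2 p (1 - p) over
    the individual's genotyped polymorphic sites, with allele frequencies
    taken from ``ref_group`` (all samples when None) — the
    method-of-moments convention of standard VCF tooling. Individuals with
    zero expected heterozygosity get ``nan``.
    """
    p = matrix.allele_freq(ref_group)
    poly = (p > 0) & (p < 1)
    exp_site = 2.0 * p * (1.0 - p)
    F = np.full(matrix.n_samples, np.nan)
    for i in range(matrix.n_samples):
        ok = (matrix.G[i] != MISSING) & poly
        exp = exp_site[ok].sum()
        if exp > 0:
            F[i] = 1.0 - (matrix.G[i][ok] == 1).sum() / exp
    return F
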