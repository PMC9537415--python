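"""Windowed Weir & Cockerham F_st and principal-component scores.

F_st follows the Weir & Cockerham (1984) variance-component estimator for
two populations with unequal sample sizes, computed per site from genotype
counts (components a: among populations, b: among individuals within
populations, c: within individuals). The window estimate is the weighted
ratio sum(a) / sum(a + b + c) over all sites in a fixed-size,
non-overlapping window (10 kb by default); negative values are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    windows: pd.DataFrame  # chrom, start, end, n_sites, weighted_fst, mean_fst
    genome_median: float  # median of weighted window Fst over non-empty windows
    genome_weighted: float  # sum(a)/sum(a+b+c) over all sites


def wc_components(
    matrix: GenotypeMatrix, groupA: str, groupB: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) components (a, b, c) plus a use-mask.

    Sites with fewer than two genotyped individuals in either group, or
    monomorphic across both groups, are masked out.
    """
    ia = matrix.sample_indices(groupA)
    ib = matrix.sample_indices(groupB)
    r = 2.0
    comps = []
    for idx in (ia, ib):
        sub = matrix.G[idx]
        called = sub != MISSING
        n_i = called.sum(axis=0).astype(float)  # genotyped diploids
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * n_i), np.nan)
        het_i = np.where(
            n_i > 0, (np.where(called, sub, 0) == 1).sum(axis=0) / np.maximum(n_i, 1), np.nan
        )
        comps.append((n_i, p_i, het_i))
    (nA, pA, hA), (nB, pB, hB) = comps

    use = (nA >= 2) & (nB >= 2)
    nbar = (nA + nB) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    use &= (pbar > 0) & (pbar < 1)  # monomorphic across both groups -> skip
    return a, b, c, use


def windowed_fst(
    matrix: GenotypeMatrix,
    groupA: str,
    groupB: str,
    window_bp: int = 10_000,
) -> FstResult:
    """Weir & Cockerham F_st in non-overlapping fixed-size windows.

    Windows are half-open ``[start, start + window_bp)`` anchored at
    position 1. Per window the weighted estimate sum(a)/sum(a+b+c) and the
    unweighted mean of per-site ratios are reported; windows without
    usable sites carry ``n_sites = 0`` and NaN F_st. The genome-wide
    median is the median of weighted window values over non-empty windows.
    """
    a, b, c, use = wc_components(matrix, groupA, groupB)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        site_fst = np.where(use & (denom != 0), a / denom, np.nan)
    win_start = ((matrix.pos - 1) // window_bp) * window_bp + 1

    rows = []
    for ch in pd.unique(matrix.chrom):
        on = matrix.chrom == ch
        for ws in np.unique(win_start[on]):
            j = np.flatnonzero(on & (win_start == ws))
            ju = j[use[j] & (denom[j] != 0)]
            n_sites = len(ju)
            if n_sites:
                wfst = float(a[ju].sum() / denom[ju].sum())
                mfst = float(np.nanmean(site_fst[ju]))
            else:
                wfst = mfst = np.nan
            rows.append(
                dict(
                    chrom=ch,
                    start=int(ws),
                    end=int(ws + window_bp),
                    n_sites=n_sites,
                    weighted_fst=wfst,
                    mean_fst=mfst,
                )
            )
    windows = pd.DataFrame(rows)
    nonempty = windows["n_sites"] > 0
    genome_median = float(windows.loc[nonempty, "weighted_fst"].median())
    tot = use & (denom != 0)
    genome_weighted = float(a[tot].sum() / denom[tot].sum()) if tot.any() else np.nan
    return FstResult(
        windows=windows, genome_median=genome_median, genome_weighted=genome_weighted
    )


def pca_scores(
    matrix: GenotypeMatrix, n_components: int = 6, scale: bool = False
):
    """PCA of the dosage matrix.

    Sites are mean-centered with missing dosages imputed to the site mean
    (center-only by default; per-site unit scaling behind ``scale``).
    Deterministic up to sign, fixed by making each component's
    largest-magnitude loading positive. Returns (scores DataFrame,
    explained-variance fractions).
    """
    from sklearn.decomposition import PCA

    X = matrix.G.astype(float)
    X[matrix.G == MISSING] = np.nan
    mean = np.nanmean(X, axis=0)
    poly = np.nanstd(X, axis=0) > 0
    if matrix.n_samples < 2 or poly.sum() < 2:
        raise ValueError("need >= 2 samples and >= 2 polymorphic sites")
    X = np.where(np.isnan(X), mean, X)[:, poly]
    if scale:
        X = X / X.std(axis=0, ddof=0)
    n_components = min(n_components, matrix.n_samples, int(poly.sum()))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # fix signs: largest-|loading| positive per component
    for k in range(n_components):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            scores[:, k] *= -1
            pca.components_[k] *= -1
    df = pd.DataFrame(
        scores, columns=[f"PC{k + 1}" for k in range(n_components)]
    )
    df.insert(0, "sample_id", matrix.samples)
    df["group"] = matrix.groups
    return df, pca.explained_variance_ratio_
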