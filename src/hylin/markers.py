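"""Diagnostic-marker discovery: private alleles, fixed differences, panels.

A *diagnostic panel* is a set of SNPs whose alleles are (nearly) fixed for
alternative variants in two parental species, oriented so that one allele
per site is "the parental-A allele". Genotypes recoded against a panel
count copies of the non-parental-A allele (0 = homozygous parental A,
1 = heterozygous, 2 = homozygous for the other parent's variant), the
coding used by hybrid-index and ancestry-triangle estimation downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, thin_by_distance

logger = logging.getLogger(__name__)


@dataclass
class DiagnosticPanel:
    """Oriented parental-diagnostic SNP set with parental allele frequencies.

    ``a_is_alt[j]`` is True when the parental-A allele at site ``j`` is the
    VCF ALT allele. ``freqA``/``freqB`` are the frequencies of the
    parental-A allele in parental species A and B respectively, so by
    construction ``freqA >= threshold_hi`` and ``freqB <= threshold_lo``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    a_is_alt: np.ndarray
    freqA: np.ndarray
    freqB: np.ndarray
    threshold_hi: float = 1.0
    threshold_lo: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "a_is_alt": self.a_is_alt.astype(int),
                "freqA": self.freqA,
                "freqB": self.freqB,
            }
        )

    def write(self, path: str) -> None:
        df = self.to_frame()
        df.attrs["threshold_hi"] = self.threshold_hi
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str, threshold_hi: float = 1.0, threshold_lo: float = 0.0):
        df = pd.read_csv(path, sep="\t")
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            a_is_alt=df["a_is_alt"].to_numpy(dtype=bool),
            freqA=df["freqA"].to_numpy(dtype=float),
            freqB=df["freqB"].to_numpy(dtype=float),
            threshold_hi=threshold_hi,
            threshold_lo=threshold_lo,
        )


def _group_freq_counts(matrix: GenotypeMatrix, group: str):
    """(alt-allele frequency, genotyped count) per site within a group."""
    sub = matrix.G[matrix.sample_indices(group)]
    called = sub != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
    return freq, n


def private_alleles(
    matrix: GenotypeMatrix,
    focal: str,
    others: list[str],
    min_freq: float = 0.5,
    criterion: str = "freq",
) -> pd.DataFrame:
    """Sites carrying a high-frequency allele private to the focal group.

    A site qualifies when one of its alleles (i) segregates in the focal
    group at frequency >= ``min_freq`` but below 1 (the focal group is
    polymorphic) and (ii) has exactly zero copies among genotyped
    individuals of every other group: a single copy elsewhere disqualifies.

    ``criterion`` selects how "high frequency" is measured: ``"freq"``
    (allele frequency, the primary definition) or ``"carrier"`` (fraction
    of focal individuals carrying at least one copy).

    Returns a table with chrom, pos, the private allele ('ref'/'alt') and
    its focal frequency. Sites where any group has no genotyped individual
    are skipped and counted in ``df.attrs['skipped_nodata']``.
    """
    if focal in others:
        raise ValueError("focal group must not appear in others")
    f_focal, n_focal = _group_freq_counts(matrix, focal)
    other_freqs = []
    usable = n_focal > 0
    for g in others:
        fo, no = _group_freq_counts(matrix, g)
        usable &= no > 0
        other_freqs.append(fo)
    other_freqs = np.vstack(other_freqs) if other_freqs else np.zeros((0, matrix.n_sites))
    n_skipped = int((~usable).sum())

    focal_sub = matrix.G[matrix.sample_indices(focal)]
    called = focal_sub != MISSING
    if criterion == "freq":
        alt_high = f_focal >= min_freq
        ref_high = (1.0 - f_focal) >= min_freq
    elif criterion == "carrier":
        n_called = np.maximum(called.sum(axis=0), 1)
        alt_carrier = (np.where(called, focal_sub, 0) > 0).sum(axis=0) / n_called
        ref_carrier = (np.where(called, focal_sub, 2) < 2).sum(axis=0) / n_called
        alt_high = alt_carrier >= min_freq
        ref_high = ref_carrier >= min_freq
    else:
        raise ValueError("criterion must be 'freq' or 'carrier'")

    alt_ok = usable & alt_high & (f_focal < 1.0) & (other_freqs == 0.0).all(axis=0)
    ref_ok = usable & ref_high & (f_focal > 0.0) & (other_freqs == 1.0).all(axis=0)

    idx = np.flatnonzero(alt_ok | ref_ok)
    allele = np.where(alt_ok[idx], "alt", "ref")
    freq = np.where(alt_ok[idx], f_focal[idx], 1.0 - f_focal[idx])
    df = pd.DataFrame(
        {
            "chrom": matrix.chrom[idx],
            "pos": matrix.pos[idx],
            "private_allele": allele,
            "focal_freq": freq,
        }
    )
    df.attrs["skipped_nodata"] = n_skipped
    df.attrs["criterion"] = criterion
    logger.info(
        "private_alleles: %d sites private to %s (%d skipped for missing data)",
        len(df),
        focal,
        n_skipped,
    )
    return df


def fixed_differences(matrix: GenotypeMatrix, groupA: str, groupB: str) -> pd.DataFrame:
    """Sites fully alternatively fixed between two groups.

    The parental-A allele frequency must be exactly 1.0 in ``groupA`` and
    0.0 in ``groupB`` (either orientation; the orientation is recorded).
    No physical-distance thinning is applied here.
    """
    fa, na = _group_freq_counts(matrix, groupA)
    fb, nb = _group_freq_counts(matrix, groupB)
    if not na.size or (na == 0).all():
        raise ValueError(f"group {groupA!r} has no genotyped individuals")
    if not nb.size or (nb == 0).all():
        raise ValueError(f"group {groupB!r} has no genotyped individuals")
    ok = (na > 0) & (nb > 0)
    alt_is_a = ok & (fa == 1.0) & (fb == 0.0)
    ref_is_a = ok & (fa == 0.0) & (fb == 1.0)
    idx = np.flatnonzero(alt_is_a | ref_is_a)
    df = pd.DataFrame(
        {
            "chrom": matrix.chrom[idx],
            "pos": matrix.pos[idx],
            "a_is_alt": alt_is_a[idx],
            "freqA_allele_in_A": np.ones(len(idx)),
            "freqA_allele_in_B": np.zeros(len(idx)),
        }
    )
    logger.info("fixed_differences: %d fully fixed sites", len(df))
    return df


def diagnostic_panel(
    matrix: GenotypeMatrix,
    groupA: str,
    groupB: str,
    hi: float = 0.95,
    lo: float = 0.05,
    thin_bp: int = 50_000,
) -> DiagnosticPanel:
    """Relaxed diagnostic panel: freq >= ``hi`` in one parent, <= ``lo`` in the other.

    Candidate sites are oriented so the parental-A allele is the
    high-frequency allele in ``groupA``, then thinned greedily to a minimum
    physical separation of ``thin_bp`` (50 kb by default, to reduce
    linkage). With ``hi=1, lo=0`` the panel reduces to the fixed
    differences after thinning.
    """
    if hi <= lo:
        raise ValueError("need hi > lo")
    fa, na = _group_freq_counts(matrix, groupA)
    fb, nb = _group_freq_counts(matrix, groupB)
    ok = (na > 0) & (nb > 0)
    alt_is_a = ok & (fa >= hi) & (fb <= lo)
    ref_is_a = ok & ((1 - fa) >= hi) & ((1 - fb) <= lo)
    cand = np.flatnonzero(alt_is_a | ref_is_a)
    if cand.size == 0:
        logger.warning("diagnostic_panel: no qualifying sites")
    kept = thin_by_distance(matrix.take_sites(cand), thin_bp)
    # map kept coordinates back to candidate indices
    key_all = pd.MultiIndex.from_arrays(
        [matrix.chrom[cand].astype(str), matrix.pos[cand]]
    )
    key_kept = pd.MultiIndex.from_arrays([kept.chrom.astype(str), kept.pos])
    sel = cand[key_all.get_indexer(key_kept)]
    a_is_alt = alt_is_a[sel]
    freqA = np.where(a_is_alt, fa[sel], 1 - fa[sel])
    freqB = np.where(a_is_alt, fb[sel], 1 - fb[sel])
    panel = DiagnosticPanel(
        chrom=matrix.chrom[sel],
        pos=matrix.pos[sel],
        a_is_alt=a_is_alt,
        freqA=freqA,
        freqB=freqB,
        threshold_hi=hi,
        threshold_lo=lo,
        meta={"thin_bp": thin_bp, "n_candidates": int(cand.size)},
    )
    logger.info(
        "diagnostic_panel: %d candidates -> %d sites after %d-bp thinning",
        cand.size,
        panel.n_sites,
        thin_bp,
    )
    return panel


def recode_genotypes(matrix: GenotypeMatrix, panel: DiagnosticPanel) -> np.ndarray:
    """Recode genotypes as copies of the non-parental-A allele.

    0 = homozygous for the parental-A allele, 1 = heterozygous,
    2 = homozygous for the other parent's allele; missing stays ``MISSING``.
    Returns an int8 array of shape (n_samples, panel.n_sites).
    """
    key_m = pd.MultiIndex.from_arrays([matrix.chrom.astype(str), matrix.pos])
    key_p = pd.MultiIndex.from_arrays([panel.chrom.astype(str), panel.pos])
    loc = key_m.get_indexer(key_p)
    if (loc < 0).any():
        missing = key_p[loc < 0][0]
        raise KeyError(f"panel site {missing} absent from matrix")
    sub = matrix.G[:, loc]
    coded = np.where(sub == MISSING, MISSING, np.where(panel.a_is_alt, 2 - sub, sub))
    return coded.astype(np.int8)
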