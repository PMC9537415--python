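"""Genotype matrices, VCF input/output, and site-level filtering.

The central container is :class:`GenotypeMatrix`: individuals x biallelic
SNPs coded as alternative-allele dosage (0/1/2, ``-1`` for missing), with
1-based VCF-convention coordinates and optional per-genotype read depth.
Reading applies the study-design genotype filter (calls below a minimum
read depth are set to missing); writing emits plain VCF v4.2 that
round-trips losslessly through :func:`read_vcf`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1

#: closed vocabulary of sample group labels
GROUPS = ("outgroup", "parentalA", "parentalB", "hybrid", "backcross", "other")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-SNP dosage matrix.

    Attributes
    ----------
    samples : array of str
        Sample identifiers, order preserved from the source.
    groups : array of str
        Group label per sample, from the closed vocabulary :data:`GROUPS`.
    chrom, pos, ref, alt : arrays
        Site coordinates (1-based positions, strictly increasing within a
        chromosome) and alleles.
    G : int8 array, shape (n_samples, n_sites)
        Alternative-allele dosage in {0, 1, 2}, ``MISSING`` (-1) otherwise.
    depth : int32 array or None
        Per-genotype read depth, same shape as ``G``.
    """

    samples: np.ndarray
    groups: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    G: np.ndarray
    depth: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"genotype matrix shape {self.G.shape} does not match "
                f"{len(self.samples)} samples x {len(self.pos)} sites"
            )
        if len(self.groups) != len(self.samples):
            raise ValueError("one group label per sample required")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_indices(self, group: str | Sequence[str]) -> np.ndarray:
        """Indices of samples belonging to ``group`` (label or labels)."""
        labels = {group} if isinstance(group, str) else set(group)
        unknown = labels - set(GROUPS)
        if unknown:
            raise KeyError(f"unknown group(s): {sorted(unknown)}")
        return np.flatnonzero(np.isin(self.groups, list(labels)))

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to site indices ``idx`` (order kept)."""
        idx = np.asarray(idx)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            G=self.G[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            meta=dict(self.meta),
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            samples=self.samples[idx],
            groups=self.groups[idx],
            G=self.G[idx, :],
            depth=None if self.depth is None else self.depth[idx, :],
            meta=dict(self.meta),
        )

    def allele_freq(self, group: str | None = None) -> np.ndarray:
        """Per-site alternative-allele frequency among non-missing genotypes.

        NaN where no individual (of the group) is genotyped.
        """
        sub = self.G if group is None else self.G[self.sample_indices(group)]
        called = sub != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)

    def missing_fraction(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        sub = self.G if sample_idx is None else self.G[sample_idx]
        return (sub == MISSING).mean(axis=0)


# ----------------------------------------------------------------------
# VCF input


def read_vcf(
    path: str,
    min_depth: int = 5,
    group_map: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a VCF v4.2 into a :class:`GenotypeMatrix`.

    Non-biallelic records and non-SNPs are dropped (counts logged).
    Genotype calls with ``FORMAT/DP`` below ``min_depth`` are set to
    missing, matching the study's genotype-quality rule; explicitly
    missing calls (``./.``) stay missing. If the file carries no DP and
    ``min_depth > 0`` a single warning is issued and no depth masking is
    applied.

    Parameters
    ----------
    group_map : mapping sample id -> group label, optional
        Samples absent from the mapping get group ``"other"``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib reports the offending position
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    chrom, pos, ref, alt = [], [], [], []
    dosages, depths = [], []
    n_dropped = 0
    has_depth = False
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    gt_code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF not in "ACGT"
            or v.ALT[0] not in "ACGT"
        ):
            n_dropped += 1
            continue
        g = gt_code[v.gt_types]
        try:
            dp = v.format("DP")
        except KeyError:  # DP absent from the header entirely
            dp = None
        if dp is not None:
            has_depth = True
            d = dp[:, 0].astype(np.int32)
            d[d < 0] = 0  # htslib encodes missing DP as negative sentinel
            depths.append(d)
        else:
            depths.append(None)
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        dosages.append(g)
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic/non-SNP records", n_dropped)

    n_sites = len(pos)
    G = (
        np.stack(dosages, axis=1)
        if n_sites
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depth = None
    if has_depth:
        depth = np.stack(
            [d if d is not None else np.zeros(len(samples), np.int32) for d in depths],
            axis=1,
        )
    if min_depth > 0:
        if depth is None:
            if n_sites:
                warnings.warn(
                    "VCF has no FORMAT/DP; depth masking skipped", stacklevel=2
                )
        else:
            masked = (depth < min_depth) & (G != MISSING)
            G = np.where(masked, MISSING, G).astype(np.int8)
            logger.info(
                "read_vcf: set %d genotypes with DP < %d to missing",
                int(masked.sum()),
                min_depth,
            )
    groups = np.array(
        [group_map.get(s, "other") if group_map else "other" for s in samples],
        dtype=object,
    )
    return GenotypeMatrix(
        samples=np.array(samples, dtype=object),
        groups=groups,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        G=G,
        depth=depth,
        meta={"dropped_records": n_dropped, "min_depth": min_depth},
    )


# ----------------------------------------------------------------------
# VCF output


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write ``matrix`` as VCF v4.2 (GT, and DP when depths are present).

    Round-trip safe: ``read_vcf(write_vcf(m))`` reproduces dosages,
    coordinates and missingness. Missing genotypes are emitted as ``./.``.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hylin\n")
        for c in pd.unique(matrix.chrom):
            length = int(matrix.pos[matrix.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if matrix.depth is not None:
            fh.write(
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            )
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(cols[:-1] + ["INFO", "FORMAT"] + list(matrix.samples)) + "\n")
        fmt = "GT" if matrix.depth is None else "GT:DP"
        for j in range(matrix.n_sites):
            fields = [
                str(matrix.chrom[j]),
                str(int(matrix.pos[j])),
                ".",
                str(matrix.ref[j]),
                str(matrix.alt[j]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            if matrix.depth is None:
                fields += [gt_str[int(g)] for g in matrix.G[:, j]]
            else:
                fields += [
                    f"{gt_str[int(g)]}:{int(d)}"
                    for g, d in zip(matrix.G[:, j], matrix.depth[:, j])
                ]
            fh.write("\t".join(fields) + "\n")


# ----------------------------------------------------------------------
# Sample-group tables


def read_group_table(path: str) -> dict[str, str]:
    """Read a sample->group TSV (columns sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("group table needs columns sample_id, group")
    return dict(zip(df["sample_id"], df["group"]))


def write_group_table(matrix: GenotypeMatrix, path: str, true_class=None) -> None:
    df = pd.DataFrame({"sample_id": matrix.samples, "group": matrix.groups})
    if true_class is not None:
        df["true_class"] = list(true_class)
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# Filters


def thin_by_distance(matrix: GenotypeMatrix, min_bp: int) -> GenotypeMatrix:
    """Greedy left-to-right physical thinning.

    Per chromosome the first site is kept, then each subsequent site at
    least ``min_bp`` downstream of the last kept site. Deterministic; used
    to reduce linkage between panel markers (e.g. 50-kb separation).
    """
    if min_bp < 0:
        raise ValueError("min_bp must be >= 0")
    keep: list[int] = []
    for c in pd.unique(matrix.chrom):
        idx = np.flatnonzero(matrix.chrom == c)
        last = None
        for j in idx:
            if last is None or matrix.pos[j] - last >= min_bp:
                keep.append(j)
                last = matrix.pos[j]
    out = matrix.take_sites(np.array(keep, dtype=int))
    out.meta["thin_min_bp"] = min_bp
    out.meta["thin_dialect"] = "greedy-from-left"
    logger.info(
        "thin_by_distance: kept %d / %d sites (min_bp=%d)",
        out.n_sites,
        matrix.n_sites,
        min_bp,
    )
    return out


def filter_sites(
    matrix: GenotypeMatrix,
    max_missing_frac: float = 0.0,
    groups: Iterable[str] | None = None,
    drop_monomorphic: bool = False,
) -> GenotypeMatrix:
    """Drop sites by missing-data fraction (optionally within named groups).

    ``max_missing_frac = 0`` keeps only fully genotyped sites; ``1`` is
    the identity. With ``drop_monomorphic`` sites that are
    monomorphic among the considered samples after masking are also removed.
    Surviving genotype values are never altered.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    sidx = None if groups is None else matrix.sample_indices(list(groups))
    sub = matrix.G if sidx is None else matrix.G[sidx]
    miss = (sub == MISSING).mean(axis=0)
    keep = miss <= max_missing_frac
    if drop_monomorphic:
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        keep &= (alt > 0) & (alt < tot)
    out = matrix.take_sites(np.flatnonzero(keep))
    logger.info(
        "filter_sites: kept %d / %d sites (max_missing=%.3g)",
        out.n_sites,
        matrix.n_sites,
        max_missing_frac,
    )
    return out
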