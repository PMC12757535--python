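"""Core genotype container shared by every statistic in the package.

The :class:`GenotypeMatrix` holds diploid genotype calls for a cohort as
dense integer arrays: allele indices per call (``-1`` for missing), a phase
flag per call, and optional per-call depth and genotype-quality metadata.
All downstream modules (diversity, ROH, kinship, selection scans) operate
on this container rather than re-reading VCF records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid genotype calls.

    Parameters
    ----------
    sample_ids
        Ordered sample labels, one per column.
    chrom
        Chromosome name per variant (length ``n_variants``).
    pos
        1-based physical position per variant; strictly increasing within
        each chromosome.
    ref, alt
        Reference allele string and tuple of alternate allele strings per
        variant.  Sites with more than one alternate are carried through
        and flagged via :attr:`is_biallelic`; statistics that require
        biallelic input must filter first.
    gt
        ``(n_variants, n_samples, 2)`` int8 array of allele indices;
        ``-1`` marks a missing allele call.
    phased
        ``(n_variants, n_samples)`` bool array: True where the call is
        phased (``|`` separator in VCF).
    depth, gq
        Optional ``(n_variants, n_samples)`` int32 arrays of per-call read
        depth and genotype quality; ``-1`` where absent.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray  # object array of tuples of alt alleles
    gt: np.ndarray
    phased: np.ndarray
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        n_var, n_smp = len(self.pos), len(self.sample_ids)
        if self.gt.shape != (n_var, n_smp, 2):
            raise ValueError(
                f"gt shape {self.gt.shape} != ({n_var}, {n_smp}, 2)"
            )
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        # normalize alt into a flat object array of tuples (naive
        # np.array() on a list of equal-length tuples goes 2-D)
        alt_in = (
            self.alt.tolist()
            if isinstance(self.alt, np.ndarray) and self.alt.ndim > 1
            else list(self.alt)
        )
        alt = np.empty(n_var, dtype=object)
        for i, a in enumerate(alt_in):
            if isinstance(a, str):
                alt[i] = (a,)
            else:
                alt[i] = tuple(np.ravel(np.asarray(a, dtype=object)).tolist())
        self.alt = alt
        self.phased = np.asarray(self.phased, dtype=bool)
        self._check_sorted()

    def _check_sorted(self) -> None:
        for c in dict.fromkeys(self.chrom.tolist()):
            p = self.pos[self.chrom == c]
            bad = np.nonzero(np.diff(p) <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"positions not strictly increasing on {c} near "
                    f"{c}:{p[bad[0] + 1]}"
                )

    # ------------------------------------------------------------------
    # basic shape / masks
    # ------------------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def is_missing(self) -> np.ndarray:
        """(n_variants, n_samples) bool: either allele call missing."""
        return (self.gt < 0).any(axis=2)

    @property
    def is_het(self) -> np.ndarray:
        """(n_variants, n_samples) bool: called and heterozygous."""
        return (~self.is_missing) & (self.gt[:, :, 0] != self.gt[:, :, 1])

    @property
    def is_biallelic(self) -> np.ndarray:
        return np.fromiter(
            (len(a) == 1 for a in self.alt), dtype=bool, count=self.n_variants
        )

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (0/1/2) as float with NaN for missing calls.

        Only meaningful for biallelic sites; multi-allelic calls count any
        non-reference allele.
        """
        d = (self.gt > 0).sum(axis=2).astype(float)
        d[self.is_missing] = np.nan
        return d

    def haplotypes(self) -> np.ndarray:
        """(n_variants, 2*n_samples) int8 haplotype matrix.

        Column order is sample0|a, sample0|b, sample1|a, ...  Requires no
        missing calls is *not* enforced; missing alleles stay ``-1``.
        """
        return self.gt.reshape(self.n_variants, 2 * self.n_samples)

    # ------------------------------------------------------------------
    # subsetting
    # ------------------------------------------------------------------
    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            gt=self.gt[idx],
            phased=self.phased[idx],
            depth=None if self.depth is None else self.depth[idx],
            gq=None if self.gq is None else self.gq[idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            gt=self.gt[:, idx],
            phased=self.phased[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
        )

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    # ------------------------------------------------------------------
    # allele counting
    # ------------------------------------------------------------------
    def allele_counts(self, sample_idx=None, n_alleles: int = 2) -> np.ndarray:
        """(n_variants, n_alleles) counts of called allele copies."""
        gt = self.gt if sample_idx is None else self.gt[:, sample_idx]
        flat = gt.reshape(self.n_variants, -1)
        counts = np.zeros((self.n_variants, n_alleles), dtype=np.int64)
        for a in range(n_alleles):
            counts[:, a] = (flat == a).sum(axis=1)
        return counts

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            sample_ids=list(self.sample_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            gt=self.gt.copy(),
            phased=self.phased.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            gq=None if self.gq is None else self.gq.copy(),
        )
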