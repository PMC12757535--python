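"""Runs of homozygosity and the F_ROH inbreeding coefficient.

Detection follows the PLINK scanning-window heuristic: fixed-size SNP
windows slide along each chromosome, a window "hits" when it contains at
most ``het_allowance`` heterozygous and ``miss_allowance`` missing calls,
each SNP is scored by the fraction of overlapping windows that hit, and
maximal runs of qualifying homozygous stretches are assembled, then
screened by SNP count, physical length, SNP density and maximum
inter-SNP gap.  Long ROH mark recent inbreeding, short ROH old
background relatedness; thresholding by minimum length separates the
two.  F_ROH divides the summed ROH length above a threshold by the
SNP-covered genome length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ROHParams",
    "detect_roh",
    "genome_covered_bp",
    "f_roh",
    "compare_froh",
    "DEFAULT_THRESHOLDS_MB",
]

DEFAULT_THRESHOLDS_MB = (0.1, 0.5, 1.0, 2.0)


@dataclass
class ROHParams:
    """Scanning-window detection parameters (PLINK-homozyg style).

    ``min_length_bp`` is the detection floor; larger report thresholds
    are applied post hoc by :func:`f_roh`.  ``min_density_bp_per_snp``
    requires at least one SNP per that many bp inside a run.
    """

    window_snps: int = 50
    het_allowance: int = 1
    miss_allowance: int = 5
    hit_fraction: float = 0.05
    min_snps: int = 25
    min_length_bp: int = 100_000
    min_density_bp_per_snp: int = 50_000
    max_gap_bp: int = 1_000_000


def _chrom_runs(
    pos: np.ndarray,
    is_hom: np.ndarray,
    is_het: np.ndarray,
    is_miss: np.ndarray,
    p: ROHParams,
) -> list[tuple[int, int, int, int]]:
    """Runs on one chromosome: (start_idx, end_idx, n_snps, n_het)."""
    m = len(pos)
    w = p.window_snps
    if m < w:
        return []
    # window w starting at i covers SNPs [i, i+w); hit if few het/missing
    het_c = np.convolve(is_het.astype(int), np.ones(w, dtype=int), "valid")
    mis_c = np.convolve(is_miss.astype(int), np.ones(w, dtype=int), "valid")
    hit = (het_c <= p.het_allowance) & (mis_c <= p.miss_allowance)
    # fraction of windows covering SNP i that hit
    csum = np.concatenate([[0], np.cumsum(hit)])
    starts_lo = np.maximum(np.arange(m) - w + 1, 0)
    starts_hi = np.minimum(np.arange(m), m - w)
    n_win = starts_hi - starts_lo + 1
    n_hit = csum[starts_hi + 1] - csum[starts_lo]
    frac = np.where(n_win > 0, n_hit / np.maximum(n_win, 1), 0.0)
    qual = (frac >= p.hit_fraction) & ~is_miss & ~is_het
    # allow isolated hets inside a run up to the window allowance:
    # a het SNP joins the run if both neighbours qualify
    joinable = is_het & ~is_miss
    runs: list[tuple[int, int, int, int]] = []
    i = 0
    while i < m:
        if not qual[i]:
            i += 1
            continue
        j = i
        n_het_used = 0
        while j + 1 < m:
            nxt = j + 1
            if pos[nxt] - pos[j] > p.max_gap_bp:
                break
            if qual[nxt]:
                j = nxt
                continue
            if (
                joinable[nxt]
                and n_het_used < p.het_allowance
                and nxt + 1 < m
                and qual[nxt + 1]
                and pos[nxt + 1] - pos[nxt] <= p.max_gap_bp
            ):
                n_het_used += 1
                j = nxt + 1
                continue
            break
        runs.append((i, j, j - i + 1, n_het_used))
        i = j + 1
    return runs


def detect_roh(
    g: GenotypeMatrix,
    params: ROHParams | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Detect ROH segments for each individual.

    Returns a DataFrame with columns sample, chrom, start, end (1-based
    positions of the first/last SNP in the run), n_snps, n_het_used,
    length_bp.  Chromosomes with fewer SNPs than one window are skipped
    (logged).  Deterministic: no randomness is involved.
    """
    p = params or ROHParams()
    names = samples or list(g.sample_ids)
    sidx = g.sample_index(names)
    het = g.is_het
    mis = g.is_missing
    hom = ~het & ~mis
    rows = []
    chroms = list(dict.fromkeys(g.chrom.tolist()))
    for c in chroms:
        on = np.nonzero(g.chrom == c)[0]
        if len(on) < p.window_snps:
            logger.info(
                "chromosome %s has %d < %d SNPs; skipped for ROH",
                c, len(on), p.window_snps,
            )
            continue
        pos = g.pos[on]
        for name, j in zip(names, sidx):
            for i0, i1, n_snps, n_het_used in _chrom_runs(
                pos, hom[on, j], het[on, j], mis[on, j], p
            ):
                length = int(pos[i1] - pos[i0] + 1)
                if n_snps < p.min_snps:
                    continue
                if length < p.min_length_bp:
                    continue
                if length / n_snps > p.min_density_bp_per_snp:
                    continue
                rows.append(
                    (name, c, int(pos[i0]), int(pos[i1]), n_snps,
                     n_het_used, length)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "start", "end", "n_snps", "n_het_used",
            "length_bp",
        ],
    )


def genome_covered_bp(g: GenotypeMatrix) -> int:
    """SNP-covered genome length: per-chromosome first-to-last SNP span."""
    total = 0
    for c in dict.fromkeys(g.chrom.tolist()):
        p = g.pos[g.chrom == c]
        total += int(p.max() - p.min() + 1)
    return total


def f_roh(
    segments: pd.DataFrame,
    genome_bp: int,
    thresholds_mb=DEFAULT_THRESHOLDS_MB,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-individual F_ROH at each length threshold.

    F_ROH = (summed length of that individual's ROH at least
    threshold_mb long) / genome_bp.  Individuals without a qualifying
    segment get f_roh = 0 with ``has_roh = False``; box plots that follow
    the convention of dropping them can filter on that flag.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    names = (
        samples
        if samples is not None
        else sorted(segments["sample"].unique().tolist())
    )
    rows = []
    for t in thresholds_mb:
        t_bp = t * 1e6
        for name in names:
            seg = segments[
                (segments["sample"] == name)
                & (segments["length_bp"] >= t_bp)
            ]
            total = int(seg["length_bp"].sum())
            rows.append(
                (name, t, total / genome_bp, total, len(seg), len(seg) > 0)
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample", "threshold_mb", "f_roh", "roh_bp", "n_segments",
            "has_roh",
        ],
    )
    return df


def compare_froh(
    froh: pd.DataFrame,
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-threshold two-group comparison of F_ROH distributions.

    Only individuals with at least one qualifying ROH at a threshold
    enter that threshold's test.  Reports the two-sided Wilcoxon
    rank-sum p plus box statistics (median, quartiles) per group; a
    degenerate test (an empty group) is reported with p = NaN.
    """
    if len(groups) != 2:
        raise ValueError("compare_froh requires exactly two groups")
    (nameA, sA), (nameB, sB) = groups.items()
    rows = []
    for t, sub in froh.groupby("threshold_mb"):
        sub = sub[sub["has_roh"]]
        a = sub[sub["sample"].isin(sA)]["f_roh"].to_numpy()
        b = sub[sub["sample"].isin(sB)]["f_roh"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            rows.append((t, len(a), len(b), np.nan, *[np.nan] * 6, True))
            continue
        method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
        p = float(mannwhitneyu(a, b, alternative="two-sided",
                               method=method).pvalue)
        rows.append(
            (
                t, len(a), len(b), p,
                float(np.median(a)), float(np.quantile(a, 0.25)),
                float(np.quantile(a, 0.75)),
                float(np.median(b)), float(np.quantile(b, 0.25)),
                float(np.quantile(b, 0.75)),
                min(len(a), len(b)) < 2,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "threshold_mb", f"n_{nameA}", f"n_{nameB}", "p_value",
            f"median_{nameA}", f"q1_{nameA}", f"q3_{nameA}",
            f"median_{nameB}", f"q1_{nameB}", f"q3_{nameB}",
            "caveat",
        ],
    )
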