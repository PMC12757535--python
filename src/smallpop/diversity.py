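"""Diversity summaries: Ho/He/allelic richness, windowed pi and F_ST.

Windows are defined over variant counts (20 SNPs sliding by 5 by
default), so every window carries the same amount of polymorphism
information regardless of local SNP density.  F_ST uses the
Weir-Cockerham variance-components estimator aggregated as a ratio of
sums across the window's sites; the Hudson estimator is available as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .matrix import GenotypeMatrix

__all__ = [
    "DiversitySummary",
    "site_heterozygosity",
    "allelic_richness",
    "per_site_pi",
    "windowed_pi",
    "wc_fst_components",
    "hudson_fst_components",
    "windowed_fst",
    "global_fst",
]


@dataclass
class DiversitySummary:
    """Per-site diversity values for one group plus median/95% bounds."""

    group: str
    values: pd.DataFrame  # per-site table
    medians: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]


def _group_indices(
    g: GenotypeMatrix, groups: dict[str, list[str]] | None
) -> dict[str, np.ndarray]:
    if groups is None:
        return {"all": np.arange(g.n_samples)}
    return {name: g.sample_index(s) for name, s in groups.items()}


def site_heterozygosity(
    g: GenotypeMatrix,
    groups: dict[str, list[str]] | None = None,
    bias_correct: bool = False,
) -> dict[str, DiversitySummary]:
    """Observed and expected heterozygosity per site, per group.

    Ho is the fraction of heterozygous calls among non-missing calls;
    He is 2*p*(1-p) from the group allele frequency, optionally with the
    small-sample factor n/(n-1) applied (off by default so He stays in
    [0, 0.5] for biallelic sites).  Sites with fewer than two called
    individuals in a group are skipped for that group.  Group summaries
    are medians with 2.5/97.5 percentile bounds of the per-site values.
    """
    out: dict[str, DiversitySummary] = {}
    for name, idx in _group_indices(g, groups).items():
        sub_missing = g.is_missing[:, idx]
        called = (~sub_missing).sum(axis=1)
        het = g.is_het[:, idx].sum(axis=1)
        dos = g.dosage()[:, idx]
        n_copies = 2 * called
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(dos, axis=1) / n_copies
            ho = het / called
            he = 2 * p * (1 - p)
            if bias_correct:
                he = he * n_copies / np.maximum(n_copies - 1, 1)
        ok = called >= 2
        df = pd.DataFrame(
            {
                "chrom": g.chrom[ok],
                "pos": g.pos[ok],
                "n_called": called[ok],
                "Ho": ho[ok],
                "He": he[ok],
            }
        )
        med = {k: float(df[k].median()) for k in ("Ho", "He")}
        lo = {k: float(df[k].quantile(0.025)) for k in ("Ho", "He")}
        hi = {k: float(df[k].quantile(0.975)) for k in ("Ho", "He")}
        out[name] = DiversitySummary(name, df, med, lo, hi)
    return out


def _rarefied_allele_count(
    counts: np.ndarray, grab: int
) -> float:
    """Expected number of distinct alleles in a draw of ``grab`` copies.

    Hypergeometric rarefaction: sum over alleles of
    1 - C(N - N_a, g) / C(N, g), with N total called copies.
    """
    counts = counts[counts > 0]
    n_tot = counts.sum()
    if grab > n_tot:
        return np.nan

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    ar = 0.0
    for na in counts:
        if n_tot - na < grab:
            ar += 1.0
        else:
            ar += 1.0 - np.exp(
                log_comb(n_tot - na, grab) - log_comb(n_tot, grab)
            )
    return float(ar)


def allelic_richness(
    g: GenotypeMatrix,
    groups: dict[str, list[str]] | None = None,
    rarefaction_size: int | None = None,
) -> dict[str, DiversitySummary]:
    """Per-site allelic richness rarefied to a common allele-copy count.

    ``rarefaction_size`` defaults to twice the smallest group's diploid
    count; sites where a group has fewer called copies than the grab are
    skipped for that group.
    """
    gidx = _group_indices(g, groups)
    if rarefaction_size is None:
        rarefaction_size = 2 * min(len(v) for v in gidx.values())
    n_alleles = int(
        max((len(a) for a in g.alt), default=0) + 1
    )
    out: dict[str, DiversitySummary] = {}
    for name, idx in gidx.items():
        counts = g.allele_counts(sample_idx=idx, n_alleles=n_alleles)
        ar = np.array(
            [_rarefied_allele_count(c, rarefaction_size) for c in counts]
        )
        ok = ~np.isnan(ar)
        df = pd.DataFrame(
            {"chrom": g.chrom[ok], "pos": g.pos[ok], "AR": ar[ok]}
        )
        out[name] = DiversitySummary(
            name,
            df,
            {"AR": float(df["AR"].median())},
            {"AR": float(df["AR"].quantile(0.025))},
            {"AR": float(df["AR"].quantile(0.975))},
        )
    return out


# ----------------------------------------------------------------------
# pi
# ----------------------------------------------------------------------
def per_site_pi(
    g: GenotypeMatrix, sample_idx: np.ndarray | None = None
) -> np.ndarray:
    """Per-site nucleotide diversity over called allele copies.

    pi_site = (n/(n-1)) * (1 - sum_a p_a^2) with n the called copies at
    that site; equals the mean pairwise difference among the site's
    copies.  Sites with n < 2 return NaN.
    """
    n_alleles = int(max((len(a) for a in g.alt), default=0) + 1)
    counts = g.allele_counts(sample_idx=sample_idx, n_alleles=n_alleles)
    n = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_p2 = (counts**2).sum(axis=1) / n**2
        pi = n / (n - 1) * (1 - sum_p2)
    pi[n < 2] = np.nan
    return pi


def _window_slices(
    g: GenotypeMatrix, site_idx: np.ndarray, window_sites: int, step_sites: int
) -> list[tuple[str, np.ndarray]]:
    """SNP-count windows per chromosome over a site-index subset."""
    out = []
    for c in dict.fromkeys(g.chrom.tolist()):
        on = site_idx[g.chrom[site_idx] == c]
        i = 0
        while i < len(on):
            win = on[i : i + window_sites]
            if len(win) == 0:
                break
            out.append((c, win))
            if i + window_sites >= len(on):
                break
            i += step_sites
    return out


def windowed_pi(
    g: GenotypeMatrix,
    group: list[str] | None = None,
    window_sites: int = 20,
    step_sites: int = 5,
    site_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sliding-window pi in SNP-count windows (mean over window sites)."""
    idx = None if group is None else g.sample_index(group)
    pi = per_site_pi(g, sample_idx=idx)
    if site_idx is None:
        site_idx = np.arange(g.n_variants)
    rows = []
    for c, win in _window_slices(g, site_idx, window_sites, step_sites):
        vals = pi[win]
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        rows.append(
            (
                c,
                int(g.pos[win[0]]),
                int(g.pos[win[-1]]),
                len(win),
                float(np.mean(vals[ok])),
            )
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start_pos", "end_pos", "n_sites", "pi"]
    )


# ----------------------------------------------------------------------
# F_ST
# ----------------------------------------------------------------------
def wc_fst_components(
    g: GenotypeMatrix, idx1: np.ndarray, idx2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham per-site variance components (a, a+b+c).

    Two-population biallelic form of the 1984 estimator including the
    observed-heterozygote terms, so it is exact for non-HWE genotype
    configurations.  Returns the numerator ``a`` and total ``a+b+c`` per
    site; a site monomorphic over both groups contributes zero to both.
    """
    r = 2
    d = g.dosage()
    parts = []
    for idx in (idx1, idx2):
        sub = d[:, idx]
        n_i = np.sum(~np.isnan(sub), axis=1).astype(float)  # diploid counts
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.nansum(sub, axis=1) / (2 * n_i)
        h_i = np.sum(sub == 1, axis=1) / np.maximum(n_i, 1)  # obs het freq
        parts.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = parts

    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / (
            (r - 1) * n_bar
        )
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - 1.0
            / (n_bar - 1)
            * (
                p_bar * (1 - p_bar)
                - (r - 1) / r * s2
                - h_bar / 4.0
            )
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    tot = a + b + c
    bad = (n1 < 1) | (n2 < 1) | ~np.isfinite(tot)
    a = np.where(bad, 0.0, a)
    tot = np.where(bad, 0.0, tot)
    return a, tot


def hudson_fst_components(
    g: GenotypeMatrix, idx1: np.ndarray, idx2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson's estimator components (numerator, denominator) per site."""
    d = g.dosage()
    comps = []
    for idx in (idx1, idx2):
        sub = d[:, idx]
        n = 2 * np.sum(~np.isnan(sub), axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(sub, axis=1) / n
        comps.append((n, p))
    (n1, p1), (n2, p2) = comps
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (
            n2 - 1
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(num) | ~np.isfinite(den)
    return np.where(bad, 0.0, num), np.where(bad, 0.0, den)


def windowed_fst(
    g: GenotypeMatrix,
    pops: dict[str, list[str]],
    window_sites: int = 20,
    step_sites: int = 5,
    site_idx: np.ndarray | None = None,
    estimator: str = "wc",
) -> pd.DataFrame:
    """Sliding-window F_ST between exactly two populations.

    The per-window value is the ratio of summed numerator components to
    summed total components over the window's sites (ratio-of-sums, the
    VCFtools/W&C convention).  Negative values are retained.
    """
    if len(pops) != 2:
        raise ValueError("windowed_fst requires exactly two populations")
    (nameA, sA), (nameB, sB) = pops.items()
    idx1, idx2 = g.sample_index(sA), g.sample_index(sB)
    f = wc_fst_components if estimator == "wc" else hudson_fst_components
    num, den = f(g, idx1, idx2)
    if site_idx is None:
        site_idx = np.arange(g.n_variants)
    rows = []
    for c, win in _window_slices(g, site_idx, window_sites, step_sites):
        sn, sd = num[win].sum(), den[win].sum()
        fst = sn / sd if sd != 0 else np.nan
        rows.append(
            (
                c,
                int(g.pos[win[0]]),
                int(g.pos[win[-1]]),
                len(win),
                float(fst),
            )
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "start_pos", "end_pos", "n_sites", "fst"]
    )
    df.attrs["populations"] = (nameA, nameB)
    return df


def global_fst(
    g: GenotypeMatrix,
    pops: dict[str, list[str]],
    site_idx: np.ndarray | None = None,
    estimator: str = "wc",
    mode: str = "ratio_of_sums",
) -> float:
    """Genome-wide F_ST: ratio-of-sums or mean of per-site ratios."""
    if len(pops) != 2:
        raise ValueError("global_fst requires exactly two populations")
    (nameA, sA), (nameB, sB) = pops.items()
    idx1, idx2 = g.sample_index(sA), g.sample_index(sB)
    f = wc_fst_components if estimator == "wc" else hudson_fst_components
    num, den = f(g, idx1, idx2)
    if site_idx is not None:
        num, den = num[site_idx], den[site_idx]
    if mode == "ratio_of_sums":
        return float(num.sum() / den.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = num / den
    return float(np.nanmean(ratios[den != 0]))
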