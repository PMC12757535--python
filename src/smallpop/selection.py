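"""Extended haplotype homozygosity (EHH), its integral (iHH), and the
cross-population XP-EHH selection scan.

EHH at distance x from a core site is the probability that two randomly
drawn haplotypes are identical over the whole stretch from the core to
x; it starts at 1 and decays outward as recombination and mutation break
haplotypes up.  A recent positive sweep drags long identical haplotypes
to high frequency, inflating the area under the curve (iHH).  XP-EHH
contrasts that area between two populations at the same core:
ln(iHH_A / iHH_B), so *negative* scores mean longer haplotype
homozygosity -- recent selection -- in population B.  Scores are
standardized genome-wide (one bin) and the empirical 5% tails are
flagged as outliers.

Integration is over physical distance; no recombination map is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = ["XPEHHParams", "ehh", "ihh", "xpehh_scan"]


@dataclass
class XPEHHParams:
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 200_000
    max_extend_bp: int = 1_000_000
    max_missing_frac: float = 0.05


def _homozygosity(counts: np.ndarray, n: int) -> float:
    """Sum_k C(n_k,2) / C(n,2) for group sizes ``counts``."""
    if n < 2:
        return np.nan
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh(
    hap: np.ndarray,
    pos: np.ndarray,
    core_idx: int,
    direction: str,
    params: XPEHHParams | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One-sided EHH decay curve from a core site.

    Parameters
    ----------
    hap
        (n_haplotypes, n_sites) allele matrix (0/1; negative = missing).
    pos
        Physical positions per site (same order as columns).
    core_idx
        Column index of the core site.
    direction
        "left" or "right".

    Returns ``(distances, ehh_values, hit_edge)`` where distances start
    at 0 (EHH = 1 by definition) and ``hit_edge`` is True when the curve
    ran off the contig or a guard before decaying below the cutoff.
    Haplotypes with a missing call in the extension window are dropped
    from the curve; the whole curve is invalid (empty arrays) when more
    than ``max_missing_frac`` of haplotypes drop.
    """
    p = params or XPEHHParams()
    n_hap, n_sites = hap.shape
    if n_hap < 2:
        return np.array([]), np.array([]), False
    step = -1 if direction == "left" else 1
    order = range(core_idx + step, -1, -1) if step < 0 else range(
        core_idx + step, n_sites
    )
    dists = [0.0]
    values = [1.0]
    # group labels over haplotypes identical from core to current edge;
    # start from the core allele itself
    alive = hap[:, core_idx] >= 0
    labels = hap[:, core_idx].astype(np.int64)
    hit_edge = True
    prev_pos = pos[core_idx]
    max_drop = int(np.floor(p.max_missing_frac * n_hap))
    for k in order:
        d = abs(int(pos[k]) - int(pos[core_idx]))
        if d > p.max_extend_bp or abs(int(pos[k]) - int(prev_pos)) > p.max_gap_bp:
            break
        prev_pos = pos[k]
        a = hap[:, k]
        newly_missing = alive & (a < 0)
        if newly_missing.any():
            alive = alive & ~newly_missing
            if (n_hap - alive.sum()) > max_drop:
                return np.array([]), np.array([]), False
        lab = labels[alive] * 2 + a[alive]
        _, labels_alive, counts = np.unique(
            lab, return_inverse=True, return_counts=True
        )
        labels = labels.copy()
        labels[alive] = labels_alive
        n_alive = int(alive.sum())
        e = _homozygosity(counts.astype(float), n_alive)
        dists.append(float(d))
        values.append(e)
        if e < p.ehh_cutoff:
            hit_edge = False
            break
        if (counts <= 1).all():  # all singletons: EHH stays 0
            hit_edge = False
            break
    return np.array(dists), np.array(values), hit_edge


def ihh(
    hap: np.ndarray,
    pos: np.ndarray,
    core_idx: int,
    params: XPEHHParams | None = None,
) -> tuple[float, bool]:
    """Integrated EHH: trapezoid area over both directions in bp.

    The curve is truncated at the first point below the EHH cutoff (that
    trapezoid is included, ending at the crossing site).  Returns
    ``(area, partial)`` where ``partial`` is True when either side ran
    off the contig or a guard before reaching the cutoff.
    """
    p = params or XPEHHParams()
    area = 0.0
    partial = False
    any_side = False
    for direction in ("left", "right"):
        d, e, edge = ehh(hap, pos, core_idx, direction, p)
        if len(d) == 0:
            continue
        any_side = True
        area += float(np.trapezoid(e, d))
        partial = partial or edge
    if not any_side:
        return np.nan, True
    return area, partial


def xpehh_scan(
    g: GenotypeMatrix,
    popA: list[str],
    popB: list[str],
    params: XPEHHParams | None = None,
    site_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cross-population XP-EHH scan over polymorphic shared sites.

    Per site: xpehh_raw = ln(iHH_A / iHH_B) using all haplotypes of each
    population (unpolarized).  Raw scores are standardized by the
    genome-wide mean and SD of included sites; ``outlier_flag`` marks
    scores beyond the empirical 5th/95th percentiles.  Sites where
    either iHH is undefined or zero are reported with NaN and excluded
    from normalization and percentiles.
    """
    p = params or XPEHHParams()
    idxA = g.sample_index(popA)
    idxB = g.sample_index(popB)
    hapA = g.gt[:, idxA].reshape(g.n_variants, -1).T.astype(np.int64)
    hapB = g.gt[:, idxB].reshape(g.n_variants, -1).T.astype(np.int64)
    sites = (
        np.arange(g.n_variants) if site_idx is None else np.asarray(site_idx)
    )
    rows = []
    chroms = list(dict.fromkeys(g.chrom.tolist()))
    for c in chroms:
        on = np.nonzero(g.chrom == c)[0]
        lookup = {int(v): k for k, v in enumerate(on)}
        pos_c = g.pos[on]
        hA, hB = hapA[:, on], hapB[:, on]
        # polymorphic in the combined sample
        pooled = np.concatenate([hA, hB], axis=0)
        for s in sites:
            if int(s) not in lookup:
                continue
            k = lookup[int(s)]
            col = pooled[:, k]
            col = col[col >= 0]
            if col.size == 0 or (col == col[0]).all():
                continue
            ia, part_a = ihh(hA, pos_c, k, p)
            ib, part_b = ihh(hB, pos_c, k, p)
            if not np.isfinite(ia) or not np.isfinite(ib) or ia <= 0 or ib <= 0:
                raw = np.nan
            else:
                raw = float(np.log(ia / ib))
            rows.append(
                (c, int(g.pos[s]), ia, ib, raw, bool(part_a or part_b))
            )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ihh_a", "ihh_b", "xpehh_raw", "partial"],
    )
    ok = df["xpehh_raw"].notna()
    mu = df.loc[ok, "xpehh_raw"].mean()
    sd = df.loc[ok, "xpehh_raw"].std(ddof=0)
    df["xpehh_norm"] = np.nan
    if ok.any() and sd > 0:
        df.loc[ok, "xpehh_norm"] = (df.loc[ok, "xpehh_raw"] - mu) / sd
        lo = df.loc[ok, "xpehh_norm"].quantile(0.05)
        hi = df.loc[ok, "xpehh_norm"].quantile(0.95)
    else:
        lo = hi = np.nan
    df["outlier_flag"] = "none"
    if np.isfinite(lo):
        df.loc[ok & (df["xpehh_norm"] <= lo), "outlier_flag"] = "bottom5"
        df.loc[ok & (df["xpehh_norm"] >= hi), "outlier_flag"] = "top5"
    df.attrs["threshold_low"] = float(lo) if np.isfinite(lo) else None
    df.attrs["threshold_high"] = float(hi) if np.isfinite(hi) else None
    return df
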